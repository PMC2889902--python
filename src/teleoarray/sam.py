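"""Two-class SAM with permutation FDR, probe filtering and aggregation.

Significance Analysis of Microarrays scores each probe with a regularized
t-like statistic d = (mean_B - mean_A) / (s + s0), where s is the pooled
standard error and s0 a small "fudge factor" stabilizing low-variance
probes. Order statistics of d under balanced label permutations give the
expected null band; probes deviating from it by more than a threshold delta
are called, and the FDR of a call set is estimated from the median number of
permutation false calls scaled by the estimated null proportion pi0. Delta
is tuned to the largest call set whose estimated FDR stays at or below the
target.

The module also provides the missing-value filter applied before testing,
probe-to-transcript aggregation of the significant list, and the
tissue-dilution model translating a fold change confined to a small
anatomical region into the attenuated fold change observed on whole-tissue
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from teleoarray.dataset import ExpressionDataset, transcript_of


# ---------------------------------------------------------------------------
# missing-value handling


def missing_value_filter(
    dataset: ExpressionDataset, max_missing_per_condition: int = 2
) -> tuple[ExpressionDataset, list[str]]:
    """Drop probes with too many missing values in either condition.

    A value is missing when its detection flag is 0; a probe is removed iff
    its missing count exceeds ``max_missing_per_condition`` in at least one
    condition. Retained probes may still carry up to that many missing
    values per condition.
    """
    removed = pd.Series(False, index=dataset.probe_ids)
    for condition in dataset.samples["condition"].unique():
        cols = dataset.condition_samples(condition)
        n_missing = (dataset.flags[cols] == 0).sum(axis=1)
        removed |= n_missing > max_missing_per_condition
    removed_ids = list(dataset.probe_ids[removed])
    return dataset.subset_probes(dataset.probe_ids[~removed]), removed_ids


def impute_missing(dataset: ExpressionDataset) -> ExpressionDataset:
    """Replace flag-0 intensities by the within-condition probe mean.

    The mean is taken over the flagged (present) replicates of the same
    condition; a probe with no present value in a condition falls back to
    its overall present mean.
    """
    intensities = dataset.intensities.copy()
    present = dataset.flags == 1
    overall = intensities.where(present).mean(axis=1)
    for condition in dataset.samples["condition"].unique():
        cols = dataset.condition_samples(condition)
        block = intensities[cols]
        means = block.where(present[cols]).mean(axis=1).fillna(overall)
        for col in cols:
            mask = ~present[col]
            intensities.loc[mask, col] = means[mask]
    return dataset.with_intensities(intensities)


# ---------------------------------------------------------------------------
# the SAM statistic


@dataclass
class SamParameters:
    """Tuning knobs of the two-class SAM test.

    ``s0="auto"`` applies the original recipe (the percentile of the pooled
    standard errors minimizing the coefficient of variation of d across
    standard-error bins). Permutations are exhaustive over balanced label
    reassignments whenever their number is at most ``max_exhaustive``,
    otherwise ``n_permutations`` Monte-Carlo draws seeded by ``seed``.
    ``delta=None`` auto-tunes to the largest call set with estimated FDR at
    or below ``fdr_target``.
    """

    s0: float | str = "auto"
    n_permutations: int = 500
    max_exhaustive: int = 1000
    fdr_target: float = 0.05
    delta: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_target < 1:
            raise ValueError("fdr_target must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be at least 1")


@dataclass
class SamResult:
    table: pd.DataFrame  # per-probe statistics, indexed by probe id
    delta: float
    fdr: float  # estimated FDR of the reported call set (fraction)
    s0: float
    pi0: float
    n_permutations: int
    exhaustive: bool
    cut_up: float
    cut_low: float
    classes: tuple[str, str]

    @property
    def significant_ids(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _pooled_stats(values: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray):
    """Per-probe difference of means and pooled standard error (B minus A)."""
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    mean_a = values[:, mask_a].mean(axis=1)
    mean_b = values[:, mask_b].mean(axis=1)
    ss_a = ((values[:, mask_a] - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((values[:, mask_b] - mean_b[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n_a + 1.0 / n_b) * (ss_a + ss_b) / (n_a + n_b - 2))
    return mean_b - mean_a, s, mean_a, mean_b


def choose_s0(r: np.ndarray, s: np.ndarray, n_bins: int = 100) -> float:
    """Original fudge-factor recipe: minimize the CV of |d| spread across s-bins.

    Candidate s0 values are percentiles (0, 5, ..., 100) of s; for each, the
    median absolute deviation of d is computed within ``n_bins`` quantile
    bins of s and the candidate minimizing the coefficient of variation of
    those MADs wins. A strictly positive floor guards zero-variance probes.
    """
    candidates = np.percentile(s, np.arange(0, 101, 5))
    n_bins = max(2, min(n_bins, len(s) // 20 or 2))
    quantiles = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(quantiles, s, side="right") - 1, 0, n_bins - 1)
    best_s0, best_cv = None, np.inf
    for s0 in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = r / (s + s0)
        mads = []
        for b in range(n_bins):
            group = d[bins == b]
            if group.size:
                med = np.median(group)
                mads.append(np.median(np.abs(group - med)))
        mads = np.asarray(mads)
        if not mads.size or mads.mean() == 0 or not np.isfinite(mads).all():
            continue
        cv = mads.std(ddof=0) / mads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    if best_s0 is None or best_s0 <= 0:
        positive = s[s > 0]
        floor = float(np.percentile(positive, 5)) if positive.size else 1e-8
        best_s0 = max(best_s0 or 0.0, floor, 1e-8)
    return best_s0


def _permutation_masks(
    labels: np.ndarray, class_b: str, params: SamParameters
) -> tuple[np.ndarray, bool]:
    """Boolean masks (one per permutation) marking the class-B columns."""
    n = len(labels)
    n_b = int((labels == class_b).sum())
    total = comb(n, n_b)
    if total <= params.max_exhaustive:
        masks = np.zeros((total, n), dtype=bool)
        for row, chosen in enumerate(combinations(range(n), n_b)):
            masks[row, list(chosen)] = True
        return masks, True
    rng = np.random.default_rng(params.seed)
    masks = np.zeros((params.n_permutations, n), dtype=bool)
    for row in range(params.n_permutations):
        masks[row, rng.choice(n, size=n_b, replace=False)] = True
    return masks, False


def _cutoffs(d_sorted: np.ndarray, dbar: np.ndarray, delta: float):
    """SAM slab rule: cut points where observed order statistics leave the band."""
    diff = d_sorted - dbar
    upper = np.where((diff >= delta) & (dbar >= 0))[0]
    lower = np.where((-diff >= delta) & (dbar <= 0))[0]
    cut_up = d_sorted[upper].min() if upper.size else np.inf
    cut_low = d_sorted[lower].max() if lower.size else -np.inf
    return cut_up, cut_low


def sam_two_class(
    log2_values: pd.DataFrame,
    labels: pd.Series,
    params: SamParameters | None = None,
    classes: tuple[str, str] | None = None,
) -> SamResult:
    """Two-class unpaired SAM on log2 expression values.

    ``labels`` assigns each column to one of two classes; d is oriented as
    mean(classes[1]) - mean(classes[0]) (by default the classes in order of
    first appearance, i.e. reference first). Requires at least two
    replicates per class and no missing values (impute first).
    """
    params = params or SamParameters()
    labels = pd.Series(labels, index=log2_values.columns).astype(str)
    if classes is None:
        classes = tuple(dict.fromkeys(labels))  # order of first appearance
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    class_a, class_b = classes
    mask_a = (labels == class_a).to_numpy()
    mask_b = (labels == class_b).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("need at least two replicates per class")
    if not (mask_a | mask_b).all():
        raise ValueError("every sample must belong to one of the two classes")
    values = log2_values.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing values present; impute before testing")
    m = values.shape[0]

    r, s, mean_a, mean_b = _pooled_stats(values, mask_a, mask_b)
    s0 = choose_s0(r, s) if params.s0 == "auto" else float(params.s0)
    if s0 <= 0 and (s == 0).any():
        raise ValueError("s0 must be positive when zero-variance probes exist")
    d = r / (s + s0)

    masks, exhaustive = _permutation_masks(labels.to_numpy(), class_b, params)
    perm_sorted = np.empty((masks.shape[0], m))
    for row, mb in enumerate(masks):
        pr, ps, *_ = _pooled_stats(values, ~mb, mb)
        perm_sorted[row] = np.sort(pr / (ps + s0))
    dbar = perm_sorted.mean(axis=0)

    flat = perm_sorted.ravel()
    q25, q75 = np.percentile(flat, [25, 75])
    pi0 = min(1.0, ((d > q25) & (d < q75)).sum() / (0.5 * m))

    order = np.argsort(d, kind="mergesort")
    d_sorted = d[order]
    diffs = np.abs(d_sorted - dbar)
    grid = np.unique(diffs)
    if grid.size > 400:  # keep the scan tractable on platform-scale inputs
        grid = np.unique(np.quantile(grid, np.linspace(0, 1, 400)))
    grid = np.unique(np.concatenate([[0.0], grid]))

    cut_ups = np.empty(grid.size)
    cut_lows = np.empty(grid.size)
    for k, delta in enumerate(grid):
        cut_ups[k], cut_lows[k] = _cutoffs(d_sorted, dbar, delta)
    n_called = (
        (m - np.searchsorted(d_sorted, cut_ups, side="left"))
        + np.searchsorted(d_sorted, cut_lows, side="right")
    )
    false_counts = np.empty((perm_sorted.shape[0], grid.size))
    for row in range(perm_sorted.shape[0]):
        false_counts[row] = (
            m - np.searchsorted(perm_sorted[row], cut_ups, side="left")
        ) + np.searchsorted(perm_sorted[row], cut_lows, side="right")
    median_false = np.median(false_counts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_called > 0, pi0 * median_false / n_called, 0.0)

    # per-probe q-value: smallest estimated FDR at which the probe is called
    q = np.full(m, 1.0)
    for k in range(grid.size):
        called = (d >= cut_ups[k]) | (d <= cut_lows[k])
        q[called] = np.minimum(q[called], fdr[k])

    if params.delta is not None:
        delta = float(params.delta)
        cut_up, cut_low = _cutoffs(d_sorted, dbar, delta)
        called = (d >= cut_up) | (d <= cut_low)
        k = int(np.searchsorted(grid, delta, side="right") - 1)
        call_fdr = float(fdr[k]) if called.any() else 0.0
    else:
        ok = np.where((fdr <= params.fdr_target) & (n_called > 0))[0]
        if ok.size:
            best = ok[np.argmax(n_called[ok])]
            delta = float(grid[best])
            cut_up, cut_low = cut_ups[best], cut_lows[best]
            call_fdr = float(fdr[best])
        else:
            delta = float(grid[-1] + 1.0)
            cut_up, cut_low = np.inf, -np.inf
            call_fdr = 0.0
        called = (d >= cut_up) | (d <= cut_low)

    ratio = 2.0 ** r  # log2 data: difference of means is the log2 ratio
    signed = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    table = pd.DataFrame(
        {
            f"mean_{class_a}": mean_a,
            f"mean_{class_b}": mean_b,
            "d": d,
            "ratio_fc": ratio,
            "signed_fc": signed,
            "q_value_pct": q * 100.0,
            "significant": called,
        },
        index=log2_values.index,
    )
    return SamResult(
        table=table,
        delta=delta,
        fdr=call_fdr,
        s0=s0,
        pi0=pi0,
        n_permutations=masks.shape[0],
        exhaustive=exhaustive,
        cut_up=float(cut_up),
        cut_low=float(cut_low),
        classes=(class_a, class_b),
    )


# ---------------------------------------------------------------------------
# fold changes and aggregation


def fold_change(
    intensities: pd.DataFrame, labels: pd.Series, classes: tuple[str, str]
) -> pd.DataFrame:
    """Linear-scale ratio (classes[1] over classes[0]) and signed fold change.

    The signed convention maps a ratio below 1 to -1/ratio, so a ratio of
    0.25 reads as a 4-fold down-regulation (-4.0).
    """
    labels = pd.Series(labels, index=intensities.columns).astype(str)
    mean_a = intensities.loc[:, (labels == classes[0]).to_numpy()].mean(axis=1)
    mean_b = intensities.loc[:, (labels == classes[1]).to_numpy()].mean(axis=1)
    if (mean_a <= 0).any() or (mean_b <= 0).any():
        raise ValueError("group means must be positive on the linear scale")
    ratio = mean_b / mean_a
    signed = ratio.where(ratio >= 1.0, -1.0 / ratio)
    return pd.DataFrame({"ratio_fc": ratio, "signed_fc": signed})


def signed_fold_change(ratio: float) -> float:
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return ratio if ratio >= 1.0 else -1.0 / ratio


@dataclass
class TranscriptCalls:
    table: pd.DataFrame  # per-transcript category and per-probe detail
    counts: dict[str, int] = field(default_factory=dict)


def aggregate_to_transcripts(
    significant_probe_ids,
    platform_probe_ids,
    filtered_probe_ids=(),
) -> TranscriptCalls:
    """Collapse the significant probe list to unique transcripts.

    Each called transcript is categorized: ``both-probe`` (both platform
    probes significant), ``single-filtered`` (the second probe was removed by
    the missing-value filter), ``single-not-significant`` (the second probe
    was tested but not called), or ``single-on-platform`` (the transcript has
    a single probe). Counts reconcile: 2 x both + singles = significant
    probes.
    """
    platform: dict[str, set[str]] = {}
    for pid in platform_probe_ids:
        platform.setdefault(transcript_of(pid), set()).add(pid)
    filtered = set(filtered_probe_ids)
    sig = list(dict.fromkeys(significant_probe_ids))
    orphans = [pid for pid in sig if transcript_of(pid) not in platform]
    if orphans:
        raise KeyError(f"significant probes absent from the platform: {orphans}")
    by_transcript: dict[str, list[str]] = {}
    for pid in sig:
        by_transcript.setdefault(transcript_of(pid), []).append(pid)
    rows = []
    for tid, called in by_transcript.items():
        probes = platform[tid]
        if len(called) == len(probes) == 2:
            category = "both-probe"
        elif len(probes) == 1:
            category = "single-on-platform"
        else:
            other = next(iter(probes - set(called)))
            category = (
                "single-filtered" if other in filtered else "single-not-significant"
            )
        rows.append(
            {"transcript_id": tid, "n_significant_probes": len(called),
             "category": category, "probes": ",".join(sorted(called))}
        )
    table = pd.DataFrame(
        rows,
        columns=["transcript_id", "n_significant_probes", "category", "probes"],
    ).set_index("transcript_id")
    counts = table["category"].value_counts().to_dict()
    counts["n_transcripts"] = len(table)
    counts["n_significant_probes"] = len(sig)
    return TranscriptCalls(table=table, counts=counts)


# ---------------------------------------------------------------------------
# tissue-dilution model


def dilution_adjusted_fc(f: float, local_fc: float) -> float:
    """Whole-tissue fold change when regulation is confined to a subregion.

    A gene regulated ``local_fc``-fold in a region comprising fraction ``f``
    of the sampled tissue, and unchanged elsewhere, shows an observed
    whole-tissue fold change of ``f * local_fc + (1 - f)``. With f = 1/10
    and a 10-fold local change the observable effect is only 1.9-fold —
    the arithmetic behind profiling dissected tissue rather than whole heads.
    """
    if not 0 < f <= 1:
        raise ValueError("tissue fraction must lie in (0, 1]")
    if local_fc <= 0:
        raise ValueError("local fold change must be positive")
    return f * local_fc + (1.0 - f)
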