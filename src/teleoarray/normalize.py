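"""Normalization of one-color intensity matrices and array-level QC.

Normalization quality is scored by spike-in flatness: exogenous controls
spiked at fixed concentrations should be uniform across arrays after
normalization, so the mean coefficient of variation of the spike rows ranks
candidate methods (quantile, cyclic loess, median scaling, none). QC
surfaces cover flag-based hybridization success, probe-pair intensity
concordance, and replicate correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from teleoarray.dataset import ExpressionDataset, transcript_of

METHODS = ("quantile", "cyclic_loess", "median", "none")


# ---------------------------------------------------------------------------
# normalization methods


def quantile_normalize(frame: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of per-rank means.

    After normalization the sorted values of every column equal the mean of
    the sorted input columns; within-column ranks are preserved. Ties are
    assigned the mean of the rank means they jointly occupy, so all-constant
    columns are handled without failure.
    """
    if frame.shape[1] < 2:
        raise ValueError("quantile normalization needs at least two samples")
    values = frame.to_numpy(dtype=float)
    n = values.shape[0]
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        column = values[:, j]
        order = np.argsort(column, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = target
        # average the assigned values within each tie group
        series = pd.Series(assigned).groupby(pd.Series(column)).transform("mean")
        out[:, j] = series.to_numpy()
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)


def cyclic_loess_normalize(
    frame: pd.DataFrame, span: float = 0.4, cycles: int = 3
) -> pd.DataFrame:
    """Pairwise cyclic loess on the log2 scale (the comparator method).

    For every pair of arrays an M-vs-A loess trend is fitted and split evenly
    between the two columns; the sweep over all pairs is repeated ``cycles``
    times. Implemented for completeness as the method that spike-in flatness
    is expected to rank below quantile normalization on distorted arrays.
    """
    log2 = np.log2(frame.to_numpy(dtype=float))
    n_samples = log2.shape[1]
    for _ in range(cycles):
        for i in range(n_samples):
            for j in range(i + 1, n_samples):
                m = log2[:, i] - log2[:, j]
                a = 0.5 * (log2[:, i] + log2[:, j])
                trend = lowess(m, a, frac=span, return_sorted=False)
                log2[:, i] -= trend / 2.0
                log2[:, j] += trend / 2.0
    return pd.DataFrame(2.0 ** log2, index=frame.index, columns=frame.columns)


def median_scale(frame: pd.DataFrame) -> pd.DataFrame:
    """Scale each column so all column medians match the global mean median."""
    medians = frame.median(axis=0)
    return frame * (medians.mean() / medians)


def normalize(frame: pd.DataFrame, method: str) -> pd.DataFrame:
    if method == "quantile":
        return quantile_normalize(frame)
    if method == "cyclic_loess":
        return cyclic_loess_normalize(frame)
    if method == "median":
        return median_scale(frame)
    if method == "none":
        return frame.copy()
    raise ValueError(f"unknown normalization method {method!r}")


def normalize_dataset(dataset: ExpressionDataset, method: str) -> ExpressionDataset:
    return dataset.with_intensities(normalize(dataset.intensities, method))


# ---------------------------------------------------------------------------
# spike-in based method selection


def spike_flatness(frame: pd.DataFrame, spike_ids) -> float:
    """Mean CV of the spike-in rows across samples (lower is flatter)."""
    if frame.shape[1] < 2:
        raise ValueError("flatness is undefined on a single sample")
    spikes = frame.loc[list(spike_ids)]
    if spikes.empty:
        raise ValueError("no spike-in rows in the matrix")
    means = spikes.mean(axis=1)
    keep = means != 0
    spikes = spikes.loc[keep]
    if spikes.empty:
        raise ValueError("all spike rows have zero mean")
    cv = spikes.std(axis=1, ddof=1) / spikes.mean(axis=1)
    return float(cv.mean())


def select_normalization(
    dataset: ExpressionDataset, methods: tuple[str, ...] = METHODS
) -> tuple[str, dict[str, float]]:
    """Pick the method whose spike-in CV is smallest; ties keep listing order."""
    scores = {
        method: spike_flatness(
            normalize(dataset.intensities, method), dataset.spike_ids
        )
        for method in methods
    }
    best = min(methods, key=lambda m: scores[m])
    return best, scores


# ---------------------------------------------------------------------------
# QC surfaces


def hybridization_success(
    flags: pd.DataFrame, min_fraction: float = 0.5
) -> tuple[pd.Series, dict[str, float]]:
    """Per-probe detection counts over all experiments, plus a summary.

    A probe counts as "detected in at least half" when its flag-1 count is at
    least ``ceil(n_experiments * min_fraction)`` — the conservative reading
    for odd experiment counts.
    """
    counts = flags.sum(axis=1)
    n_experiments = flags.shape[1]
    threshold = math.ceil(n_experiments * min_fraction)
    n_at_least = int((counts >= threshold).sum())
    summary = {
        "n_experiments": n_experiments,
        "threshold": threshold,
        "n_never_detected": int((counts == 0).sum()),
        "n_detected_at_least_half": n_at_least,
        "fraction_detected_at_least_half": n_at_least / len(counts),
    }
    return counts, summary


@dataclass
class ProbePairConcordance:
    fold_change: pd.DataFrame  # transcripts x samples, max/min probe ratio, >= 1
    fraction_below_2: pd.Series  # per sample, strict inequality
    overall_fraction_below_2: float  # over all transcript x sample cells
    pearson: pd.Series  # per transcript, probe 1 vs probe 2 across samples


def probe_pair_map(probe_ids) -> dict[str, tuple[str, str]]:
    """Transcript -> (probe_1, probe_2) for transcripts with exactly two probes."""
    grouped: dict[str, list[str]] = {}
    for pid in probe_ids:
        grouped.setdefault(transcript_of(pid), []).append(pid)
    return {
        tid: tuple(sorted(pids)) for tid, pids in grouped.items() if len(pids) == 2
    }


def probe_pair_concordance(
    intensities: pd.DataFrame, probe_ids=None
) -> ProbePairConcordance:
    """Intensity agreement between the two probes of each transcript.

    The per-sample fold change is the symmetric ratio max(I1, I2)/min(I1, I2)
    on the normalized linear scale; single-probe transcripts are skipped.
    """
    probe_ids = intensities.index if probe_ids is None else probe_ids
    pairs = probe_pair_map(probe_ids)
    if not pairs:
        raise ValueError("no two-probe transcripts found")
    p1 = intensities.loc[[pair[0] for pair in pairs.values()]].to_numpy(float)
    p2 = intensities.loc[[pair[1] for pair in pairs.values()]].to_numpy(float)
    fc = np.maximum(p1, p2) / np.minimum(p1, p2)
    fold_change = pd.DataFrame(fc, index=list(pairs), columns=intensities.columns)
    fraction = (fold_change < 2.0).mean(axis=0)
    with np.errstate(invalid="ignore"):
        centered1 = p1 - p1.mean(axis=1, keepdims=True)
        centered2 = p2 - p2.mean(axis=1, keepdims=True)
        denom = np.sqrt((centered1 ** 2).sum(axis=1) * (centered2 ** 2).sum(axis=1))
        pearson = np.where(denom > 0, (centered1 * centered2).sum(axis=1) / denom, np.nan)
    return ProbePairConcordance(
        fold_change=fold_change,
        fraction_below_2=fraction,
        overall_fraction_below_2=float((fc < 2.0).mean()),
        pearson=pd.Series(pearson, index=list(pairs)),
    )


def replicate_correlation(
    intensities: pd.DataFrame, log_scale: bool = True
) -> pd.DataFrame:
    """Pairwise Pearson correlation over samples (log2 values by default).

    Constant samples yield NaN rows/columns; the matrix is symmetric with a
    unit diagonal elsewhere.
    """
    if intensities.shape[1] < 2:
        raise ValueError("need at least two samples")
    values = np.log2(intensities) if log_scale else intensities
    return values.corr(method="pearson")


# ---------------------------------------------------------------------------
# GEO series-matrix reader (for running the pipeline on archived series)


def read_series_matrix(path: str) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Parse a GEO series-matrix TSV into (values, metadata).

    Metadata lines (prefixed ``!``) are collected verbatim keyed by their
    label; the expression table between the table-begin/end markers becomes a
    probes x samples DataFrame indexed by ID_REF.
    """
    metadata: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                key, _, rest = line[1:].partition("\t")
                fields = [f.strip('"') for f in rest.split("\t")] if rest else []
                metadata.setdefault(key, []).extend(fields)
    if not table_lines:
        raise ValueError(f"{path}: no series-matrix table found")
    from io import StringIO

    frame = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    frame.index = frame.index.astype(str).str.strip('"')
    frame.columns = [c.strip('"') for c in frame.columns]
    return frame, metadata
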