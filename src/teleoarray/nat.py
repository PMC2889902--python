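"""Natural antisense transcript inference from hit-table strand signs.

Catalog transcripts are assumed to be sense strands; a transcript whose best
matches in reference transcriptomes consistently lie on the opposite strand
is a candidate natural antisense transcript (NAT). The strongest tier
requires a hit in all five reference species, always antisense. Separately,
two catalog entries best-matching the same reference transcript on opposite
strands form a sense/antisense pair whose probes allow comparing sense vs
antisense expression at the same (or a duplicated) locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from teleoarray.annotation import best_hits
from teleoarray.dataset import ExpressionDataset, transcript_of


@dataclass
class OrientationTiers:
    table: pd.DataFrame  # per-query class, per-species strands
    n_any_opposite: int  # >=1 species with an opposite-strand best hit
    n_antisense_consistent: int  # opposite in every species hit
    n_high_confidence: int  # hits all species, all opposite


def classify_orientation(
    hits: pd.DataFrame,
    species: tuple[str, ...],
    query_ids=None,
    best_hit_only: bool = True,
) -> OrientationTiers:
    """Classify each query's orientation against each reference species.

    ``hits`` needs columns (qseqid, species, sseqid, evalue, bitscore,
    strand_sign). With ``best_hit_only`` the per-species call uses the single
    best hit (min e-value, ties by bit score then subject id); otherwise all
    hits of a species must agree for that species to count as consistent.

    Classes: ``no-hit``, ``sense-consistent`` (every species' call is +1),
    ``antisense-consistent`` (every call is -1), ``discordant`` (mixed calls,
    including within-species disagreement in all-hits mode).
    """
    required = {"qseqid", "species", "evalue", "bitscore", "sseqid", "strand_sign"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table lacks columns: {sorted(missing)}")
    if query_ids is None:
        query_ids = sorted(hits["qseqid"].unique())

    calls: dict[str, dict[str, int]] = {qid: {} for qid in query_ids}
    for sp in species:
        sp_hits = hits[hits["species"] == sp]
        if sp_hits.empty:
            continue
        if best_hit_only:
            for _, row in best_hits(sp_hits).iterrows():
                if row["qseqid"] in calls:
                    calls[row["qseqid"]][sp] = int(row["strand_sign"])
        else:
            for qid, group in sp_hits.groupby("qseqid"):
                if qid not in calls:
                    continue
                strands = set(group["strand_sign"].astype(int))
                calls[qid][sp] = strands.pop() if len(strands) == 1 else 0  # 0 = mixed

    rows = []
    for qid in query_ids:
        per_species = calls[qid]
        strands = list(per_species.values())
        if not strands:
            cls = "no-hit"
        elif all(s == 1 for s in strands):
            cls = "sense-consistent"
        elif all(s == -1 for s in strands):
            cls = "antisense-consistent"
        else:
            cls = "discordant"
        high_conf = cls == "antisense-consistent" and len(strands) == len(species)
        row = {"qseqid": qid, "class": cls, "n_species_hit": len(strands),
               "high_confidence": high_conf}
        for sp in species:
            row[f"strand_{sp}"] = per_species.get(sp, 0)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("qseqid")
    n_any = int(
        sum(
            1
            for _, row in table.iterrows()
            if any(row[f"strand_{sp}"] == -1 for sp in species)
        )
    )
    return OrientationTiers(
        table=table,
        n_any_opposite=n_any,
        n_antisense_consistent=int((table["class"] == "antisense-consistent").sum()),
        n_high_confidence=int(table["high_confidence"].sum()),
    )


@dataclass
class SenseAntisensePair:
    sense_id: str
    antisense_id: str
    subject_id: str


def pair_sense_antisense(hits: pd.DataFrame) -> list[SenseAntisensePair]:
    """Pairs of queries best-hitting the same subject on opposite strands.

    Each query is assigned to its single best subject (min e-value, ties by
    bit score then subject id), so no query appears in more than one pair.
    For a subject matched on both strands, the best plus-strand and best
    minus-strand queries form the pair. Deterministic under row permutation.
    """
    if hits.empty:
        return []
    assigned = best_hits(hits)  # one subject per query
    pairs = []
    for subject, group in assigned.groupby("sseqid"):
        plus = group[group["strand_sign"] == 1]
        minus = group[group["strand_sign"] == -1]
        if plus.empty or minus.empty:
            continue
        best_plus = best_hits(plus.assign(_key=0), by="_key").iloc[0]
        best_minus = best_hits(minus.assign(_key=0), by="_key").iloc[0]
        pairs.append(
            SenseAntisensePair(
                sense_id=str(best_plus["qseqid"]),
                antisense_id=str(best_minus["qseqid"]),
                subject_id=str(subject),
            )
        )
    pairs.sort(key=lambda p: p.subject_id)
    return pairs


def compare_pair_expression(
    pairs: list[SenseAntisensePair],
    dataset: ExpressionDataset,
    stage=None,
    max_missing_fraction: float = 0.5,
) -> pd.DataFrame:
    """Sense/antisense expression ratio per pair, with missing-data filtering.

    A pair member is excluded when its probes are flag-missing in at least
    ``max_missing_fraction`` of the stage's experiments; pairs with an
    excluded member are dropped (status recorded). Expression of a member is
    the mean of its probes' normalized intensities over the stage's samples.
    Returns one row per pair with columns (sense_id, antisense_id, status,
    sense_mean, antisense_mean, ratio, sense_dominant).
    """
    samples = dataset.stage_samples(stage) if stage is not None else list(dataset.sample_ids)
    if not samples:
        raise ValueError(f"no samples for stage {stage!r}")
    probes_by_transcript: dict[str, list[str]] = {}
    for pid in dataset.probe_ids:
        probes_by_transcript.setdefault(transcript_of(pid), []).append(pid)

    def member_stats(tid: str) -> tuple[float, float] | None:
        probes = probes_by_transcript.get(tid)
        if not probes:
            return None
        flags = dataset.flags.loc[probes, samples].to_numpy()
        missing_fraction = float((flags == 0).mean())
        mean = float(dataset.intensities.loc[probes, samples].to_numpy().mean())
        return missing_fraction, mean

    rows = []
    for pair in pairs:
        sense = member_stats(pair.sense_id)
        anti = member_stats(pair.antisense_id)
        status = "ok"
        if sense is None or anti is None:
            status = "no-probes"
        elif sense[0] >= max_missing_fraction or anti[0] >= max_missing_fraction:
            status = "filtered-missing"
        row = {
            "sense_id": pair.sense_id,
            "antisense_id": pair.antisense_id,
            "subject_id": pair.subject_id,
            "status": status,
            "sense_mean": sense[1] if sense else np.nan,
            "antisense_mean": anti[1] if anti else np.nan,
        }
        if status == "ok":
            row["ratio"] = row["sense_mean"] / row["antisense_mean"]
            row["sense_dominant"] = row["ratio"] > 1.0
        else:
            row["ratio"] = np.nan
            row["sense_dominant"] = pd.NA
        rows.append(row)
    return pd.DataFrame(rows)


def sense_dominant_fraction(comparison: pd.DataFrame) -> float:
    """Fraction of retained pairs where the sense member is more expressed."""
    kept = comparison[comparison["status"] == "ok"]
    if kept.empty:
        raise ValueError("no pairs survived filtering")
    return float(kept["sense_dominant"].mean())
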