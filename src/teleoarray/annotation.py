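"""Homology-hit joining, annotation status, GO-slim rollups, id mapping.

Hit tables are standard 12-column BLAST tabular files; a strand sign is
derived from subject coordinate order (nucleotide searches) or from the
query frame sign when a ``qframe`` column is present (translated searches).
A transcript is *protein-annotated* when any protein-database hit beats the
protein e-value cutoff, otherwise *nucleotide-only* when any nucleotide hit
beats the (stricter) nucleotide cutoff, otherwise *unannotated*. Both
cutoffs are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

PROTEIN_CUTOFF = 1e-3
NUCLEOTIDE_CUTOFF = 1e-5

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

ROUTES = (
    "direct-human",
    "via-stickleback-human",
    "direct-zebrafish",
    "via-stickleback-zebrafish",
)


def read_blast_tabular(path: str, db: str | None = None) -> pd.DataFrame:
    """Read an outfmt-6-style hit table, attach the strand sign and db tag.

    A 13th column, when present, is interpreted as the query frame
    (``qframe``) and its sign takes precedence for the strand call.
    Malformed rows raise with the offending line number.
    """
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected >=12 columns, got {len(fields)}")
            try:
                row = dict(zip(BLAST_COLUMNS, fields))
                for col in ("pident", "evalue", "bitscore"):
                    row[col] = float(row[col])
                for col in ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"):
                    row[col] = int(row[col])
                if len(fields) > 12:
                    row["qframe"] = int(fields[12])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
            rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty:
        frame = pd.DataFrame(columns=BLAST_COLUMNS)
    frame = add_strand_sign(frame)
    if db is not None:
        frame["db"] = db
    return frame


def add_strand_sign(hits: pd.DataFrame) -> pd.DataFrame:
    """Attach ``strand_sign`` (+1/-1) from coordinates or the frame sign."""
    hits = hits.copy()
    if hits.empty:
        hits["strand_sign"] = pd.Series(dtype=int)
        return hits
    reversed_subject = hits["sstart"] > hits["send"]
    reversed_query = hits["qstart"] > hits["qend"]
    sign = pd.Series(1, index=hits.index)
    sign[reversed_subject ^ reversed_query] = -1
    if "qframe" in hits.columns:
        framed = hits["qframe"].notna()
        sign[framed] = hits.loc[framed, "qframe"].apply(lambda f: -1 if f < 0 else 1)
    hits["strand_sign"] = sign
    return hits


def best_hits(hits: pd.DataFrame, by: str = "qseqid") -> pd.DataFrame:
    """One best hit per group: min e-value, then max bit score, then subject id.

    Deterministic under any row order of the input.
    """
    if hits.empty:
        return hits
    ranked = hits.sort_values(
        by=[by, "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return ranked.drop_duplicates(subset=[by], keep="first")


# ---------------------------------------------------------------------------
# annotation status


@dataclass
class AnnotationRecord:
    transcript_id: str
    status: str  # protein-annotated | nucleotide-only | unannotated
    best_protein_hit: str | None = None
    best_protein_evalue: float | None = None
    best_nucleotide_hit: str | None = None
    best_nucleotide_evalue: float | None = None


def assign_annotation(
    hits: pd.DataFrame,
    transcript_ids,
    protein_dbs: tuple[str, ...] = ("nr", "SwissProt", "TrEMBL"),
    protein_cutoff: float = PROTEIN_CUTOFF,
    nucleotide_cutoff: float = NUCLEOTIDE_CUTOFF,
) -> pd.DataFrame:
    """Annotation status per transcript from a tagged, concatenated hit table.

    ``hits`` must carry a ``db`` column; databases listed in ``protein_dbs``
    are treated as protein searches (cutoff e < 1e-3 by default), all others
    as nucleotide searches (e < 1e-5). Returns one row per transcript.
    """
    if "db" not in hits.columns and not hits.empty:
        raise ValueError("hit table must carry a 'db' column")
    records = []
    protein = hits[hits["db"].isin(protein_dbs)] if not hits.empty else hits
    nucleotide = hits[~hits["db"].isin(protein_dbs)] if not hits.empty else hits
    best_prot = best_hits(protein[protein["evalue"] < protein_cutoff]) if not protein.empty else protein
    best_nuc = (
        best_hits(nucleotide[nucleotide["evalue"] < nucleotide_cutoff])
        if not nucleotide.empty
        else nucleotide
    )
    prot_map = best_prot.set_index("qseqid") if not best_prot.empty else None
    nuc_map = best_nuc.set_index("qseqid") if not best_nuc.empty else None
    for tid in transcript_ids:
        rec = AnnotationRecord(transcript_id=tid, status="unannotated")
        if prot_map is not None and tid in prot_map.index:
            rec.status = "protein-annotated"
            rec.best_protein_hit = prot_map.loc[tid, "sseqid"]
            rec.best_protein_evalue = float(prot_map.loc[tid, "evalue"])
        if nuc_map is not None and tid in nuc_map.index:
            if rec.status == "unannotated":
                rec.status = "nucleotide-only"
            rec.best_nucleotide_hit = nuc_map.loc[tid, "sseqid"]
            rec.best_nucleotide_evalue = float(nuc_map.loc[tid, "evalue"])
        records.append(rec)
    return pd.DataFrame([vars(r) for r in records]).set_index("transcript_id")


def venn_counts(
    hits: pd.DataFrame,
    dbs: tuple[str, ...] = ("nr", "SwissProt", "TrEMBL"),
    cutoff: float = PROTEIN_CUTOFF,
) -> dict[frozenset, int]:
    """Exclusive region counts of the db-membership Venn diagram."""
    membership: dict[str, set[str]] = {}
    if not hits.empty:
        significant = hits[(hits["evalue"] < cutoff) & hits["db"].isin(dbs)]
        for qid, group in significant.groupby("qseqid"):
            membership[qid] = set(group["db"])
    counts: dict[frozenset, int] = {}
    for r in range(1, len(dbs) + 1):
        for combo in combinations(dbs, r):
            region = frozenset(combo)
            counts[region] = sum(1 for dbset in membership.values() if dbset == region)
    return counts


# ---------------------------------------------------------------------------
# GO slim rollup


def rollup_go_slim(
    go_annotations: pd.DataFrame,
    slim_map: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Summarize full GO annotations into slim classes per namespace.

    ``go_annotations`` has columns (transcript_id, term); ``slim_map`` maps
    term -> slim class with columns (term, slim, namespace) and may be
    many-to-many. Returns a per-(namespace, slim) table with the number of
    distinct annotated transcripts and total term mappings, plus the list of
    terms absent from the slim map (counted as unmapped).
    """
    for col in ("transcript_id", "term"):
        if col not in go_annotations.columns:
            raise ValueError(f"go_annotations must have a {col!r} column")
    for col in ("term", "slim", "namespace"):
        if col not in slim_map.columns:
            raise ValueError(f"slim_map must have a {col!r} column")
    merged = go_annotations.merge(slim_map, on="term", how="left")
    unmapped = sorted(merged.loc[merged["slim"].isna(), "term"].unique())
    mapped = merged.dropna(subset=["slim"])
    if mapped.empty:
        table = pd.DataFrame(columns=["namespace", "slim", "n_transcripts", "n_terms"])
    else:
        table = (
            mapped.groupby(["namespace", "slim"])
            .agg(
                n_transcripts=("transcript_id", "nunique"),
                n_terms=("term", "count"),
            )
            .reset_index()
        )
    return table, unmapped


def slim_class_counts(table: pd.DataFrame) -> dict[str, int]:
    """Number of distinct slim classes per namespace from a rollup table."""
    if table.empty:
        return {}
    return table.groupby("namespace")["slim"].nunique().to_dict()


# ---------------------------------------------------------------------------
# model-organism id mapping


def map_to_model_ids(
    route: str,
    direct_hits: pd.DataFrame | None = None,
    to_intermediate: pd.DataFrame | None = None,
    intermediate_to_target: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Best-hit id mapping via one of four routes.

    Direct routes take the best hit of each transcript against the target
    species; indirect routes compose the best hit against the intermediate
    (stickleback) with that subject's best hit against the target. Returns
    columns (transcript_id, route, model_id); use
    :func:`unique_model_ids` for the deduplicated count alongside the raw one.
    """
    if route not in ROUTES:
        raise ValueError(f"route must be one of {ROUTES}")
    if route.startswith("direct"):
        if direct_hits is None:
            raise ValueError(f"route {route!r} needs the direct hit table")
        best = best_hits(direct_hits)
        frame = best[["qseqid", "sseqid"]].rename(
            columns={"qseqid": "transcript_id", "sseqid": "model_id"}
        )
    else:
        if to_intermediate is None or intermediate_to_target is None:
            raise ValueError(f"route {route!r} needs both intermediate hit tables")
        first = best_hits(to_intermediate)[["qseqid", "sseqid"]]
        second = best_hits(intermediate_to_target)[["qseqid", "sseqid"]].rename(
            columns={"qseqid": "sseqid", "sseqid": "model_id"}
        )
        frame = first.merge(second, on="sseqid")[["qseqid", "model_id"]].rename(
            columns={"qseqid": "transcript_id"}
        )
    frame = frame.copy()
    frame["route"] = route
    return frame.reset_index(drop=True)[["transcript_id", "route", "model_id"]]


def unique_model_ids(mapping: pd.DataFrame) -> tuple[int, int]:
    """(raw mapped transcripts, unique model ids) for one route's mapping."""
    return int(mapping["transcript_id"].nunique()), int(mapping["model_id"].nunique())
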