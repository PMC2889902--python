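"""EST clustering into unique transcripts.

ESTs and mRNAs are grouped with single-linkage clustering: two sequences
belong to the same cluster when their best end-free (overlap) alignment
covers at least ``min_overlap`` bases at an identity of at least
``min_identity``. Candidate pairs are pre-screened by exact shared k-mers
(a deterministic stand-in for a BLAST screen), and a consensus per cluster
is built by majority vote over a pairwise-overlap layout — a deliberately
simple substitute for a full OLC assembler, adequate at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Seq, SeqIO
from Bio.Align import PairwiseAligner

DEFAULT_MIN_OVERLAP = 40
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_K = 16

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class EstSequence:
    """A single EST or mRNA read (assumed 5'-sequenced, orientation fallible)."""

    id: str
    seq: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        seq = self.seq.upper()
        if set(seq) - _ALPHABET:
            raise ValueError(f"{self.id}: alphabet must be ACGTN")
        object.__setattr__(self, "seq", seq)


@dataclass(frozen=True)
class OverlapResult:
    accept: bool
    overlap_len: int
    identity: float
    orientation: int  # +1 forward/forward, -1 forward/revcomp


@dataclass
class ClusterResult:
    cluster_id: str
    member_ids: list[str]
    consensus: str
    # (id_a, id_b, overlap_len, identity) for each accepted pair
    overlaps: list[tuple[str, str, int, float]] = field(default_factory=list)


def revcomp(seq: str) -> str:
    return str(Seq.Seq(seq).reverse_complement())


def read_fasta(path: str) -> list[EstSequence]:
    return [EstSequence(id=rec.id, seq=str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


# ---------------------------------------------------------------------------
# candidate screening


def _kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            yield kmer


def find_candidate_pairs(
    seqs: list[EstSequence], k: int = DEFAULT_K
) -> list[tuple[str, str]]:
    """All unordered pairs sharing an exact k-mer in either orientation.

    A superset of every pair that can pass :func:`overlap_check` with
    ``min_overlap >= k``, since any accepted overlap of that length at 90%+
    identity need not contain an exact k-mer in pathological cases — which is
    why the screen is only applied with ``k`` well below ``min_overlap`` when
    identities below 1.0 matter. With the defaults (k=16, min_overlap=40) a
    40 bp overlap at >=90% identity has at most 4 mismatches, leaving a
    mismatch-free stretch of at least 8 bp; callers needing a strict superset
    guarantee at high divergence should lower ``k``.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    index: dict[str, set[str]] = {}
    for est in seqs:
        seen = set(_kmers(est.seq, k)) | set(_kmers(revcomp(est.seq), k))
        for kmer in seen:
            index.setdefault(kmer, set()).add(est.id)
    pairs: set[tuple[str, str]] = set()
    for ids in index.values():
        members = sorted(ids)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                pairs.add((a, b))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# overlap alignment


def _overlap_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    # free end gaps turn the global alignment into an overlap alignment
    aligner.end_gap_score = 0.0
    return aligner


def _overlap_stats(row_a: str, row_b: str) -> tuple[int, int]:
    """(overlap columns, matched columns) of a gapped alignment pair.

    The overlap region runs from the first column where both sequences have
    started to the last column before either trails off; internal gaps count
    toward the column total but never as matches.
    """
    both = [i for i in range(len(row_a)) if row_a[i] != "-" and row_b[i] != "-"]
    if not both:
        return 0, 0
    start, end = both[0], both[-1] + 1
    columns = end - start
    matches = sum(
        1 for i in range(start, end) if row_a[i] == row_b[i] and row_a[i] != "-"
    )
    return columns, matches


def _best_overlap(a: str, b: str) -> tuple[float, int, int, int]:
    """Best-scoring overlap alignment of ``a`` vs ``b`` in either orientation.

    Returns (score, orientation, overlap columns, matched columns); ties in
    score prefer the forward orientation.
    """
    aligner = _overlap_aligner()
    best = None
    for orientation, b_seq in ((1, b), (-1, revcomp(b))):
        alignment = aligner.align(a, b_seq)[0]
        if best is None or alignment.score > best[0]:
            best = (alignment.score, orientation, alignment[0], alignment[1])
    score, orientation, row_a, row_b = best
    columns, matches = _overlap_stats(row_a, row_b)
    return score, orientation, columns, matches


def overlap_check(
    a: EstSequence,
    b: EstSequence,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> OverlapResult:
    """Accept a pair iff its best overlap alignment meets both thresholds.

    Both thresholds are inclusive; identity is matches over aligned columns
    of the overlap region, internal gaps included in the denominator. Both
    orientations of ``b`` are tried and the higher-scoring one judged.
    """
    score, orientation, columns, matches = _best_overlap(a.seq, b.seq)
    identity = matches / columns if columns else 0.0
    accept = columns >= min_overlap and identity >= min_identity
    return OverlapResult(accept, columns, identity, orientation)


# ---------------------------------------------------------------------------
# clustering and consensus


class _UnionFind:
    def __init__(self, items):
        self.parent = {item: item for item in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _merge_into_layout(columns: list[dict[str, int]], order: list[list[str]], member: str,
                       consensus: str) -> tuple[list[dict[str, int]], list[list[str]]]:
    """Align one member against the current consensus and vote it into the layout."""
    aligner = _overlap_aligner()
    best = None
    for cand in (member, revcomp(member)):
        alignment = aligner.align(consensus, cand)[0]
        if best is None or alignment.score > best.score:
            best = alignment
    row_c, row_m = best[0], best[1]
    new_columns: list[dict[str, int]] = []
    new_order: list[list[str]] = []
    ci = 0  # index into existing columns
    for col in range(len(row_c)):
        base_c, base_m = row_c[col], row_m[col]
        if base_c != "-":
            counts, seen = columns[ci], order[ci]
            ci += 1
        else:
            counts, seen = {}, []
        if base_m != "-":
            counts[base_m] = counts.get(base_m, 0) + 1
            if base_m not in seen:
                seen.append(base_m)
        new_columns.append(counts)
        new_order.append(seen)
    return new_columns, new_order


def _call_consensus(columns: list[dict[str, int]], order: list[list[str]]) -> str:
    out = []
    for counts, seen in zip(columns, order):
        if not counts:
            continue
        best = max(seen, key=lambda base: counts[base])  # tie -> first seen
        out.append(best)
    return "".join(out)


def cluster(
    seqs: list[EstSequence],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    k: int = DEFAULT_K,
) -> list[ClusterResult]:
    """Single-linkage clustering under the overlap acceptance rule.

    Returns one :class:`ClusterResult` per cluster; singletons pass through
    with their own sequence as consensus. Clusters are numbered in order of
    their first member's appearance in the input.
    """
    by_id = {est.id: est for est in seqs}
    if len(by_id) != len(seqs):
        raise ValueError("duplicate sequence ids")
    uf = _UnionFind(by_id)
    evidence: dict[str, list[tuple[str, str, int, float]]] = {}
    for id_a, id_b in find_candidate_pairs(seqs, k=k):
        result = overlap_check(by_id[id_a], by_id[id_b], min_overlap, min_identity)
        if result.accept:
            uf.union(id_a, id_b)
            evidence.setdefault(id_a, []).append(
                (id_a, id_b, result.overlap_len, result.identity)
            )
    groups: dict[str, list[str]] = {}
    for est in seqs:  # input order
        groups.setdefault(uf.find(est.id), []).append(est.id)
    results = []
    for number, members in enumerate(groups.values(), start=1):
        member_seqs = sorted((by_id[m].seq for m in members), key=len, reverse=True)
        backbone = member_seqs[0]
        columns = [{base: 1} for base in backbone]
        order = [[base] for base in backbone]
        for seq in member_seqs[1:]:
            consensus = _call_consensus(columns, order)
            columns, order = _merge_into_layout(columns, order, seq, consensus)
        consensus = _call_consensus(columns, order)
        overlaps = [pair for m in members for pair in evidence.get(m, [])]
        results.append(
            ClusterResult(
                cluster_id=f"CL{number:05d}",
                member_ids=members,
                consensus=consensus,
                overlaps=overlaps,
            )
        )
    return results


def write_clusters(results: list[ClusterResult], table_path: str, fasta_path: str) -> None:
    with open(table_path, "w") as handle:
        handle.write("cluster_id\tmember_id\n")
        for res in results:
            for member in res.member_ids:
                handle.write(f"{res.cluster_id}\t{member}\n")
    with open(fasta_path, "w") as handle:
        for res in results:
            handle.write(f">{res.cluster_id}\n{res.consensus}\n")
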