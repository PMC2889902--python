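"""Dual 60-mer probe selection, as near as possible to the transcript 3' end.

Each unique transcript (assumed to be the sense strand) receives up to two
non-overlapping 60-mer probes, indexed ``_1`` (the more 3'-proximal window)
and ``_2``. Candidate windows are screened on composition — GC content,
homopolymer runs, ambiguous bases — and on a cross-hybridization penalty
counting 15-mers shared with any other transcript in the catalog. All
thresholds are package-level substitutes for a vendor's proprietary probe
scorer and are exposed as parameters; the contract itself (two disjoint
3'-proximal 60-mers per transcript) is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

PROBE_LENGTH = 60
CROSS_HYB_K = 15


@dataclass(frozen=True)
class TranscriptRecord:
    """A unique assembled transcript on its assumed sense strand."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProbeRecord:
    """One 60-mer probe; ``start`` is 0-based on the window [start, start+60)."""

    probe_id: str
    transcript_id: str
    start: int
    seq: str
    gc: float
    cross_hyb: int

    @property
    def end(self) -> int:
        return self.start + PROBE_LENGTH


@dataclass
class DesignParameters:
    gc_min: float = 0.35
    gc_max: float = 0.60
    max_homopolymer: int = 7  # runs of 8+ identical bases are rejected
    max_cross_hyb: int = 0  # shared 15-mers tolerated with other transcripts
    polya_min_run: int = 10  # 3'-terminal A-runs at least this long are masked


@dataclass
class Window:
    start: int
    seq: str
    gc: float
    cross_hyb: int
    passes: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


class NoProbeError(ValueError):
    """Raised when a transcript is too short to carry a single probe."""


def read_transcripts(path: str) -> list[TranscriptRecord]:
    return [TranscriptRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def mask_polya(seq: str, min_run: int = 10) -> str:
    """Trim a 3'-terminal poly-A run of at least ``min_run`` bases."""
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    return seq[:i] if n - i >= min_run else seq


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def build_kmer_index(
    transcripts: list[TranscriptRecord], k: int = CROSS_HYB_K
) -> dict[str, set[str]]:
    """k-mer -> set of transcript ids containing it (forward strand only)."""
    index: dict[str, set[str]] = {}
    for t in transcripts:
        for i in range(len(t.seq) - k + 1):
            index.setdefault(t.seq[i : i + k], set()).add(t.id)
    return index


def cross_hyb_penalty(
    window_seq: str, transcript_id: str, kmer_index: dict[str, set[str]], k: int = CROSS_HYB_K
) -> int:
    """Number of k-mers in the window occurring in any *other* transcript."""
    penalty = 0
    for i in range(len(window_seq) - k + 1):
        owners = kmer_index.get(window_seq[i : i + k], set())
        if owners - {transcript_id}:
            penalty += 1
    return penalty


def enumerate_windows(
    transcript: TranscriptRecord,
    kmer_index: dict[str, set[str]] | None = None,
    params: DesignParameters | None = None,
) -> list[Window]:
    """All 60-nt windows of the (poly-A-masked) transcript, scored and filtered.

    Windows are returned 5'->3' by start coordinate; ``passes`` reflects the
    composition filters and the cross-hybridization cap.
    """
    params = params or DesignParameters()
    seq = mask_polya(transcript.seq, params.polya_min_run)
    if len(seq) < PROBE_LENGTH:
        raise NoProbeError(
            f"{transcript.id}: {len(seq)} nt after masking, below probe length"
        )
    n = len(seq)
    # prefix sums let every window be screened in O(1)
    gc_prefix = [0]
    n_prefix = [0]
    run_end_prefix = [0]  # positions ending a homopolymer longer than the cap
    run = 1
    for i, base in enumerate(seq):
        gc_prefix.append(gc_prefix[-1] + (base in "GC"))
        n_prefix.append(n_prefix[-1] + (base == "N"))
        if i > 0 and base == seq[i - 1]:
            run += 1
        else:
            run = 1
        run_end_prefix.append(run_end_prefix[-1] + (run > params.max_homopolymer))
    shared_prefix = [0]
    if kmer_index is not None:
        for i in range(n - CROSS_HYB_K + 1):
            owners = kmer_index.get(seq[i : i + CROSS_HYB_K], set())
            hit = 1 if owners - {transcript.id} else 0
            shared_prefix.append(shared_prefix[-1] + hit)
    windows = []
    kmers_per_window = PROBE_LENGTH - CROSS_HYB_K + 1
    cap = params.max_homopolymer
    for start in range(n - PROBE_LENGTH + 1):
        end = start + PROBE_LENGTH
        gc = (gc_prefix[end] - gc_prefix[start]) / PROBE_LENGTH
        penalty = (
            shared_prefix[start + kmers_per_window] - shared_prefix[start]
            if kmer_index is not None
            else 0
        )
        reasons = []
        if n_prefix[end] - n_prefix[start]:
            reasons.append("ambiguous-base")
        if not params.gc_min <= gc <= params.gc_max:
            reasons.append("gc")
        # a run of cap+1 bases fits the window iff it ends in [start+cap, end)
        if run_end_prefix[end] - run_end_prefix[min(start + cap, n)]:
            reasons.append("homopolymer")
        if penalty > params.max_cross_hyb:
            reasons.append("cross-hyb")
        windows.append(
            Window(
                start,
                seq[start:end],
                gc,
                penalty,
                passes=not reasons,
                reasons=tuple(reasons),
            )
        )
    return windows


def select_probe_pair(
    transcript: TranscriptRecord,
    kmer_index: dict[str, set[str]] | None = None,
    params: DesignParameters | None = None,
) -> tuple[ProbeRecord, ...]:
    """The two most 3'-proximal disjoint passing windows, as probes.

    ``_1`` is the more 3'-proximal probe. Transcripts supporting only one
    passing window yield a single probe; transcripts with none yield an
    empty tuple. Deterministic for a fixed catalog.
    """
    try:
        windows = enumerate_windows(transcript, kmer_index, params)
    except NoProbeError:
        return ()
    passing = [w for w in windows if w.passes]
    if not passing:
        return ()
    by_3prime = sorted(passing, key=lambda w: w.start, reverse=True)
    first = by_3prime[0]
    second = next(
        (w for w in by_3prime[1:] if w.start + PROBE_LENGTH <= first.start), None
    )
    probes = [
        ProbeRecord(
            probe_id=f"{transcript.id}_1",
            transcript_id=transcript.id,
            start=first.start,
            seq=first.seq,
            gc=first.gc,
            cross_hyb=first.cross_hyb,
        )
    ]
    if second is not None:
        probes.append(
            ProbeRecord(
                probe_id=f"{transcript.id}_2",
                transcript_id=transcript.id,
                start=second.start,
                seq=second.seq,
                gc=second.gc,
                cross_hyb=second.cross_hyb,
            )
        )
    return tuple(probes)


def design_probes(
    transcripts: list[TranscriptRecord], params: DesignParameters | None = None
) -> tuple[list[ProbeRecord], list[str]]:
    """Design probes for a whole catalog.

    Returns the probe list and the ids of transcripts for which no probe
    could be designed.
    """
    index = build_kmer_index(transcripts)
    probes: list[ProbeRecord] = []
    failed: list[str] = []
    for t in transcripts:
        pair = select_probe_pair(t, index, params)
        if pair:
            probes.extend(pair)
        else:
            failed.append(t.id)
    return probes, failed


def probes_to_frame(probes: list[ProbeRecord]) -> pd.DataFrame:
    """Platform-table layout: one row per probe."""
    return pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in probes],
            "transcript_id": [p.transcript_id for p in probes],
            "start": [p.start for p in probes],
            "seq": [p.seq for p in probes],
            "gc": [p.gc for p in probes],
            "cross_hyb": [p.cross_hyb for p in probes],
        }
    ).set_index("probe_id")


def write_probes(probes: list[ProbeRecord], path: str) -> None:
    probes_to_frame(probes).to_csv(path, sep="\t")
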