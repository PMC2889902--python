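"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the structure of a two-condition, one-color oligo
microarray study of a jaw deformity in juvenile fish: a catalog of unique
transcripts with planted sense/antisense pairs, two 60-mer probes per
transcript, log-normal intensities with per-array affine distortions on the
log scale, ten spike-in controls at fixed concentrations, binary detection
flags with controllable missingness, replicate pools for a normal and a
deformed condition with a planted down-regulated gene set, strand-annotated
homology-hit tables against five reference transcriptomes, and qPCR
crossing-point tables consistent with the planted fold changes.

Everything is driven by a single integer seed: identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from teleoarray.clustering import EstSequence, revcomp
from teleoarray.dataset import ExpressionDataset, transcript_of
from teleoarray.probes import ProbeRecord, TranscriptRecord

FIVE_SPECIES = ("gasAcu", "oryLat", "danRer", "tetNig", "takRub")
REFERENCE_SPECIES = "gasAcu"  # closest reference; sense/antisense pairing uses it

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic catalog and expression matrix.

    Defaults mirror a two-condition design with four replicate pools per
    condition (the deformed-vs-normal contrast at the later stage), planted
    down-regulation spanning the fold-change range seen on real arrays
    (|log2 FC| from ~0.16 to ~3.97), and ten spike-in species.
    """

    seed: int = 0
    n_transcripts: int = 300
    n_antisense_pairs: int = 10
    n_spikeins: int = 10
    conditions: tuple[tuple[str, int], ...] = (("normal", 4), ("deformed", 4))
    stage: int = 58
    n_de_genes: int = 25
    de_log2fc_range: tuple[float, float] = (0.16, 3.97)
    intensity_location: float = 8.0  # mean of per-transcript log2 abundance
    intensity_scale: float = 1.5  # sd of per-transcript log2 abundance
    probe_offset_sd: float = 0.3  # per-probe affinity offset, log2
    probe_noise_sd: float = 0.25  # per-spot noise, log2
    spike_noise_sd: float = 0.05
    flag_missingness_rate: float = 0.02
    array_distortion: float = 0.0  # strength of per-array affine log2 distortion
    detection_floor_log2: float = 2.0
    transcript_length_range: tuple[int, int] = (200, 3000)

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        if self.n_de_genes > self.n_transcripts:
            raise ValueError("n_de_genes cannot exceed n_transcripts")
        if 2 * self.n_antisense_pairs > self.n_transcripts:
            raise ValueError("antisense pairs need two transcripts each")
        if not 0 <= self.flag_missingness_rate <= 1:
            raise ValueError("flag_missingness_rate must lie in [0, 1]")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are supported")
        lo, hi = self.de_log2fc_range
        if not 0 <= lo <= hi:
            raise ValueError("de_log2fc_range must be a nonnegative interval")
        lo, hi = self.transcript_length_range
        if lo < 200:
            raise ValueError("transcripts shorter than 200 nt are not simulated")


@dataclass
class GroundTruth:
    """Planted truth cross-referencing only ids present in the emitted catalog."""

    de_log2fc: dict[str, float] = field(default_factory=dict)  # negative = down
    antisense_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    # (sense_id, antisense_id, shared subject id in the reference species)
    est_clusters: dict[str, str] = field(default_factory=dict)  # est id -> transcript
    qpcr_efficiencies: dict[str, float] = field(default_factory=dict)

    def write(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        pd.DataFrame(
            {"transcript_id": list(self.de_log2fc), "log2fc": list(self.de_log2fc.values())}
        ).to_csv(os.path.join(directory, "truth_de.tsv"), sep="\t", index=False)
        pd.DataFrame(
            self.antisense_pairs, columns=["sense_id", "antisense_id", "subject_id"]
        ).to_csv(os.path.join(directory, "truth_antisense.tsv"), sep="\t", index=False)
        pd.DataFrame(
            {"est_id": list(self.est_clusters), "transcript_id": list(self.est_clusters.values())}
        ).to_csv(os.path.join(directory, "truth_est_clusters.tsv"), sep="\t", index=False)
        pd.DataFrame(
            {"gene": list(self.qpcr_efficiencies), "efficiency": list(self.qpcr_efficiencies.values())}
        ).to_csv(os.path.join(directory, "truth_qpcr_efficiency.tsv"), sep="\t", index=False)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic stream per generator stage
    return np.random.default_rng([config.seed, stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# transcript catalog


def simulate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[TranscriptRecord], GroundTruth]:
    """Emit the transcript catalog and its planted ground truth.

    For each planted antisense pair, two catalog entries derive from a shared
    reference-species locus: the sense member copies a subregion on the plus
    strand and the antisense member is the reverse complement of another
    (partially overlapping) subregion, so downstream hit tables show the two
    entries matching the same subject on opposite strands.
    """
    rng = _rng(config, stream=1)
    truth = GroundTruth()
    lo, hi = config.transcript_length_range
    transcripts: list[TranscriptRecord] = []

    ids = [f"TX{i:05d}" for i in range(1, config.n_transcripts + 1)]
    pair_slots = list(range(0, 2 * config.n_antisense_pairs, 2))
    for slot in pair_slots:
        locus_len = int(rng.integers(max(600, lo * 2), max(900, lo * 2 + 600)))
        locus = _random_seq(rng, locus_len)
        sense_len = int(rng.integers(lo, min(hi, locus_len - 50)))
        anti_len = int(rng.integers(lo, min(hi, locus_len - 50)))
        sense_seq = locus[:sense_len]
        anti_start = locus_len - anti_len
        anti_seq = revcomp(locus[anti_start:])
        sense_id, anti_id = ids[slot], ids[slot + 1]
        subject = f"REF{REFERENCE_SPECIES}_{slot // 2 + 1:05d}"
        transcripts.append(TranscriptRecord(sense_id, sense_seq))
        transcripts.append(TranscriptRecord(anti_id, anti_seq))
        truth.antisense_pairs.append((sense_id, anti_id, subject))
    for i in range(2 * config.n_antisense_pairs, config.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        transcripts.append(TranscriptRecord(ids[i], _random_seq(rng, length)))

    # planted down-regulation in the second (deformed) condition
    paired = {tid for pair in truth.antisense_pairs for tid in pair[:2]}
    free = [t.id for t in transcripts if t.id not in paired]
    de_ids = rng.choice(free, size=config.n_de_genes, replace=False)
    lo_fc, hi_fc = config.de_log2fc_range
    magnitudes = rng.uniform(lo_fc, hi_fc, size=config.n_de_genes)
    truth.de_log2fc = {tid: -float(m) for tid, m in zip(de_ids, magnitudes)}

    # planted qPCR assay efficiencies for every catalog gene
    efficiencies = rng.uniform(1.8, 2.0, size=config.n_transcripts)
    truth.qpcr_efficiencies = {t.id: float(e) for t, e in zip(transcripts, efficiencies)}
    return transcripts, truth


def simulate_ests(
    transcripts: list[TranscriptRecord],
    config: SimulationConfig,
    reads_per_transcript: int = 3,
    min_overlap: int = 60,
) -> tuple[list[EstSequence], dict[str, str]]:
    """Fragment each transcript into overlapping reads that tile it.

    Consecutive reads overlap by at least ``min_overlap`` bases, so the reads
    of one transcript form a single cluster under the 40 bp / 90% rule while
    reads of different (random) transcripts do not. Returns the reads and the
    read -> transcript membership map.
    """
    rng = _rng(config, stream=2)
    ests: list[EstSequence] = []
    members: dict[str, str] = {}
    for t in transcripts:
        n_reads = reads_per_transcript if len(t.seq) >= 300 else 1
        if n_reads == 1:
            est_id = f"{t.id}.r1"
            ests.append(EstSequence(est_id, t.seq, source="sim"))
            members[est_id] = t.id
            continue
        read_len = max(150, len(t.seq) // n_reads + min_overlap)
        step = (len(t.seq) - read_len) // (n_reads - 1) if n_reads > 1 else 0
        for r in range(n_reads):
            start = min(r * step, len(t.seq) - read_len)
            seq = t.seq[start : start + read_len]
            est_id = f"{t.id}.r{r + 1}"
            if rng.random() < 0.2:  # orientation errors occur in real libraries
                seq = revcomp(seq)
            ests.append(EstSequence(est_id, seq, source="sim"))
            members[est_id] = t.id
    return ests, members


# ---------------------------------------------------------------------------
# homology-hit tables

_HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _hit_row(rng, query, subject, qlen, minus_strand, evalue=None):
    aln = int(rng.integers(120, max(150, qlen)))
    qstart = 1
    qend = aln
    sstart, send = (aln + 20, 21) if minus_strand else (21, aln + 20)
    if evalue is None:
        evalue = float(10.0 ** rng.uniform(-80, -20))
    return {
        "qseqid": query, "sseqid": subject, "pident": float(rng.uniform(85, 99)),
        "length": aln, "mismatch": int(rng.integers(0, 10)), "gapopen": 0,
        "qstart": qstart, "qend": qend, "sstart": sstart, "send": send,
        "evalue": evalue, "bitscore": float(rng.uniform(100, 800)),
    }


def simulate_hit_tables(
    transcripts: list[TranscriptRecord],
    truth: GroundTruth,
    config: SimulationConfig,
    species: tuple[str, ...] = FIVE_SPECIES,
    hit_fraction: float = 0.6,
) -> dict[str, pd.DataFrame]:
    """Strand-annotated tabular hit tables against each reference species.

    Planted pair members hit their shared subject in every species: the sense
    member on the plus strand, the antisense member on the minus strand
    (subject coordinates reversed). Unpaired transcripts receive a
    plus-strand hit on a private subject in a random subset of species.
    """
    rng = _rng(config, stream=3)
    lengths = {t.id: len(t.seq) for t in transcripts}
    tables: dict[str, pd.DataFrame] = {sp: [] for sp in species}
    for sense_id, anti_id, subject in truth.antisense_pairs:
        for sp in species:
            subj = subject if sp == REFERENCE_SPECIES else subject.replace(
                REFERENCE_SPECIES, sp
            )
            tables[sp].append(_hit_row(rng, sense_id, subj, lengths[sense_id], False))
            tables[sp].append(_hit_row(rng, anti_id, subj, lengths[anti_id], True))
    paired = {tid for pair in truth.antisense_pairs for tid in pair[:2]}
    for t in transcripts:
        if t.id in paired:
            continue
        for sp in species:
            if rng.random() < hit_fraction:
                subj = f"REF{sp}_{t.id}"
                tables[sp].append(_hit_row(rng, t.id, subj, lengths[t.id], False))
    return {
        sp: pd.DataFrame(rows, columns=_HIT_COLUMNS) for sp, rows in tables.items()
    }


# ---------------------------------------------------------------------------
# expression matrix


def sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for name, n_reps in config.conditions:
        for r in range(1, n_reps + 1):
            sample_id = f"{config.stage}d_{name[0].upper()}{r}"
            rows.append({"sample_id": sample_id, "stage": config.stage,
                         "condition": name, "replicate": r})
    return pd.DataFrame(rows).set_index("sample_id")


def spike_levels(config: SimulationConfig) -> pd.Series:
    """Fixed log2 concentrations for the spike-in species."""
    ids = [f"SPK{i:02d}" for i in range(1, config.n_spikeins + 1)]
    return pd.Series(np.linspace(6.0, 14.0, config.n_spikeins), index=ids)


def simulate_expression(
    config: SimulationConfig,
    probes: list[ProbeRecord] | list[str],
    truth: GroundTruth,
) -> ExpressionDataset:
    """Probe-level intensities, detection flags and sample metadata.

    Both probes of a transcript share the transcript's per-sample expression
    signal plus an independent probe affinity offset and per-spot noise.
    Planted DE transcripts are shifted by their planted log2 fold change in
    the deformed condition. Spike-ins carry condition-independent signals.
    Per-array distortions are affine on the log2 scale (hence monotone), and
    flags are Bernoulli(1 - missingness) forced to 0 below a detection floor.
    """
    probe_ids = [p.probe_id if isinstance(p, ProbeRecord) else p for p in probes]
    transcripts = sorted({transcript_of(pid) for pid in probe_ids})
    samples = sample_table(config)
    deformed = config.conditions[1][0]
    rng = _rng(config, stream=4)

    base = pd.Series(
        rng.normal(config.intensity_location, config.intensity_scale, len(transcripts)),
        index=transcripts,
    )
    offsets = pd.Series(
        rng.normal(0.0, config.probe_offset_sd, len(probe_ids)), index=probe_ids
    )
    log2 = np.empty((len(probe_ids), len(samples)))
    for j, sample in enumerate(samples.index):
        shift = samples.loc[sample, "condition"] == deformed
        for i, pid in enumerate(probe_ids):
            tid = transcript_of(pid)
            mu = base[tid] + offsets[pid]
            if shift and tid in truth.de_log2fc:
                mu += truth.de_log2fc[tid]
            log2[i, j] = mu
    log2 += rng.normal(0.0, config.probe_noise_sd, size=log2.shape)

    spikes = spike_levels(config)
    spike_log2 = (
        spikes.to_numpy()[:, None]
        + rng.normal(0.0, config.spike_noise_sd, size=(len(spikes), len(samples)))
    )
    all_ids = probe_ids + list(spikes.index)
    log2 = np.vstack([log2, spike_log2])

    if config.array_distortion > 0:
        gains = 1.0 + rng.uniform(-0.5, 0.5, len(samples)) * config.array_distortion
        shifts = rng.uniform(-1.0, 1.0, len(samples)) * config.array_distortion
        log2 = log2 * gains[None, :] + shifts[None, :]

    flags = (rng.random(log2.shape) >= config.flag_missingness_rate).astype(int)
    flags[log2 < config.detection_floor_log2] = 0

    intensities = pd.DataFrame(2.0 ** log2, index=all_ids, columns=samples.index)
    flag_frame = pd.DataFrame(flags, index=all_ids, columns=samples.index)
    return ExpressionDataset(
        intensities=intensities,
        flags=flag_frame,
        samples=samples,
        spike_ids=tuple(spikes.index),
    )


# ---------------------------------------------------------------------------
# qPCR


def planted_quantities(
    truth: GroundTruth, genes: list[str], samples: pd.DataFrame, deformed: str = "deformed"
) -> pd.DataFrame:
    """Relative template quantities implied by the planted fold changes.

    Normal-condition samples sit at quantity 1; deformed samples at
    2**log2fc for planted DE genes (1 otherwise).
    """
    quantities = pd.DataFrame(1.0, index=genes, columns=samples.index)
    for gene in genes:
        if gene in truth.de_log2fc:
            mask = samples["condition"] == deformed
            quantities.loc[gene, mask.to_numpy()] = 2.0 ** truth.de_log2fc[gene]
    return quantities


def simulate_qpcr(
    quantities: pd.DataFrame,
    efficiencies: dict[str, float],
    calibrator: str,
    reference_gene: str = "MDH",
    noise_sd: float = 0.0,
    n_dilutions: int = 6,
    n_duplicates: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Crossing-point tables consistent with the given relative quantities.

    Cp = intercept - log_E(quantity) + noise. The reference gene is added
    with condition-independent quantity 1 in every sample; the dilution
    series spans ``n_dilutions`` two-fold steps of the calibrator sample.
    Every (gene, sample) is measured in duplicate.

    Returns ``(cp_table, dilution_series)`` with columns
    (sample, gene, replicate, cp) and (gene, log2_input, replicate, cp).
    """
    if calibrator not in quantities.columns:
        raise ValueError(f"calibrator {calibrator!r} absent from quantities")
    rng = np.random.default_rng(seed)
    table = quantities.copy()
    if reference_gene not in table.index:
        table.loc[reference_gene] = 1.0
    efficiencies = dict(efficiencies)
    efficiencies.setdefault(reference_gene, 2.0)

    intercepts = {
        gene: float(rng.uniform(18.0, 26.0)) for gene in table.index
    }
    cp_rows = []
    for gene in table.index:
        e = efficiencies[gene]
        for sample in table.columns:
            q = table.loc[gene, sample]
            cp = intercepts[gene] - np.log(q) / np.log(e)
            for rep in range(1, n_duplicates + 1):
                cp_rows.append(
                    {"sample": sample, "gene": gene, "replicate": rep,
                     "cp": cp + rng.normal(0.0, noise_sd)}
                )
    dilution_rows = []
    for gene in table.index:
        e = efficiencies[gene]
        q_cal = table.loc[gene, calibrator]
        for step in range(n_dilutions):
            q = q_cal * 2.0 ** (-step)
            cp = intercepts[gene] - np.log(q) / np.log(e)
            for rep in range(1, n_duplicates + 1):
                dilution_rows.append(
                    {"gene": gene, "log2_input": -step, "replicate": rep,
                     "cp": cp + rng.normal(0.0, noise_sd)}
                )
    return pd.DataFrame(cp_rows), pd.DataFrame(dilution_rows)


# ---------------------------------------------------------------------------
# GO annotation maps


def simulate_go_map(
    transcript_ids: list[str],
    config: SimulationConfig,
    n_terms: int = 40,
    terms_per_gene: tuple[int, int] = (1, 4),
    annotated_fraction: float = 0.6,
) -> pd.DataFrame:
    """A transcript -> GO-term map over an invented term vocabulary."""
    rng = _rng(config, stream=5)
    terms = [f"GO:{7000000 + i:07d}" for i in range(n_terms)]
    rows = []
    for tid in transcript_ids:
        if rng.random() > annotated_fraction:
            continue
        k = int(rng.integers(terms_per_gene[0], terms_per_gene[1] + 1))
        for term in rng.choice(terms, size=k, replace=False):
            rows.append({"transcript_id": tid, "term": term})
    return pd.DataFrame(rows, columns=["transcript_id", "term"])


# ---------------------------------------------------------------------------
# one-call convenience


def run_simulation(config: SimulationConfig, out_dir: str) -> GroundTruth:
    """Generate and write every fixture the pipeline consumes."""
    from teleoarray.probes import design_probes, write_probes

    os.makedirs(out_dir, exist_ok=True)
    transcripts, truth = simulate_transcriptome(config)
    with open(os.path.join(out_dir, "transcripts.fasta"), "w") as handle:
        for t in transcripts:
            handle.write(f">{t.id}\n{t.seq}\n")
    ests, members = simulate_ests(transcripts, config)
    truth.est_clusters = members
    with open(os.path.join(out_dir, "ests.fasta"), "w") as handle:
        for est in ests:
            handle.write(f">{est.id}\n{est.seq}\n")
    probes, _failed = design_probes(transcripts)
    write_probes(probes, os.path.join(out_dir, "probes.tsv"))
    dataset = simulate_expression(config, probes, truth)
    dataset.write(os.path.join(out_dir, "expression"))
    for sp, table in simulate_hit_tables(transcripts, truth, config).items():
        table.to_csv(os.path.join(out_dir, f"hits_{sp}.tsv"), sep="\t", index=False)
    go_map = simulate_go_map([t.id for t in transcripts], config)
    go_map.to_csv(os.path.join(out_dir, "go_map.tsv"), sep="\t", index=False)
    samples = sample_table(config)
    genes = sorted(truth.de_log2fc)[: min(13, len(truth.de_log2fc))]
    quantities = planted_quantities(truth, genes, samples)
    cp_table, dilutions = simulate_qpcr(
        quantities,
        {g: truth.qpcr_efficiencies[g] for g in genes},
        calibrator=samples.index[0],
        seed=config.seed,
    )
    cp_table.to_csv(os.path.join(out_dir, "qpcr_cp.tsv"), sep="\t", index=False)
    dilutions.to_csv(os.path.join(out_dir, "qpcr_dilutions.tsv"), sep="\t", index=False)
    truth.write(os.path.join(out_dir, "truth"))
    return truth
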