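"""Core expression-data container shared by normalization, QC and testing modules."""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


def transcript_of(probe_id: str) -> str:
    """Transcript id for a probe named ``<transcript>_1`` / ``<transcript>_2``.

    Ids without a ``_<index>`` suffix (e.g. spike-in controls) are returned
    unchanged.
    """
    stem, _, suffix = probe_id.rpartition("_")
    if stem and suffix.isdigit():
        return stem
    return probe_id


@dataclass
class ExpressionDataset:
    """One-color intensities with per-spot detection flags and sample metadata.

    Parameters
    ----------
    intensities
        Probes x samples matrix of background-corrected intensities on the
        linear scale. Values must be positive wherever the corresponding flag
        is 1.
    flags
        Binary detection flags with the same shape and labels: 1 means the
        spot intensity was significantly above the local background, 0 is
        treated as a missing value downstream.
    samples
        One row per array, indexed by sample id, with at least the columns
        ``stage``, ``condition`` and ``replicate``.
    spike_ids
        Row ids of exogenous spike-in control probes; these are excluded from
        biological summaries and used to score normalization methods.
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame
    samples: pd.DataFrame
    spike_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.spike_ids = tuple(self.spike_ids)
        if not self.intensities.index.equals(self.flags.index) or not (
            self.intensities.columns.equals(self.flags.columns)
        ):
            raise ValueError("intensities and flags must share labels and shape")
        if not self.intensities.columns.equals(self.samples.index):
            raise ValueError("sample metadata must be indexed by the matrix columns")
        flag_values = self.flags.to_numpy()
        if not np.isin(flag_values, (0, 1)).all():
            raise ValueError("flags must be binary")
        flagged = self.intensities.to_numpy()[flag_values == 1]
        if flagged.size and not (flagged > 0).all():
            raise ValueError("flagged intensities must be positive")
        missing = set(self.spike_ids) - set(self.intensities.index)
        if missing:
            raise ValueError(f"spike ids absent from the matrix: {sorted(missing)}")

    # -- convenience views ------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def target_probe_ids(self) -> pd.Index:
        """Probe ids excluding spike-in controls."""
        return self.intensities.index.difference(pd.Index(self.spike_ids), sort=False)

    def condition_samples(self, condition: str) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == condition])

    def stage_samples(self, stage) -> list[str]:
        return list(self.samples.index[self.samples["stage"] == stage])

    def with_intensities(self, intensities: pd.DataFrame) -> "ExpressionDataset":
        """A copy of the dataset with a replacement intensity matrix."""
        return replace(self, intensities=intensities)

    def subset_probes(self, probe_ids) -> "ExpressionDataset":
        keep = pd.Index(probe_ids)
        spikes = tuple(s for s in self.spike_ids if s in keep)
        return ExpressionDataset(
            intensities=self.intensities.loc[keep],
            flags=self.flags.loc[keep],
            samples=self.samples,
            spike_ids=spikes,
        )

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        keep = list(sample_ids)
        return ExpressionDataset(
            intensities=self.intensities[keep],
            flags=self.flags[keep],
            samples=self.samples.loc[keep],
            spike_ids=self.spike_ids,
        )

    # -- on-disk TSV layout ----------------------------------------------

    def write(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        self.intensities.to_csv(os.path.join(directory, "intensities.tsv"), sep="\t")
        self.flags.to_csv(os.path.join(directory, "flags.tsv"), sep="\t")
        self.samples.to_csv(os.path.join(directory, "samples.tsv"), sep="\t")
        with open(os.path.join(directory, "spike_ids.txt"), "w") as handle:
            handle.write("\n".join(self.spike_ids) + ("\n" if self.spike_ids else ""))

    @classmethod
    def read(cls, directory: str) -> "ExpressionDataset":
        intensities = pd.read_csv(
            os.path.join(directory, "intensities.tsv"), sep="\t", index_col=0
        )
        flags = pd.read_csv(os.path.join(directory, "flags.tsv"), sep="\t", index_col=0)
        samples = pd.read_csv(
            os.path.join(directory, "samples.tsv"), sep="\t", index_col=0
        )
        spike_path = os.path.join(directory, "spike_ids.txt")
        spikes: tuple[str, ...] = ()
        if os.path.exists(spike_path):
            with open(spike_path) as handle:
                spikes = tuple(line.strip() for line in handle if line.strip())
        return cls(intensities=intensities, flags=flags, samples=samples, spike_ids=spikes)
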