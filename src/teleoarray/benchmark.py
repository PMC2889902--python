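"""Run the filtering/SAM/QC pipeline on an archived expression series.

These helpers reproduce the platform-scale summary counts on real data:
given probe-level flags and normalized intensities for the two-condition
lower-jaw contrast, they report the number of probes removed by the
missing-value filter, the transcripts retained (split one-probe vs
two-probe), the SAM call counts at 5% FDR with probe-to-transcript
aggregation, and the flag-based hybridization-success summary across all
arrays. Raw series must be fetched separately (see
:func:`fetch_series_matrix`); nothing here ships data.
"""

from __future__ import annotations

import os
import urllib.request
from dataclasses import dataclass

import pandas as pd

from teleoarray import sam
from teleoarray.dataset import ExpressionDataset, transcript_of
from teleoarray.normalize import hybridization_success

GEO_MATRIX_URL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/series/{stub}nnn/{accession}/matrix/"
    "{accession}_series_matrix.txt.gz"
)


def fetch_series_matrix(accession: str, dest_dir: str, timeout: float = 30.0) -> str:
    """Download and decompress a GEO series-matrix file; returns the txt path."""
    import gzip
    import shutil

    os.makedirs(dest_dir, exist_ok=True)
    stub = accession[: -3]
    url = GEO_MATRIX_URL.format(stub=stub, accession=accession)
    gz_path = os.path.join(dest_dir, f"{accession}_series_matrix.txt.gz")
    txt_path = gz_path[: -3]
    if not os.path.exists(txt_path):
        with urllib.request.urlopen(url, timeout=timeout) as response, open(
            gz_path, "wb"
        ) as out:
            shutil.copyfileobj(response, out)
        with gzip.open(gz_path, "rb") as zipped, open(txt_path, "wb") as out:
            shutil.copyfileobj(zipped, out)
    return txt_path


@dataclass
class Stage58Benchmark:
    n_probes_removed: int
    n_transcripts_retained: int
    n_one_probe: int
    n_two_probe: int
    n_significant_probes: int
    n_unique_transcripts: int
    n_both_probe: int


def stage58_benchmark(
    dataset: ExpressionDataset,
    params: sam.SamParameters | None = None,
) -> Stage58Benchmark:
    """Missing-value filter + two-class SAM counts on a normalized dataset.

    ``dataset`` must carry normalized intensities, flags and a two-condition
    sample table (four replicate pools each). Values are log2-transformed for
    the test after imputation of residual missing entries.
    """
    import numpy as np

    params = params or sam.SamParameters()
    target = dataset.subset_probes(dataset.target_probe_ids)
    filtered, removed = sam.missing_value_filter(target)
    imputed = sam.impute_missing(filtered)
    per_transcript: dict[str, int] = {}
    for pid in filtered.probe_ids:
        tid = transcript_of(pid)
        per_transcript[tid] = per_transcript.get(tid, 0) + 1
    log2 = np.log2(imputed.intensities)
    result = sam.sam_two_class(log2, imputed.samples["condition"], params)
    calls = sam.aggregate_to_transcripts(
        result.significant_ids, target.probe_ids, removed
    )
    return Stage58Benchmark(
        n_probes_removed=len(removed),
        n_transcripts_retained=len(per_transcript),
        n_one_probe=sum(1 for n in per_transcript.values() if n == 1),
        n_two_probe=sum(1 for n in per_transcript.values() if n == 2),
        n_significant_probes=len(result.significant_ids),
        n_unique_transcripts=calls.counts.get("n_transcripts", 0),
        n_both_probe=calls.counts.get("both-probe", 0),
    )


def detection_summary(flag_tables: list[pd.DataFrame], min_fraction: float = 0.5):
    """Hybridization success over the union of experiments from several series."""
    flags = pd.concat(flag_tables, axis=1, join="inner")
    return hybridization_success(flags, min_fraction=min_fraction)
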