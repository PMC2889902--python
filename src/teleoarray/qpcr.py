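"""Efficiency-corrected qPCR relative quantification and array agreement.

Assay efficiency E (amplification factor per cycle) comes from the slope m
of a standard curve Cp vs log10(input): E = 10**(-1/m); a perfect assay
doubles per cycle (m = -3.3219, E = 2). Relative expression is the
efficiency-corrected, calibrator-relative ratio normalized to a reference
gene:

    ratio = E_t**(Cp_cal,t - Cp_s,t) / E_r**(Cp_cal,r - Cp_s,r)

Duplicate crossing points are averaged before the ratio. Cross-platform
agreement with array fold changes uses Spearman rank correlation, per probe
and pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress, spearmanr


@dataclass
class StandardCurve:
    efficiency: float
    slope: float
    intercept: float
    r_squared: float


def efficiency_from_curve(
    log2_input, cp, min_abs_slope: float = 0.5
) -> StandardCurve:
    """Fit a standard curve and derive the amplification efficiency.

    ``log2_input`` is the log2 relative template amount of each dilution
    point (0, -1, -2, ... for a two-fold series); at least three distinct
    dilutions are required. Slopes too shallow to represent amplification
    raise.
    """
    log2_input = np.asarray(log2_input, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if log2_input.shape != cp.shape:
        raise ValueError("input and Cp arrays must align")
    if np.unique(log2_input).size < 3:
        raise ValueError("a standard curve needs at least three distinct dilutions")
    log10_input = log2_input * np.log10(2.0)
    fit = linregress(log10_input, cp)
    if abs(fit.slope) < min_abs_slope:
        raise ValueError(f"slope {fit.slope:.3f} too shallow: assay not amplifying")
    efficiency = 10.0 ** (-1.0 / fit.slope)
    return StandardCurve(
        efficiency=float(efficiency),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def efficiencies_from_dilutions(dilutions: pd.DataFrame) -> dict[str, StandardCurve]:
    """One standard curve per gene from a (gene, log2_input, cp) long table."""
    return {
        str(gene): efficiency_from_curve(group["log2_input"], group["cp"])
        for gene, group in dilutions.groupby("gene")
    }


def mean_cp(cp_table: pd.DataFrame) -> pd.DataFrame:
    """Average duplicate Cp measurements into a genes x samples matrix."""
    for col in ("sample", "gene", "cp"):
        if col not in cp_table.columns:
            raise ValueError(f"Cp table must have a {col!r} column")
    return cp_table.pivot_table(index="gene", columns="sample", values="cp", aggfunc="mean")


def relative_expression(
    cp_target_sample: float,
    cp_target_calibrator: float,
    cp_reference_sample: float,
    cp_reference_calibrator: float,
    e_target: float,
    e_reference: float,
) -> float:
    """Efficiency-corrected, calibrator-relative, reference-normalized ratio."""
    for e in (e_target, e_reference):
        if not 1.0 < e <= 2.2:
            raise ValueError(f"efficiency {e} outside the plausible (1, 2.2] range")
    target = e_target ** (cp_target_calibrator - cp_target_sample)
    reference = e_reference ** (cp_reference_calibrator - cp_reference_sample)
    return target / reference


def relative_expression_table(
    cp_table: pd.DataFrame,
    calibrator: str,
    reference_gene: str,
    efficiencies: dict[str, float],
) -> pd.DataFrame:
    """Genes x samples matrix of relative expression values.

    Duplicates are averaged first; every gene needs a Cp in the calibrator
    sample and the reference gene must be measured everywhere.
    """
    cp = mean_cp(cp_table)
    if calibrator not in cp.columns:
        raise ValueError(f"calibrator sample {calibrator!r} missing from the Cp table")
    if reference_gene not in cp.index:
        raise ValueError(f"reference gene {reference_gene!r} missing from the Cp table")
    genes = [g for g in cp.index if g != reference_gene]
    out = pd.DataFrame(index=genes, columns=cp.columns, dtype=float)
    for gene in genes:
        e_t = efficiencies[gene]
        e_r = efficiencies.get(reference_gene, 2.0)
        for sample in cp.columns:
            out.loc[gene, sample] = relative_expression(
                cp.loc[gene, sample],
                cp.loc[gene, calibrator],
                cp.loc[reference_gene, sample],
                cp.loc[reference_gene, calibrator],
                e_t,
                e_r,
            )
    return out


def reference_stability(values, ddof: int = 1) -> float:
    """CV% of a reference probe's intensity across all arrays (sample sd)."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean == 0:
        raise ZeroDivisionError("zero mean signal: CV undefined")
    return float(100.0 * values.std(ddof=ddof) / mean)


def crossplatform_agreement(
    qpcr: pd.DataFrame,
    array: pd.DataFrame,
    probe_to_gene: dict[str, str],
) -> pd.DataFrame:
    """Spearman agreement between qPCR and array expression, per probe.

    ``qpcr`` is genes x samples (relative quantities); ``array`` is probes x
    samples on matching sample ids. Returns one row per (gene, probe) with
    rho and the two-sided p-value (average-rank ties), plus a ``pooled`` row
    over all paired points (requires at least five pairs). Probes whose
    vectors are constant yield NaN rho.
    """
    shared = [s for s in qpcr.columns if s in array.columns]
    if len(shared) < 3:
        raise ValueError("need at least three shared samples")
    rows = []
    pooled_x: list[float] = []
    pooled_y: list[float] = []
    for probe, gene in sorted(probe_to_gene.items()):
        if gene not in qpcr.index or probe not in array.index:
            continue
        x = qpcr.loc[gene, shared].to_numpy(dtype=float)
        y = array.loc[probe, shared].to_numpy(dtype=float)
        pooled_x.extend(x)
        pooled_y.extend(y)
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            rho, p = np.nan, np.nan
        else:
            rho, p = spearmanr(x, y)
        rows.append({"gene": gene, "probe": probe, "rho": rho, "p_value": p, "n": len(x)})
    if len(pooled_x) >= 5:
        rho, p = spearmanr(pooled_x, pooled_y)
        rows.append(
            {"gene": "(all)", "probe": "pooled", "rho": rho, "p_value": p, "n": len(pooled_x)}
        )
    return pd.DataFrame(rows, columns=["gene", "probe", "rho", "p_value", "n"])
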