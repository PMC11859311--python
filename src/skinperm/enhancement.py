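"""Enhancement ratios, SC/vehicle partitioning and solubility-parameter gaps.

A penetration enhancer's effect is summarized by three treated/control
ratios: QER (on the cumulative permeated amount Q), PER (on the
permeability coefficient P) and KER (on the stratum-corneum/vehicle
partition coefficient K = C_SC/C_vehicle).  All three are the same
operation on different quantities, which :func:`enhancement_ratio` makes
explicit.  The module also houses the signed solubility-parameter
difference Δδ = δ_compound − δ_reference used to rank drug/lipid
compatibility, and first-order uncertainty propagation for ratios of
group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PartitionRecord",
    "EnhancementRecord",
    "SolubilityParameters",
    "enhancement_ratio",
    "ratio_uncertainty",
    "partition_coefficient",
    "delta_solubility_difference",
    "enhancement_table",
    "solubility_differences",
]


def enhancement_ratio(value_treated: float, value_control: float) -> float:
    """Treated/control ratio; the single definition behind QER, PER and KER."""
    if value_control <= 0:
        raise ValueError(f"control value must be positive, got {value_control}")
    return value_treated / value_control


def ratio_uncertainty(
    mean_t: float, sd_t: float, mean_c: float, sd_c: float
) -> float:
    """First-order SD of a ratio of two independent means.

    sd(t/c) ≈ (t/c)·sqrt((sd_t/t)² + (sd_c/c)²).  Group means from
    independent diffusion cells justify the independence assumption.
    """
    if mean_t <= 0 or mean_c <= 0:
        raise ValueError("means must be positive for ratio propagation")
    if sd_t < 0 or sd_c < 0:
        raise ValueError("standard deviations must be non-negative")
    ratio = mean_t / mean_c
    return ratio * math.sqrt((sd_t / mean_t) ** 2 + (sd_c / mean_c) ** 2)


def partition_coefficient(c_sc: float, c_vehicle: float) -> float:
    """K = C_SC / C_vehicle in the field's mixed units (µg/g over µg/mL).

    No tissue-density correction is applied: the convention reports the
    raw concentration ratio.
    """
    if c_vehicle <= 0:
        raise ValueError(f"vehicle concentration must be positive, got {c_vehicle}")
    return c_sc / c_vehicle


def delta_solubility_difference(
    delta_compound: float, delta_reference: float
) -> float:
    """Signed Δδ = δ_compound − δ_reference, (J/cm³)^½."""
    return delta_compound - delta_reference


@dataclass(frozen=True)
class PartitionRecord:
    """One SC/vehicle partition measurement (mixed-unit convention)."""

    c_sc: float  # µg/g
    c_vehicle: float  # µg/mL

    @property
    def k(self) -> float:
        return partition_coefficient(self.c_sc, self.c_vehicle)


@dataclass(frozen=True)
class EnhancementRecord:
    """QER/PER/KER (each with a propagated SD) for one drug × treatment."""

    drug: str
    treatment: str
    qer: float
    qer_sd: float
    per: float | None = None
    per_sd: float | None = None
    ker: float | None = None
    ker_sd: float | None = None


@dataclass(frozen=True)
class SolubilityParameters:
    """Total solubility parameter of a compound and its gap to a reference lipid."""

    name: str
    delta: float  # (J/cm³)^½
    delta_diff: float  # delta − delta_reference


# ---------------------------------------------------------------------------
# Table-level helpers
# ---------------------------------------------------------------------------


def _ratio_with_sd(row_t, row_c, mean_col: str, sd_col: str) -> tuple[float, float]:
    ratio = enhancement_ratio(row_t[mean_col], row_c[mean_col])
    sd = ratio_uncertainty(row_t[mean_col], row_t[sd_col], row_c[mean_col], row_c[sd_col])
    return ratio, sd


def enhancement_table(
    group_summary: pd.DataFrame,
    partition_summary: pd.DataFrame | None = None,
    control_label: str = "control",
) -> pd.DataFrame:
    """Compute the QER/PER/KER table from per-group summaries.

    Ratios of group means are the primary output (the convention that
    reproduces published enhancement tables); per-replicate ratio spreads
    enter only through the propagated SDs.

    Parameters
    ----------
    group_summary : DataFrame
        Output of :func:`skinperm.permeation.summarize_groups` — one row
        per drug × treatment with ``q_final_mean/sd`` and (optionally)
        ``p_mean/sd`` columns.
    partition_summary : DataFrame, optional
        One row per drug × treatment with ``k_mean`` and ``k_sd``.
    control_label : str
        Treatment label of the no-enhancer arm.
    """
    if partition_summary is not None:
        merged = group_summary.merge(
            partition_summary, on=["drug", "treatment"], how="left"
        )
    else:
        merged = group_summary.copy()
        merged["k_mean"] = float("nan")
        merged["k_sd"] = float("nan")

    rows = []
    for drug, grp in merged.groupby("drug", sort=False):
        ctrl = grp[grp["treatment"] == control_label]
        if ctrl.empty:
            raise ValueError(f"no '{control_label}' arm for drug {drug!r}")
        ctrl = ctrl.iloc[0]
        for _, row in grp.iterrows():
            if row["treatment"] == control_label:
                rec = {
                    "drug": drug,
                    "treatment": control_label,
                    "qer": 1.0,
                    "qer_sd": 0.0,
                    "per": 1.0,
                    "per_sd": 0.0,
                    "ker": 1.0,
                    "ker_sd": 0.0,
                }
            else:
                qer, qer_sd = _ratio_with_sd(row, ctrl, "q_final_mean", "q_final_sd")
                rec = {"drug": drug, "treatment": row["treatment"],
                       "qer": qer, "qer_sd": qer_sd}
                if pd.notna(row.get("p_mean")) and pd.notna(ctrl.get("p_mean")):
                    rec["per"], rec["per_sd"] = _ratio_with_sd(
                        row, ctrl, "p_mean", "p_sd"
                    )
                else:
                    rec["per"] = rec["per_sd"] = float("nan")
                if pd.notna(row.get("k_mean")) and pd.notna(ctrl.get("k_mean")):
                    rec["ker"], rec["ker_sd"] = _ratio_with_sd(
                        row, ctrl, "k_mean", "k_sd"
                    )
                else:
                    rec["ker"] = rec["ker_sd"] = float("nan")
            rows.append(rec)
    return pd.DataFrame(rows)


def solubility_differences(
    deltas: pd.DataFrame,
    reference: str = "NP",
    name_col: str = "name",
    delta_col: str = "delta",
) -> pd.DataFrame:
    """Add a ``delta_diff`` column of signed gaps to the reference compound."""
    ref_rows = deltas[deltas[name_col] == reference]
    if ref_rows.empty:
        raise ValueError(f"reference compound {reference!r} not in table")
    ref = float(ref_rows[delta_col].iloc[0])
    out = deltas.copy()
    out["delta_diff"] = [
        float("nan") if n == reference else delta_solubility_difference(d, ref)
        for n, d in zip(out[name_col], out[delta_col])
    ]
    return out
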