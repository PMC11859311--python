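"""Permeation kinetics: cumulative amounts and steady-state flux estimation.

A diffusion-cell (IVPT) experiment measures the drug concentration in the
receptor chamber at a series of sampling times.  Because each draw removes
part of the receptor volume and replaces it with fresh medium, the raw
concentrations understate the amount that has actually crossed the membrane.
This module applies the standard sampling-replacement correction to obtain
the cumulative permeated amount per unit area Q(t), then estimates the
steady-state flux J_ss (terminal slope of Q vs t), the lag time T_lag
(x-intercept of that line) and the permeability coefficient P = J_ss / C
where C is the drug solubility in the donor vehicle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiffusionCellProtocol",
    "ConcentrationSeries",
    "PermeationProfile",
    "PermeationParameters",
    "FluxEstimationError",
    "cumulative_permeation",
    "estimate_flux_lag",
    "permeability_coefficient",
    "read_concentration_csv",
    "fit_replicates",
    "summarize_groups",
]


class FluxEstimationError(ValueError):
    """Raised when no physically meaningful flux can be estimated."""


@dataclass(frozen=True)
class DiffusionCellProtocol:
    """Geometry and sampling schedule of a horizontal diffusion cell.

    Defaults match a common small Franz-type setup: 1.77 cm² effective
    diffusion area, 4 mL receptor, 2 mL drawn (and replaced with fresh
    medium) at each of 1..8 h.

    Parameters
    ----------
    area : float
        Effective diffusion area, cm².
    receptor_volume : float
        Receptor chamber volume, mL.
    sample_volume : float
        Volume withdrawn at each sampling time, mL; must be smaller than
        the receptor volume.
    sample_times : tuple of float
        Sampling times in hours, strictly increasing and positive.
    temperature_c : float
        Bath temperature, °C (metadata only).
    """

    area: float = 1.77
    receptor_volume: float = 4.0
    sample_volume: float = 2.0
    sample_times: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    temperature_c: float = 32.0

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"area must be positive, got {self.area}")
        if not 0 < self.sample_volume < self.receptor_volume:
            raise ValueError(
                "sample_volume must satisfy 0 < sample_volume < receptor_volume "
                f"(got {self.sample_volume} vs {self.receptor_volume})"
            )
        t = np.asarray(self.sample_times, dtype=float)
        if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sample_times must be strictly increasing and positive")
        object.__setattr__(self, "sample_times", tuple(float(x) for x in t))


@dataclass(frozen=True)
class ConcentrationSeries:
    """Measured receptor concentrations for one replicate.

    ``times`` are hours (strictly increasing, positive); ``concentrations``
    are µg/mL, non-negative, one per time point.
    """

    replicate_id: str
    drug: str
    treatment: str
    times: tuple[float, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.size == 0:
            raise ValueError("empty concentration series")
        if t.size != c.size:
            raise ValueError("times and concentrations must have equal length")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and positive")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "concentrations", tuple(float(x) for x in c))


@dataclass(frozen=True)
class PermeationProfile:
    """Cumulative permeated amount per area (µg/cm²) for one replicate."""

    series: ConcentrationSeries
    cumulative_q: tuple[float, ...]

    @property
    def times(self) -> tuple[float, ...]:
        return self.series.times


@dataclass(frozen=True)
class PermeationParameters:
    """Steady-state permeation parameters fitted from one profile.

    ``fit_window`` is the (start, stop) index range of the points used for
    the terminal linear fit.  ``window_forced`` flags that no window met the
    R² threshold and the minimal terminal window was used; ``negative_lag``
    flags a negative x-intercept, which is reported rather than clipped.
    """

    jss: float
    tlag: float
    r_squared: float
    fit_window: tuple[int, int]
    q_final: float
    p_coefficient: float | None = None
    window_forced: bool = False
    negative_lag: bool = field(default=False)


def cumulative_permeation(
    series: ConcentrationSeries, protocol: DiffusionCellProtocol
) -> PermeationProfile:
    """Apply the sampling-replacement correction to a concentration series.

    Q_i = (V_receptor · C_i + V_sample · Σ_{j<i} C_j) / area

    The first term is the drug mass currently in the receptor; the second
    restores the mass removed in all earlier draws, so Q_i equals the total
    mass that has permeated per unit area up to time i.  With the default
    protocol this is (4·C_i + 2·ΣC_earlier)/1.77.
    """
    c = np.asarray(series.concentrations, dtype=float)
    removed_before = protocol.sample_volume * np.concatenate(([0.0], np.cumsum(c)[:-1]))
    q = (protocol.receptor_volume * c + removed_before) / protocol.area
    return PermeationProfile(series=series, cumulative_q=tuple(float(x) for x in q))


def _linfit(t: np.ndarray, q: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line through (t, q); returns (slope, intercept, r²)."""
    slope, intercept = np.polyfit(t, q, 1)
    resid = q - (slope * t + intercept)
    sst = float(np.sum((q - q.mean()) ** 2))
    if sst == 0.0:
        # flat data: a horizontal line fits exactly but carries no flux signal
        return float(slope), float(intercept), 1.0 if np.allclose(resid, 0) else 0.0
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    return float(slope), float(intercept), max(0.0, min(1.0, r2))


def estimate_flux_lag(
    profile: PermeationProfile,
    min_points: int = 3,
    r2_threshold: float = 0.9999,
) -> PermeationParameters:
    """Estimate J_ss and T_lag from the terminal linear portion of Q(t).

    The "linear portion" is identified as the longest terminal window (the
    last k points, k ≥ ``min_points``) whose least-squares line reaches
    R² ≥ ``r2_threshold``.  The default threshold is deliberately strict:
    an 8-point profile still inside its lag phase can show R² ≈ 0.996
    despite visible curvature, so only a near-perfect line is accepted as
    the steady-state portion.  If no window qualifies, the terminal
    ``min_points`` window is used and ``window_forced`` is set.  J_ss is the
    slope of that line and T_lag its x-intercept (−intercept/slope); a
    negative lag is reported with ``negative_lag`` set rather than clipped.

    Raises
    ------
    ValueError
        If the profile has fewer than ``min_points`` points.
    FluxEstimationError
        If the fitted slope is not positive (no measurable flux).
    """
    if min_points < 3:
        raise ValueError("min_points must be at least 3")
    t = np.asarray(profile.times, dtype=float)
    q = np.asarray(profile.cumulative_q, dtype=float)
    n = t.size
    if n < min_points:
        raise ValueError(f"profile has {n} points; at least {min_points} required")

    chosen: tuple[int, int] | None = None
    slope = intercept = r2 = float("nan")
    for k in range(n, min_points - 1, -1):  # longest terminal window first
        s, b, r = _linfit(t[n - k :], q[n - k :])
        if r >= r2_threshold:
            chosen, slope, intercept, r2 = (n - k, n), s, b, r
            break
    forced = chosen is None
    if forced:
        chosen = (n - min_points, n)
        slope, intercept, r2 = _linfit(t[chosen[0] :], q[chosen[0] :])

    if slope <= 0:
        raise FluxEstimationError(
            f"terminal slope {slope:.3g} is not positive: no measurable flux"
        )
    tlag = -intercept / slope
    return PermeationParameters(
        jss=slope,
        tlag=tlag,
        r_squared=r2,
        fit_window=chosen,
        q_final=float(q[-1]),
        window_forced=forced,
        negative_lag=tlag < 0,
    )


def permeability_coefficient(jss: float, donor_solubility: float) -> float:
    """P = J_ss / C, in cm/h (J_ss in µg·cm⁻²·h⁻¹, C in µg/mL)."""
    if donor_solubility <= 0:
        raise ValueError(f"donor solubility must be positive, got {donor_solubility}")
    return jss / donor_solubility


# ---------------------------------------------------------------------------
# Tidy-CSV interface and replicate/group summaries
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["replicate", "drug", "treatment", "time_h", "conc_ug_per_ml"]


def read_concentration_csv(path) -> list[ConcentrationSeries]:
    """Read a tidy IVPT CSV (replicate, drug, treatment, time_h, conc_ug_per_ml)."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = []
    for (rep, drug, trt), grp in df.groupby(
        ["replicate", "drug", "treatment"], sort=False
    ):
        grp = grp.sort_values("time_h")
        out.append(
            ConcentrationSeries(
                replicate_id=str(rep),
                drug=str(drug),
                treatment=str(trt),
                times=tuple(grp["time_h"].astype(float)),
                concentrations=tuple(grp["conc_ug_per_ml"].astype(float)),
            )
        )
    return out


def fit_replicates(
    series_list: Sequence[ConcentrationSeries],
    protocol: DiffusionCellProtocol,
    donor_solubility: dict[tuple[str, str], float] | None = None,
    min_points: int = 3,
    r2_threshold: float = 0.9999,
) -> pd.DataFrame:
    """Fit J_ss, T_lag (and P when solubility is known) for every replicate.

    ``donor_solubility`` maps (drug, treatment) to the donor solubility C in
    µg/mL.  Replicates are fitted individually; see :func:`summarize_groups`
    for the mean ± SD group table.
    """
    rows = []
    for s in series_list:
        profile = cumulative_permeation(s, protocol)
        params = estimate_flux_lag(profile, min_points, r2_threshold)
        p = None
        if donor_solubility is not None:
            c = donor_solubility.get((s.drug, s.treatment))
            if c is not None:
                p = permeability_coefficient(params.jss, c)
        rows.append(
            {
                "replicate": s.replicate_id,
                "drug": s.drug,
                "treatment": s.treatment,
                "jss": params.jss,
                "tlag": params.tlag,
                "q_final": params.q_final,
                "p": p,
                "r_squared": params.r_squared,
                "window_forced": params.window_forced,
                "negative_lag": params.negative_lag,
            }
        )
    return pd.DataFrame(rows)


def summarize_groups(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of J_ss, T_lag, Q_final and P per drug × treatment group."""
    agg = {}
    for col in ["jss", "tlag", "q_final", "p"]:
        agg[f"{col}_mean"] = (col, "mean")
        agg[f"{col}_sd"] = (col, "std")
    out = per_replicate.groupby(["drug", "treatment"], sort=False).agg(**agg)
    return out.reset_index()
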