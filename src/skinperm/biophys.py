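"""Membrane-perturbation readouts: FTIR deltas, DSC deltas, Einstein MSD fits.

Small exact utilities for the spectroscopic and calorimetric evidence of
lipid-bilayer disruption (CH₂ stretching peak areas and positions, Amide I
band shifts, phase-transition deltas) plus a generic mean-square-
displacement → diffusion-coefficient fit via the Einstein relation, with a
Gaussian random-walk generator for validating that fit against known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PeakRecord",
    "ThermalRecord",
    "MSDSeries",
    "peak_area_decrease",
    "band_shift",
    "einstein_diffusion_fit",
    "generate_random_walk",
]


@dataclass(frozen=True)
class PeakRecord:
    """One infrared band: label (e.g. asymmetric CH₂), position (cm⁻¹), area."""

    band: str
    position: float
    area: float

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


@dataclass(frozen=True)
class ThermalRecord:
    """A lipid phase transition: midpoint temperature (°C) and enthalpy (kJ/mol)."""

    tm: float
    delta_h: float


@dataclass(frozen=True)
class MSDSeries:
    """A mean-square-displacement curve: times (ps), MSD (Å²), dimensionality."""

    times: tuple[float, ...]
    msd: tuple[float, ...]
    dimension: int

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.msd, dtype=float)
        if t.size != m.size or t.size == 0:
            raise ValueError("times and msd must be non-empty and of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(m < 0):
            raise ValueError("msd must be non-negative")
        if t[0] == 0 and m[0] != 0:
            raise ValueError("msd must be 0 at t = 0")
        if self.dimension not in (1, 2, 3):
            raise ValueError("dimension must be 1, 2 or 3")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "msd", tuple(float(x) for x in m))


def peak_area_decrease(area_control: float, area_treated: float) -> float:
    """Percent decrease in peak area: 100·(1 − treated/control), 2 dp.

    Shrinking CH₂ stretching areas indicate lipid extraction from the
    stratum corneum; the value is reported rounded to two decimals, the
    convention of published FTIR tables.
    """
    if area_control <= 0:
        raise ValueError(f"control area must be positive, got {area_control}")
    return round(100.0 * (1.0 - area_treated / area_control), 2)


def band_shift(position_control: float, position_treated: float) -> float:
    """Signed band displacement, treated − control, cm⁻¹."""
    return position_treated - position_control


def einstein_diffusion_fit(series: MSDSeries, fit_fraction: float = 0.5) -> float:
    """Diffusion coefficient from an MSD curve via the Einstein relation.

    Fits a least-squares line to MSD vs t over the terminal ``fit_fraction``
    of points (where diffusive, linear behaviour holds) and returns
    slope / (2·dimension), in Å²/ps.
    """
    if not 0 < fit_fraction <= 1:
        raise ValueError("fit_fraction must be in (0, 1]")
    t = np.asarray(series.times, dtype=float)
    m = np.asarray(series.msd, dtype=float)
    n_fit = max(int(round(fit_fraction * t.size)), 3)
    if n_fit > t.size:
        raise ValueError(
            f"fit window needs at least 3 points; series has {t.size}"
        )
    slope = np.polyfit(t[-n_fit:], m[-n_fit:], 1)[0]
    return float(slope) / (2.0 * series.dimension)


def generate_random_walk(
    d_true: float,
    dimension: int = 3,
    n_steps: int = 1000,
    dt: float = 1.0,
    n_walkers: int = 100,
    seed: int = 0,
) -> MSDSeries:
    """Ensemble MSD of isotropic Gaussian random walks with diffusivity ``d_true``.

    Each coordinate takes independent displacements of variance 2·D·dt per
    step, so the expected MSD is 2·dimension·D·t; averaging over
    ``n_walkers`` walkers (all starting at the origin) gives the returned
    curve.  A fixed seed reproduces the series exactly.
    """
    if d_true <= 0:
        raise ValueError("d_true must be positive")
    if dimension not in (1, 2, 3):
        raise ValueError("dimension must be 1, 2 or 3")
    if n_steps < 1 or n_walkers < 1:
        raise ValueError("n_steps and n_walkers must be at least 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    step_sd = np.sqrt(2.0 * d_true * dt)
    steps = rng.normal(0.0, step_sd, size=(n_walkers, n_steps, dimension))
    positions = np.cumsum(steps, axis=1)
    msd = np.mean(np.sum(positions**2, axis=2), axis=0)
    times = dt * np.arange(1, n_steps + 1)
    return MSDSeries(times=tuple(times), msd=tuple(msd), dimension=dimension)
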