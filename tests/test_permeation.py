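"""Sampling correction, flux/lag estimation and the permeability coefficient."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skinperm import (
    ConcentrationSeries,
    DiffusionCellProtocol,
    FluxEstimationError,
    MembraneModel,
    NoiseModel,
    PermeationProfile,
    cumulative_permeation,
    estimate_flux_lag,
    permeability_coefficient,
    simulate_ivpt,
)
from skinperm.permeation import fit_replicates, summarize_groups
from skinperm.synthetic import ivpt_to_frame


def _series(times, concs, **kw):
    defaults = dict(replicate_id="r1", drug="d", treatment="t")
    defaults.update(kw)
    return ConcentrationSeries(times=tuple(times), concentrations=tuple(concs), **defaults)


class TestCumulativePermeation:
    def test_all_zero_concentrations(self, protocol):
        prof = cumulative_permeation(_series([1, 2, 3], [0, 0, 0]), protocol)
        assert prof.cumulative_q == (0.0, 0.0, 0.0)

    def test_hand_mass_ledger(self, protocol):
        """C = [10, 20] µg/mL: 40 µg in the receptor at t₁; at t₂ 80 µg are
        present plus the 20 µg removed in draw 1 → Q = [40, 100]/1.77."""
        prof = cumulative_permeation(_series([1, 2], [10, 20]), protocol)
        np.testing.assert_allclose(prof.cumulative_q, [40 / 1.77, 100 / 1.77])

    def test_monotone_for_physically_consistent_series(self, protocol):
        """Q is non-decreasing whenever each concentration is at least the
        post-draw residue of the previous one, C_i ≥ (1 − V_s/V)·C_{i−1} —
        the condition every draw-and-replace experiment satisfies."""
        rng = np.random.default_rng(5)
        residue = 1.0 - protocol.sample_volume / protocol.receptor_volume
        concs = [rng.uniform(0, 50)]
        for _ in range(7):
            concs.append(residue * concs[-1] + rng.uniform(0, 20))
        prof = cumulative_permeation(_series(range(1, 9), concs), protocol)
        assert np.all(np.diff(prof.cumulative_q) >= 0)

    @settings(deadline=None, max_examples=25)
    @given(scale=st.floats(0.1, 100), seed=st.integers(0, 10))
    def test_scale_equivariance(self, scale, seed):
        """Scaling all concentrations by s scales Q and J_ss by s, not T_lag."""
        protocol = DiffusionCellProtocol()
        rng = np.random.default_rng(seed)
        base = np.cumsum(rng.uniform(1, 10, 8))  # increasing, positive
        p1 = cumulative_permeation(_series(range(1, 9), base), protocol)
        p2 = cumulative_permeation(_series(range(1, 9), scale * base), protocol)
        np.testing.assert_allclose(
            np.asarray(p2.cumulative_q), scale * np.asarray(p1.cumulative_q), rtol=1e-9
        )
        f1 = estimate_flux_lag(p1)
        f2 = estimate_flux_lag(p2)
        assert f2.jss == pytest.approx(scale * f1.jss, rel=1e-9)
        assert f2.tlag == pytest.approx(f1.tlag, rel=1e-6, abs=1e-9)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            _series([], [])


class TestEstimateFluxLag:
    def test_exact_line(self, protocol):
        """Q = 5·(t − 1) over t = 2..8 → slope 5, lag 1, R² 1."""
        t = np.arange(2, 9, dtype=float)
        prof = PermeationProfile(
            series=_series(t, np.ones_like(t)), cumulative_q=tuple(5.0 * (t - 1.0))
        )
        fit = estimate_flux_lag(prof)
        assert fit.jss == pytest.approx(5.0)
        assert fit.tlag == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert not fit.window_forced and not fit.negative_lag

    def test_noiseless_diffusion_profile_recovers_truth(self, lagged_membrane, protocol):
        """Noiseless profile with T_lag = 1.5 h: J_ss within 2%, T_lag within 5%."""
        sim = simulate_ivpt(lagged_membrane, protocol, NoiseModel(0.0, 0), 1)
        fit = estimate_flux_lag(cumulative_permeation(sim.replicates[0], protocol))
        assert fit.jss == pytest.approx(lagged_membrane.true_flux, rel=0.02)
        assert fit.tlag == pytest.approx(lagged_membrane.true_lag_time, rel=0.05)

    def test_two_point_profile_rejected(self, protocol):
        prof = cumulative_permeation(_series([1, 2], [1, 2]), protocol)
        with pytest.raises(ValueError):
            estimate_flux_lag(prof)

    def test_non_positive_slope_raises(self, protocol):
        t = np.arange(1, 9, dtype=float)
        prof = PermeationProfile(
            series=_series(t, np.ones_like(t)), cumulative_q=tuple(10.0 - t)
        )
        with pytest.raises(FluxEstimationError):
            estimate_flux_lag(prof)

    def test_negative_lag_reported_with_flag(self, protocol):
        t = np.arange(1, 9, dtype=float)
        prof = PermeationProfile(
            series=_series(t, np.ones_like(t)), cumulative_q=tuple(2.0 * t + 1.0)
        )
        fit = estimate_flux_lag(prof)
        assert fit.tlag == pytest.approx(-0.5)
        assert fit.negative_lag

    def test_curved_profile_flagged_when_no_window_linear(self, protocol):
        t = np.arange(1, 9, dtype=float)
        prof = PermeationProfile(
            series=_series(t, np.ones_like(t)), cumulative_q=tuple(t**3)
        )
        fit = estimate_flux_lag(prof)
        assert fit.window_forced
        assert fit.fit_window == (5, 8)

    def test_stochastic_recovery_median(self):
        """3% assay noise, 4 replicates, 100 seeds over lag times 0.5–2.5 h:
        median J_ss error < 5%, median T_lag error < 15%."""
        protocol = DiffusionCellProtocol()
        jerr, terr = [], []
        for tlag in (0.5, 1.5, 2.5):
            h = float(np.sqrt(6 * 1e-4 * tlag))
            m = MembraneModel(1.0, 1e-4, h, 1000.0)
            for seed in range(100):
                sim = simulate_ivpt(m, protocol, NoiseModel(0.03, seed), 4)
                for rep in sim.replicates:
                    fit = estimate_flux_lag(cumulative_permeation(rep, protocol))
                    jerr.append(abs(fit.jss - m.true_flux) / m.true_flux)
                    terr.append(abs(fit.tlag - tlag) / tlag)
        assert np.median(jerr) < 0.05
        assert np.median(terr) < 0.15


class TestPermeabilityCoefficient:
    @pytest.mark.parametrize(
        "jss, c, expected",
        [
            (14.79, 307.06, 0.04816),  # control-arm division of published means
            (28.15, 467.53, 0.06021),  # enhanced-arm division of published means
            (0.0, 100.0, 0.0),
        ],
    )
    def test_examples(self, jss, c, expected):
        assert permeability_coefficient(jss, c) == pytest.approx(expected, abs=1e-5)

    def test_non_positive_solubility_rejected(self):
        with pytest.raises(ValueError):
            permeability_coefficient(1.0, 0.0)


def test_fit_replicates_and_group_summary(lagged_membrane, protocol, tmp_path):
    """Per-replicate fits round-trip through the tidy CSV and group means."""
    sim = simulate_ivpt(lagged_membrane, protocol, NoiseModel(0.03, 9), 4)
    df = ivpt_to_frame(sim, drug="demo", treatment="control")
    path = tmp_path / "conc.csv"
    df.to_csv(path, index=False)
    from skinperm import read_concentration_csv

    series = read_concentration_csv(path)
    assert len(series) == 4
    per_rep = fit_replicates(
        series, protocol, donor_solubility={("demo", "control"): 1000.0}
    )
    assert set(per_rep["replicate"]) == {"rep1", "rep2", "rep3", "rep4"}
    assert (per_rep["p"] == per_rep["jss"] / 1000.0).all()
    groups = summarize_groups(per_rep)
    assert len(groups) == 1
    assert groups["jss_mean"].iloc[0] == pytest.approx(per_rep["jss"].mean())


def test_read_csv_missing_column(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("replicate,drug,time_h\nr1,d,1\n")
    from skinperm import read_concentration_csv

    with pytest.raises(ValueError, match="missing column"):
        read_concentration_csv(path)
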