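"""Simulator tests: series solution, truth ledgers, partition, panels."""

import numpy as np
import pandas as pd
import pytest

from skinperm import (
    MembraneModel,
    NoiseModel,
    PartitionGroundTruth,
    cumulative_permeation,
    finite_difference_cumulative_amount,
    generate_enhancement_panel,
    simulate_ivpt,
    simulate_partition,
    true_cumulative_amount,
)
from skinperm.permeation import DiffusionCellProtocol
from skinperm.qspr import fit_linear_model
from skinperm.synthetic import ivpt_to_frame


class TestTimeLagSeries:
    def test_zero_at_time_zero(self, membrane):
        assert true_cumulative_amount(membrane, 0.0) == 0.0

    def test_negative_time_rejected(self, membrane):
        with pytest.raises(ValueError):
            true_cumulative_amount(membrane, -0.1)

    def test_asymptotic_linear_regime(self, membrane):
        """At 10× the lag time, Q is within 0.5% of J_ss·(t − T_lag)."""
        t = 10 * membrane.true_lag_time
        expected = membrane.true_flux * (t - membrane.true_lag_time)
        assert true_cumulative_amount(membrane, t) == pytest.approx(expected, rel=5e-3)

    def test_against_pde_solver(self, membrane):
        """Series matches a 2000-node finite-difference PDE solve to 0.1%."""
        t = 0.05  # deep in the transient: 3× the 1-minute lag time
        q_series = true_cumulative_amount(membrane, t)
        q_pde = finite_difference_cumulative_amount(membrane, np.array([t]))[0]
        assert q_pde == pytest.approx(q_series, rel=1e-3)

    def test_non_decreasing_in_time(self, lagged_membrane):
        ts = np.linspace(0, 8, 60)
        qs = [true_cumulative_amount(lagged_membrane, t) for t in ts]
        assert np.all(np.diff(qs) >= 0)

    def test_asymptotic_flux_consistency(self, lagged_membrane):
        """dQ/dt is within 1% of K·D·C/h for t ≥ 5·T_lag."""
        tl = lagged_membrane.true_lag_time
        for t in np.linspace(5 * tl, 10 * tl, 5):
            dq = (
                true_cumulative_amount(lagged_membrane, t + 1e-3)
                - true_cumulative_amount(lagged_membrane, t - 1e-3)
            ) / 2e-3
            assert dq == pytest.approx(lagged_membrane.true_flux, rel=1e-2)


class TestSimulateIVPT:
    def test_noiseless_measurements_equal_ledger(self, membrane, protocol):
        sim = simulate_ivpt(membrane, protocol, NoiseModel(0.0, 7), n_replicates=3)
        pre = sim.truth_ledger["conc_pre_draw"].to_numpy()
        for rep in sim.replicates:
            np.testing.assert_array_equal(np.asarray(rep.concentrations), pre)

    def test_same_seed_bit_identical(self, membrane, protocol):
        a = simulate_ivpt(membrane, protocol, NoiseModel(0.03, 42), 4)
        b = simulate_ivpt(membrane, protocol, NoiseModel(0.03, 42), 4)
        for ra, rb in zip(a.replicates, b.replicates):
            assert ra.concentrations == rb.concentrations
        pd.testing.assert_frame_equal(a.truth_ledger, b.truth_ledger)

    def test_ledger_mass_non_decreasing(self, lagged_membrane, protocol):
        sim = simulate_ivpt(lagged_membrane, protocol, NoiseModel(0.03, 1), 1)
        mass = sim.truth_ledger["true_cumulative_ug"].to_numpy()
        assert np.all(np.diff(mass) >= 0)

    def test_mass_conservation_every_draw(self, lagged_membrane, protocol):
        """Permeated mass = mass in receptor + all removed sample masses."""
        sim = simulate_ivpt(lagged_membrane, protocol, NoiseModel(0.0, 1), 1)
        led = sim.truth_ledger
        receptor_mass = led["conc_post_draw"] * protocol.receptor_volume
        np.testing.assert_allclose(
            led["true_cumulative_ug"],
            receptor_mass + led["removed_cumulative_ug"],
            rtol=0,
            atol=1e-10,
        )

    def test_eq1_correction_inverts_sampling(self, lagged_membrane, protocol):
        """Central cross-module check: the sampling correction applied to a
        noiseless simulation reproduces ledger-true Q/area to float precision."""
        sim = simulate_ivpt(lagged_membrane, protocol, NoiseModel(0.0, 0), 2)
        truth = sim.truth_ledger["true_cumulative_ug_per_cm2"].to_numpy()
        for rep in sim.replicates:
            profile = cumulative_permeation(rep, protocol)
            np.testing.assert_allclose(profile.cumulative_q, truth, rtol=1e-12)

    def test_tidy_frame_schema(self, membrane, protocol):
        sim = simulate_ivpt(membrane, protocol, NoiseModel(0.03, 3), 2)
        df = ivpt_to_frame(sim, drug="demo", treatment="control")
        assert list(df.columns) == [
            "replicate",
            "drug",
            "treatment",
            "time_h",
            "conc_ug_per_ml",
        ]
        assert len(df) == 2 * len(protocol.sample_times)

    def test_replicate_count_validated(self, membrane, protocol):
        with pytest.raises(ValueError):
            simulate_ivpt(membrane, protocol, NoiseModel(0.0, 0), 0)


class TestSimulatePartition:
    def test_noiseless_ratio_exact(self):
        truth = PartitionGroundTruth(
            k_true=5.0, vehicle_volume=4.0, total_drug=500.0, noise=NoiseModel(0.0, 0)
        )
        df = simulate_partition(truth, 4)
        ratios = df["c_sc_ug_per_g"] / df["c_vehicle_ug_per_ml"]
        np.testing.assert_allclose(ratios, 5.0, rtol=1e-12)

    def test_unit_ratio_gives_equal_concentrations(self):
        truth = PartitionGroundTruth(
            k_true=1.0, vehicle_volume=4.0, total_drug=100.0, noise=NoiseModel(0.0, 0)
        )
        df = simulate_partition(truth, 2)
        np.testing.assert_allclose(df["c_sc_ug_per_g"], df["c_vehicle_ug_per_ml"])

    def test_parameter_recovery_within_3se(self):
        truth = PartitionGroundTruth(
            k_true=5.0, vehicle_volume=4.0, total_drug=500.0, noise=NoiseModel(0.05, 11)
        )
        df = simulate_partition(truth, 4)
        k = df["c_sc_ug_per_g"] / df["c_vehicle_ug_per_ml"]
        se = k.std(ddof=1) / np.sqrt(len(k))
        assert abs(k.mean() - 5.0) < 3 * se

    def test_invalid_total_drug_rejected(self):
        with pytest.raises(ValueError):
            PartitionGroundTruth(
                k_true=5.0, vehicle_volume=4.0, total_drug=0.0, noise=NoiseModel(0, 0)
            )


class TestEnhancementPanel:
    def test_noiseless_panel_recovers_coefficients_exactly(self):
        panel = generate_enhancement_panel(noise_sd=0.0, seed=3, n_drugs=10)
        res = fit_linear_model(panel.table[["ker", "per"]], panel.table["qer"].to_numpy())
        np.testing.assert_allclose(res.coefficients, panel.qer_coeffs[:2], atol=1e-8)
        assert res.intercept == pytest.approx(panel.qer_coeffs[2], abs=1e-8)
        assert res.multiple_r == pytest.approx(1.0, abs=1e-8)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            generate_enhancement_panel(noise_sd=-0.1)

    def test_too_few_drugs_rejected(self):
        with pytest.raises(ValueError):
            generate_enhancement_panel(n_drugs=3)

    def test_panel_floors_ratios_positive(self):
        panel = generate_enhancement_panel(noise_sd=5.0, seed=0, n_drugs=20)
        assert (panel.table[["ker", "per", "qer"]] > 0).all().all()


def test_tight_protocol_validation():
    with pytest.raises(ValueError):
        DiffusionCellProtocol(sample_volume=5.0)  # larger than receptor
    with pytest.raises(ValueError):
        DiffusionCellProtocol(sample_times=(2, 1))
    with pytest.raises(ValueError):
        MembraneModel(0.0, 1e-4, 0.01, 100.0)
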