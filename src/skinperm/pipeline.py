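"""End-to-end pipeline: simulate → permeation fits → ratios → regressions.

Ties the stages together behind a single YAML-configurable entry point.
All interchange is tidy CSV; one seed in the config drives every source of
randomness, so identical config + seed reproduces every output byte for
byte.  Packaged reference tables (molecular descriptors, solubility
parameters, a published permeation-parameter table and an FTIR peak
table) are available through :func:`load_fixture`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biophys, enhancement, permeation, qspr, synthetic
from .permeation import DiffusionCellProtocol

__all__ = [
    "PipelineConfig",
    "load_fixture",
    "run_pipeline",
    "qer_from_printed_table",
    "default_drug_specs",
    "DrugSpec",
]

log = logging.getLogger("skinperm")

_FIXTURES = {
    "descriptors": "descriptors.csv",
    "solubility": "solubility.csv",
    "permeation_table2": "permeation_table2.csv",
    "ftir_table4": "ftir_table4.csv",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table by name.

    Known names: ``descriptors`` (molecular descriptors of the five model
    drugs), ``solubility`` (total solubility parameters and their gaps to
    ceramide NP), ``permeation_table2`` (published mean ± SD permeation
    parameters), ``ftir_table4`` (CH₂/Amide I peak areas and positions).
    """
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        )
    ref = resources.files("skinperm.data").joinpath(_FIXTURES[name])
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def qer_from_printed_table(table: pd.DataFrame, control_label: str = "control") -> pd.DataFrame:
    """QER per drug × treatment from a mean ± SD permeation table.

    Treats each printed group mean as a single observation and computes the
    ratio of Q at the final time against the control arm, with first-order
    propagated SDs.  Returns drug, treatment, qer, qer_sd.
    """
    rows = []
    for drug, grp in table.groupby("drug", sort=False):
        ctrl = grp[grp["treatment"] == control_label]
        if ctrl.empty:
            raise ValueError(f"no {control_label!r} row for drug {drug!r}")
        ctrl = ctrl.iloc[0]
        for _, row in grp.iterrows():
            if row["treatment"] == control_label:
                continue
            qer = enhancement.enhancement_ratio(row["q8h_mean"], ctrl["q8h_mean"])
            sd = enhancement.ratio_uncertainty(
                row["q8h_mean"], row["q8h_sd"], ctrl["q8h_mean"], ctrl["q8h_sd"]
            )
            rows.append(
                {"drug": drug, "treatment": row["treatment"], "qer": qer, "qer_sd": sd}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugSpec:
    """Ground truth for one simulated drug across treatment arms.

    ``treatments`` maps a treatment label to (membrane partition
    multiplier, diffusivity multiplier, donor concentration in µg/mL,
    SC/vehicle partition multiplier); the control arm has multipliers
    (1, 1, ·, 1).  ``k_partition`` is the control-arm SC/vehicle partition
    ratio used in the partition-experiment simulation, kept separate from
    the membrane partition coefficient because the two experiments probe
    different equilibria.
    """

    name: str
    thickness: float
    diffusivity: float
    partition_k: float
    donor_concentration: float
    treatments: dict[str, tuple[float, float, float, float]]
    k_partition: float = 5.0


@dataclass
class PipelineConfig:
    """Settings for one pipeline run (constructible from YAML).

    When ``input_csv`` is given the simulation stage is skipped and the
    tidy concentration CSV is analyzed directly; otherwise the built-in
    five-drug panel (or ``drugs``) is simulated.
    """

    seed: int = 0
    outdir: str = "skinperm_out"
    protocol: DiffusionCellProtocol = field(default_factory=DiffusionCellProtocol)
    n_replicates: int = 4
    noise_cv: float = 0.03
    min_points: int = 3
    r2_threshold: float = 0.9999
    input_csv: str | None = None
    drugs: list[DrugSpec] | None = None
    control_label: str = "control"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        proto = DiffusionCellProtocol(**raw.pop("protocol", {}))
        drugs = raw.pop("drugs", None)
        if drugs is not None:
            drugs = [
                DrugSpec(
                    name=d["name"],
                    thickness=d["thickness"],
                    diffusivity=d["diffusivity"],
                    partition_k=d["partition_k"],
                    donor_concentration=d["donor_concentration"],
                    treatments={
                        k: tuple(v) for k, v in d["treatments"].items()
                    },
                    k_partition=d.get("k_partition", 5.0),
                )
                for d in drugs
            ]
        if raw.get("input_csv") is not None:
            p = Path(raw["input_csv"])
            if not p.exists():
                raise FileNotFoundError(f"input_csv does not exist: {p}")
        return cls(protocol=proto, drugs=drugs, **raw)

    def config_hash(self) -> str:
        payload = {
            k: (v if not isinstance(v, (DiffusionCellProtocol, list)) else repr(v))
            for k, v in vars(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=repr).encode()
        ).hexdigest()[:16]


def default_drug_specs(
    thickness: float = 0.03,
) -> list[DrugSpec]:
    """Five-drug demo panel anchored to the packaged reference tables.

    For each model drug the control-arm membrane parameters are chosen so
    the analytic flux and lag time match the published control means
    (D = h²/(6·T_lag), K = J_ss·h/(D·C)).  Enhancer arms scale the
    membrane partition coefficient by the descriptor-predicted
    permeability enhancement (so the arm's ground-truth PER follows the
    published linear Δδ model, with lag time unchanged) and scale the
    SC/vehicle partition ratio by the descriptor-predicted partition
    enhancement (so its ground-truth KER follows the published PSA /
    H-bond-donor model).
    """
    table2 = load_fixture("permeation_table2")
    desc = load_fixture("descriptors").set_index("drug")
    sol = load_fixture("solubility").set_index("name")
    ker_coeffs = {"3% PEK": (0.011, 0.234, 1.987), "5% PEK": (0.015, 0.314, 1.042)}
    per_coeffs = {"3% PEK": (0.058, 1.103), "5% PEK": (0.064, 1.119)}

    specs = []
    for drug, grp in table2.groupby("drug", sort=False):
        ctrl = grp[grp["treatment"] == "control"].iloc[0]
        tlag, jss, c0 = ctrl["tlag_mean"], ctrl["jss_mean"], ctrl["c_mean"]
        d0 = thickness**2 / (6.0 * tlag)
        k0 = jss * thickness / (d0 * c0)
        psa, hbd = desc.loc[drug, "psa"], desc.loc[drug, "hbd"]
        ddelta = sol.loc[drug, "delta_diff"]
        treatments: dict[str, tuple[float, float, float, float]] = {
            "control": (1.0, 1.0, float(c0), 1.0)
        }
        for trt in ("3% PEK", "5% PEK"):
            ka, kb, kc = ker_coeffs[trt]
            pa, pc = per_coeffs[trt]
            ker_true = kc + ka * psa + kb * hbd
            per_true = pc + pa * ddelta
            c_trt = float(grp[grp["treatment"] == trt]["c_mean"].iloc[0])
            treatments[trt] = (float(per_true), 1.0, c_trt, float(ker_true))
        specs.append(
            DrugSpec(
                name=drug,
                thickness=thickness,
                diffusivity=float(d0),
                partition_k=float(k0),
                donor_concentration=float(c0),
                treatments=treatments,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def _simulate_panel(config: PipelineConfig) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Simulate every drug × treatment arm; returns (tidy data, solubility map, partition data)."""
    specs = config.drugs if config.drugs is not None else default_drug_specs()
    frames, partition_rows = [], []
    solubility: dict[tuple[str, str], float] = {}
    # derive one child seed per arm from the config seed (kept below 2^31)
    seed_rng = np.random.default_rng(config.seed)
    for spec in specs:
        for trt, (k_mult, d_mult, donor_c, part_mult) in spec.treatments.items():
            arm_seed = int(seed_rng.integers(0, 2**31 - 1))
            model = synthetic.MembraneModel(
                partition_k=spec.partition_k * k_mult,
                diffusivity=spec.diffusivity * d_mult,
                thickness=spec.thickness,
                donor_concentration=donor_c,
            )
            sim = synthetic.simulate_ivpt(
                model,
                config.protocol,
                synthetic.NoiseModel(config.noise_cv, arm_seed),
                config.n_replicates,
            )
            frames.append(synthetic.ivpt_to_frame(sim, drug=spec.name, treatment=trt))
            solubility[(spec.name, trt)] = donor_c

            part_seed = int(seed_rng.integers(0, 2**31 - 1))
            truth = synthetic.PartitionGroundTruth(
                k_true=spec.k_partition * part_mult,
                vehicle_volume=4.0,
                total_drug=1000.0,
                noise=synthetic.NoiseModel(config.noise_cv, part_seed),
            )
            part = synthetic.simulate_partition(truth, config.n_replicates)
            part["drug"] = spec.name
            part["treatment"] = trt
            partition_rows.append(part)
    return pd.concat(frames, ignore_index=True), solubility, pd.concat(
        partition_rows, ignore_index=True
    )


def _partition_summary(partition_data: pd.DataFrame) -> pd.DataFrame:
    part = partition_data.copy()
    part["k"] = [
        enhancement.partition_coefficient(a, b)
        for a, b in zip(part["c_sc_ug_per_g"], part["c_vehicle_ug_per_ml"])
    ]
    return (
        part.groupby(["drug", "treatment"], sort=False)["k"]
        .agg(k_mean="mean", k_sd="std")
        .reset_index()
    )


def _fit_regressions(
    enh: pd.DataFrame, control_label: str
) -> tuple[dict[str, qspr.RegressionResult], pd.DataFrame]:
    """Per-treatment fits: QER~(KER,PER); KER~(PSA,HBD); PER~Δδ."""
    desc = load_fixture("descriptors")[["drug", "psa", "hbd"]]
    sol = load_fixture("solubility").rename(columns={"name": "drug"})[
        ["drug", "delta_diff"]
    ]
    joined = enh.merge(desc, on="drug", how="left").merge(sol, on="drug", how="left")
    joined = joined[joined["treatment"] != control_label]
    results: dict[str, qspr.RegressionResult] = {}
    rows = []
    for trt, grp in joined.groupby("treatment", sort=False):
        fits = {
            "qer_on_ker_per": (grp[["ker", "per"]], grp["qer"]),
            "ker_on_psa_hbd": (grp[["psa", "hbd"]], grp["ker"]),
            "per_on_delta_diff": (grp[["delta_diff"]], grp["per"]),
        }
        for label, (x, y) in fits.items():
            res = qspr.fit_linear_model(x, y.to_numpy())
            results[f"{label}[{trt}]"] = res
            rows.append(
                {
                    "treatment": trt,
                    "model": label,
                    **{f"b_{n}": c for n, c in zip(res.predictor_names, res.coefficients)},
                    "intercept": res.intercept,
                    "multiple_r": res.multiple_r,
                    "p_value": res.p_value,
                    "n": res.n,
                }
            )
    return results, pd.DataFrame(rows)


def _biophys_report() -> pd.DataFrame:
    """FTIR deltas recomputed from the packaged peak table."""
    ftir = load_fixture("ftir_table4")
    rows = []
    for band, grp in ftir.groupby("band", sort=False):
        ctrl = grp[grp["sample"] == "control"].iloc[0]
        for _, row in grp.iterrows():
            if row["sample"] == "control":
                continue
            rec = {"band": band, "sample": row["sample"]}
            if pd.notna(row["peak_area"]) and pd.notna(ctrl["peak_area"]):
                rec["area_decrease_pct"] = biophys.peak_area_decrease(
                    ctrl["peak_area"], row["peak_area"]
                )
            if pd.notna(row["position_cm1"]) and pd.notna(ctrl["position_cm1"]):
                rec["band_shift_cm1"] = biophys.band_shift(
                    ctrl["position_cm1"], row["position_cm1"]
                )
            rows.append(rec)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle to ``config.outdir``.

    Stages: (optional) simulation of permeation + partition experiments,
    per-replicate flux/lag/permeability fits, group summaries, QER/PER/KER
    table, the three descriptor regressions per treatment, and the FTIR
    delta report.  Writes every intermediate table as CSV plus a
    ``summary.json`` and ``run.log``; returns the tables in a dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("seed=%d config_hash=%s", config.seed, config.config_hash())
        log.info(
            "versions numpy=%s pandas=%s scipy=%s",
            np.__version__,
            pd.__version__,
            __import__("scipy").__version__,
        )

        partition_summary = None
        solubility = None
        if config.input_csv is not None:
            series = permeation.read_concentration_csv(config.input_csv)
            tidy = pd.concat(
                [
                    pd.DataFrame(
                        {
                            "replicate": s.replicate_id,
                            "drug": s.drug,
                            "treatment": s.treatment,
                            "time_h": s.times,
                            "conc_ug_per_ml": s.concentrations,
                        }
                    )
                    for s in series
                ],
                ignore_index=True,
            )
        else:
            tidy, solubility, partition_data = _simulate_panel(config)
            partition_data.to_csv(outdir / "partition_data.csv", index=False)
            partition_summary = _partition_summary(partition_data)
            series = None
        tidy.to_csv(outdir / "concentrations.csv", index=False)

        if series is None:
            series = permeation.read_concentration_csv(outdir / "concentrations.csv")
        per_rep = permeation.fit_replicates(
            series,
            config.protocol,
            donor_solubility=solubility,
            min_points=config.min_points,
            r2_threshold=config.r2_threshold,
        )
        per_rep.to_csv(outdir / "permeation_parameters.csv", index=False)
        groups = permeation.summarize_groups(per_rep)
        groups.to_csv(outdir / "group_summary.csv", index=False)

        enh = enhancement.enhancement_table(
            groups, partition_summary, control_label=config.control_label
        )
        enh.to_csv(outdir / "enhancement_table.csv", index=False)

        reg_results, reg_table = _fit_regressions(enh, config.control_label)
        reg_table.to_csv(outdir / "regressions.csv", index=False)

        # response-surface grid for the QER model of each treatment
        for key, res in reg_results.items():
            if not key.startswith("qer_on_ker_per"):
                continue
            trt = key.split("[")[1].rstrip("]")
            sub = enh[enh["treatment"] == trt]
            grid = qspr.response_surface(
                res,
                {
                    "ker": (sub["ker"].min(), sub["ker"].max()),
                    "per": (sub["per"].min(), sub["per"].max()),
                },
            )
            safe = trt.replace("%", "pct").replace(" ", "_")
            grid.to_csv(outdir / f"qer_surface_{safe}.csv", index=False)

        bio = _biophys_report()
        bio.to_csv(outdir / "biophys_deltas.csv", index=False)

        summary = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_series": len(series),
            "enhancement": enh.round(6).to_dict(orient="records"),
            "regressions": reg_table.round(6).to_dict(orient="records"),
            "biophys": bio.round(6).to_dict(orient="records"),
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, allow_nan=True)
        )
        log.info("pipeline complete: %s", outdir)
        return {
            "per_replicate": per_rep,
            "group_summary": groups,
            "enhancement": enh,
            "regressions": reg_table,
            "regression_results": reg_results,
            "biophys": bio,
            "summary": summary,
        }
    finally:
        log.removeHandler(handler)
        handler.close()
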