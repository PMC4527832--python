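"""End-to-end vulnerability pipeline: generate -> fit -> classify ->
project -> summarize.

Stages communicate only through files in the output directory, so any
stage can be rerun from saved intermediates with identical results:

    a. generate            reach_table.csv, daily_series.csv,
                           site_truth.csv, anc_truth.csv
    b. fit-thermal         thermal_model.txt, jmmst_contemporary.csv
    c. fit-sensitivity     logistic_model.txt, beta_model.txt,
                           site_betas.csv, sensitivity_results.csv
       fit-anc             anc_gate_model.txt, anc_linear_model.txt,
                           recalibration.csv, anc_results.csv
    d. project + summarize jmmst_delta*.csv, habitat_*.csv,
                           habitat_changes_*.csv

All randomness descends from the generator seed; a rerun with the same
config is byte-identical for every data output.  A run manifest records
the seed, config hash, stage timings, and headline model diagnostics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acidbase, habitat, sensitivity, synthetic_data, thermal
from .habitat import HabitatThresholds
from .sensitivity import HIGH, LOW, Scenario
from .stream_network import StreamNetwork, validate
from .synthetic_data import GeneratorConfig, ANCProfile

log = logging.getLogger("coldwater")

DEFAULT_THERMAL_CANDIDATES = (
    "JMMAT", "WSAREA", "LITHCAR", "BFI", "CCRIP", "PPTJUL", "LITHSIL", "TWI",
)
DEFAULT_LOGISTIC_TERMS = ("WSAREA", "LITHCAR", "EVHRIP")
DEFAULT_BETA_TERMS = ("BFI", "WSAREA", "LITHSIL", "TWI", "LITHCAR")
DEFAULT_ANC_TERMS = ("JMMAT", "LITHCAR", "LITHSIL", "BFI")


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    thresholds: HabitatThresholds = field(default_factory=HabitatThresholds)
    scenarios: tuple[float, ...] = (0.0, 2.0, 4.0)
    beta_threshold: float = sensitivity.BETA_THRESHOLD
    logistic_cutoff: float = 0.50
    anc_gate: float = acidbase.ANC_GATE_UEQ_L
    recalibration_pivot: float = acidbase.RECAL_PIVOT_UEQ_L
    output_dir: str = "coldwater_out"
    thermal_candidates: tuple[str, ...] = DEFAULT_THERMAL_CANDIDATES
    logistic_terms: tuple[str, ...] = DEFAULT_LOGISTIC_TERMS
    beta_terms: tuple[str, ...] = DEFAULT_BETA_TERMS
    anc_terms: tuple[str, ...] = DEFAULT_ANC_TERMS
    n_anc_calibration: int = 500

    def __post_init__(self) -> None:
        self.scenarios = tuple(float(d) for d in self.scenarios)
        if not self.scenarios or 0.0 not in self.scenarios:
            raise ValueError("scenario list must be nonempty and include 0")
        if any(d < 0 for d in self.scenarios):
            raise ValueError("scenario deltas must be >= 0")
        for name in ("beta_threshold", "logistic_cutoff", "anc_gate",
                     "recalibration_pivot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # ---- yaml round trip -------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = dict(d.pop("generator", {}))
        if "anc_elevation_profile" in gen and isinstance(
            gen["anc_elevation_profile"], dict
        ):
            gen["anc_elevation_profile"] = ANCProfile(
                **gen["anc_elevation_profile"]
            )
        for key in ("elevation_range_m", "beta_range"):
            if key in gen:
                gen[key] = tuple(gen[key])
        thr = dict(d.pop("thresholds", {}))
        for key in ("scenarios", "thermal_candidates", "logistic_terms",
                    "beta_terms", "anc_terms"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(
            generator=GeneratorConfig(**gen),
            thresholds=HabitatThresholds(**thr),
            **d,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------

def stage_generate(config: PipelineConfig, outdir: Path) -> dict:
    network = synthetic_data.generate_network(config.generator)
    diag = validate(network)
    if not diag.ok:
        raise ValueError(
            f"generated network failed validation: {diag}"
        )
    synthetic_data.generate_covariates(network, config.generator)
    anc_truth = synthetic_data.generate_anc_truth(network, config.generator)
    series, truth = synthetic_data.generate_daily_series(
        network, config.generator
    )
    network.to_csv(outdir / "reach_table.csv")
    synthetic_data.series_to_frame(series).to_csv(
        outdir / "daily_series.csv", index=False
    )
    truth.to_csv(outdir / "site_truth.csv", index=False)
    anc_truth.to_frame().to_csv(outdir / "anc_truth.csv")
    return {"n_reaches": len(network), "n_sites": len(series)}


def _load_covariates(outdir: Path) -> tuple[StreamNetwork, pd.DataFrame]:
    network = StreamNetwork.read_csv(outdir / "reach_table.csv")
    cov = network.to_frame().set_index("reach_id")
    return network, cov


def stage_fit_thermal(config: PipelineConfig, outdir: Path) -> dict:
    network, cov = _load_covariates(outdir)
    series = synthetic_data.series_from_frame(
        pd.read_csv(outdir / "daily_series.csv")
    )
    truth = pd.read_csv(outdir / "site_truth.csv").set_index("site_id")

    jmmst_obs = np.array([s.july_mean_mdst() for s in series])
    site_cov = cov.loc[[int(truth.loc[s.site_id, "reach_id"]) for s in series]]
    site_cov = site_cov.reset_index(drop=True)

    model = thermal.select_model(
        jmmst_obs, site_cov, list(config.thermal_candidates)
    )
    model.to_text(outdir / "thermal_model.txt")
    pred = thermal.predict_jmmst(model, cov)
    pd.DataFrame({"reach_id": cov.index, "jmmst_c": pred}).to_csv(
        outdir / "jmmst_contemporary.csv", index=False
    )
    return {"terms": model.terms, "r2": model.r2, "rmse": model.rmse}


def stage_fit_sensitivity(config: PipelineConfig, outdir: Path) -> dict:
    network, cov = _load_covariates(outdir)
    series = synthetic_data.series_from_frame(
        pd.read_csv(outdir / "daily_series.csv")
    )
    truth = pd.read_csv(outdir / "site_truth.csv").set_index("site_id")

    beta_obs = np.array([sensitivity.estimate_beta(s) for s in series])
    classes = np.array(
        [sensitivity.classify_observed(b, config.beta_threshold)
         for b in beta_obs]
    )
    site_reach = np.array([int(truth.loc[s.site_id, "reach_id"]) for s in series])
    site_cov = cov.loc[site_reach].reset_index(drop=True)
    site_df = pd.DataFrame(
        {
            "site_id": [s.site_id for s in series],
            "reach_id": site_reach,
            "beta_observed": beta_obs,
            "sensitivity_class": classes,
        }
    )
    site_df.to_csv(outdir / "site_betas.csv", index=False)

    labels = (classes == HIGH).astype(int)
    logistic = sensitivity.fit_logistic(
        labels, site_cov, list(config.logistic_terms),
        cutoff=config.logistic_cutoff,
    )
    _logistic_to_text(logistic, outdir / "logistic_model.txt")
    site_pred = sensitivity.classify_predicted(logistic, site_cov)
    conf = sensitivity.confusion_summary(
        classes, site_pred["sensitivity_class"].to_numpy()
    )

    high_mask = classes == HIGH
    beta_model = sensitivity.fit_beta_model(
        beta_obs[high_mask], site_cov[high_mask],
        list(config.beta_terms), threshold=config.beta_threshold,
    )
    beta_model.to_text(outdir / "beta_model.txt")

    reach_pred = sensitivity.classify_predicted(logistic, cov)
    beta_hat = np.clip(beta_model.predict(cov), 0.0, None)
    beta_hat = np.where(
        reach_pred["sensitivity_class"] == HIGH, beta_hat, np.nan
    )
    out = pd.DataFrame(
        {
            "reach_id": cov.index,
            "p_high": reach_pred["p_high"].to_numpy(),
            "sensitivity_class": reach_pred["sensitivity_class"].to_numpy(),
            "beta_predicted": beta_hat,
        }
    )
    out.to_csv(outdir / "sensitivity_results.csv", index=False)
    return {
        "n_high_sites": int(high_mask.sum()),
        "n_low_sites": int((~high_mask).sum()),
        "overall_pct_correct": conf.overall_pct,
        "beta_model_r2": beta_model.r2,
        "frac_reaches_high": float(
            (reach_pred["sensitivity_class"] == HIGH).mean()
        ),
    }


def stage_fit_anc(config: PipelineConfig, outdir: Path) -> dict:
    network, cov = _load_covariates(outdir)
    anc_truth = pd.read_csv(outdir / "anc_truth.csv").set_index("reach_id")[
        "anc_ueq_l"
    ]
    # "measured" chemistry sites: a seeded uniform sample of reaches
    rng = np.random.default_rng(
        np.random.SeedSequence([config.generator.seed, 4])
    )
    n_cal = min(config.n_anc_calibration, len(cov))
    cal_ids = np.sort(rng.choice(cov.index.to_numpy(), n_cal, replace=False))
    cal_cov = cov.loc[cal_ids]
    cal_anc = anc_truth.loc[cal_ids]

    labels = (cal_anc > config.anc_gate).astype(int)
    gate = sensitivity.fit_logistic(
        labels, cal_cov, list(config.anc_terms), cutoff=0.50
    )
    _logistic_to_text(gate, outdir / "anc_gate_model.txt")

    low_mask = cal_anc <= config.anc_gate
    linear = thermal.fit_ols(
        cal_anc[low_mask], cal_cov[low_mask.to_numpy()],
        list(config.anc_terms),
    )
    linear.to_text(outdir / "anc_linear_model.txt")

    cal_raw = linear.predict(cal_cov[low_mask.to_numpy()])
    recal = acidbase.fit_recalibration(
        cal_raw, cal_anc[low_mask].to_numpy(),
        pivot=config.recalibration_pivot,
    )
    pd.DataFrame(
        {"knot_raw": recal.knots_x, "knot_corrected": recal.knots_y}
    ).to_csv(outdir / "recalibration.csv", index=False)

    cls = acidbase.classify_anc(gate, cov)
    low_ids = cls.index[cls == acidbase.LOW]
    raw = acidbase.estimate_anc_low(linear, cov.loc[low_ids])
    corrected = acidbase.apply_recalibration(recal, raw)
    res = pd.DataFrame(
        {"reach_id": cov.index, "anc_class": cls.to_numpy()}
    ).set_index("reach_id")
    res["anc_raw"] = np.nan
    res.loc[low_ids, "anc_raw"] = raw
    res["anc_corrected"] = np.nan
    res.loc[low_ids, "anc_corrected"] = corrected
    # value used by habitat accounting: high-class reaches sit above the
    # 300 ueq/L gate, hence above any acidity threshold
    res["anc_habitat_ueq_l"] = res["anc_corrected"].fillna(config.anc_gate)
    res.to_csv(outdir / "anc_results.csv")

    err = acidbase.stratified_rmse(
        cal_anc[low_mask].to_numpy(),
        acidbase.apply_recalibration(recal, cal_raw),
    )
    return {
        "n_calibration": int(n_cal),
        "n_low_class": int(len(low_ids)),
        **err,
    }


def stage_project(config: PipelineConfig, outdir: Path) -> dict:
    jmmst = pd.read_csv(outdir / "jmmst_contemporary.csv").set_index("reach_id")
    sens = pd.read_csv(outdir / "sensitivity_results.csv").set_index("reach_id")
    sens = sens.loc[jmmst.index]
    info = {}
    for delta in config.scenarios:
        future = sensitivity.project_future(
            jmmst["jmmst_c"].to_numpy(),
            sens["sensitivity_class"].to_numpy(),
            sens["beta_predicted"].to_numpy(),
            Scenario(delta),
        )
        pd.DataFrame({"reach_id": jmmst.index, "jmmst_c": future}).to_csv(
            outdir / f"jmmst_delta{delta:g}.csv", index=False
        )
        info[f"mean_increase_delta{delta:g}"] = float(
            np.mean(future - jmmst["jmmst_c"].to_numpy())
        )
    return info


def stage_summarize(config: PipelineConfig, outdir: Path) -> dict:
    network = StreamNetwork.read_csv(outdir / "reach_table.csv")
    anc = pd.read_csv(outdir / "anc_results.csv").set_index("reach_id")[
        "anc_habitat_ueq_l"
    ]
    summaries: dict[float, dict[str, pd.DataFrame]] = {}
    for delta in config.scenarios:
        jmmst = pd.read_csv(outdir / f"jmmst_delta{delta:g}.csv").set_index(
            "reach_id"
        )["jmmst_c"]
        summaries[delta] = {}
        for level in ("district", "forest"):
            df = habitat.summarize(
                network, jmmst, anc, config.thresholds, unit_level=level
            )
            df.to_csv(outdir / f"habitat_{level}_delta{delta:g}.csv")
            summaries[delta][level] = df
    for level in ("district", "forest"):
        frames = []
        for delta in config.scenarios:
            if delta == 0.0:
                continue
            chg = habitat.compare_scenarios(
                summaries[0.0][level], summaries[delta][level]
            )
            chg.insert(0, "delta_mdat_c", delta)
            frames.append(chg)
        if frames:
            pd.concat(frames).to_csv(outdir / f"habitat_changes_{level}.csv")
    base = summaries[0.0]["forest"].loc["TOTAL"]
    return {
        "suitable_pct_baseline": float(base["suitable_pct"]),
        "total_km": float(base["total_km"]),
    }


_STAGES = (
    ("generate", stage_generate),
    ("fit-thermal", stage_fit_thermal),
    ("fit-sensitivity", stage_fit_sensitivity),
    ("fit-anc", stage_fit_anc),
    ("project", stage_project),
    ("summarize", stage_summarize),
)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the manifest dict (also written
    to ``run_manifest.json``)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.generator.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    config.to_yaml(outdir / "config_used.yaml")
    for name, fn in _STAGES:
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        try:
            info = fn(config, outdir)
        except Exception as exc:  # annotate with the failing stage
            raise StageError(name, exc) from exc
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            **info,
        }
        log.info("stage %s done in %.2fs", name,
                 manifest["stages"][name]["seconds"])
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _logistic_to_text(model: sensitivity.LogisticModelSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"intercept\t{model.intercept!r}\n")
        fh.write(f"cutoff\t{model.cutoff!r}\n")
        fh.write(f"orientation\t{model.orientation}\n")
        fh.write(f"converged\t{model.converged}\n")
        fh.write(f"separation_flag\t{model.separation_flag}\n")
        for term, coef in model.coefficients.items():
            p = model.p_values.get(term, float("nan"))
            fh.write(f"term\t{term}\t{coef!r}\t{p!r}\n")


def logistic_from_text(path) -> sensitivity.LogisticModelSpec:
    scalars: dict[str, str] = {}
    coefficients: dict[str, float] = {}
    p_values: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "term":
                _, term, coef, p = parts
                coefficients[term] = float(coef)
                p_values[term] = float(p)
            else:
                scalars[parts[0]] = parts[1]
    return sensitivity.LogisticModelSpec(
        intercept=float(scalars["intercept"]),
        coefficients=coefficients,
        cutoff=float(scalars["cutoff"]),
        orientation=scalars["orientation"],
        p_values=p_values,
        converged=scalars["converged"] == "True",
        separation_flag=scalars["separation_flag"] == "True",
    )
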