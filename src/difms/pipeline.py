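"""End-to-end orchestration: simulate → stitch → preprocess → stats →
univariate → annotate → carbonate, from one structured configuration.

The configuration is a nested mapping (typically loaded from YAML) whose
sections mirror the stage modules; unknown keys are rejected so that typos
fail fast. One global seed fans out deterministically to per-stage child
seeds, and the resolved configuration is written beside the outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import carbonate as carb
from . import multivariate as mv
from . import preprocess as pp
from . import sim_stitch as st
from . import synthetic_data as syn
from . import univariate as uv
from .spectra_io import write_matrix

log = logging.getLogger(__name__)

_SCHEMA: dict[str, set[str] | None] = {
    "seed": None,
    "outdir": None,
    "extract": None,
    "simulate": {"n_reps", "n_qc", "groups", "ppm_error_sd", "n_tech_reps",
                 "intensity_cv", "dilution_sd", "dropout_threshold",
                 "effect_seed"},
    "stitch": {"edge_trim", "replicate_ppm", "min_reps", "align_ppm",
               "min_sample_frac"},
    "preprocess": {"knn_k", "glog_lambda", "lambda_bounds"},
    "stats": {"n_folds", "n_perm", "max_lv"},
    "univariate": {"equal_var", "q_threshold"},
    "annotate": {"tol_ppm", "max_features"},
    "carbonate": {"conditions"},
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "difms_out",
    "extract": "polar",
    "simulate": {"n_reps": 10, "n_qc": 2, "ppm_error_sd": 0.5,
                 "n_tech_reps": 3, "intensity_cv": 0.2, "dilution_sd": 0.3,
                 "dropout_threshold": 2000.0},
    "stitch": {},
    "preprocess": {"knn_k": 5, "glog_lambda": "optimize"},
    "stats": {"n_folds": 7, "n_perm": 999, "max_lv": 5},
    "univariate": {"equal_var": False, "q_threshold": 0.05},
    "annotate": {"tol_ppm": 1.0, "max_features": 20},
    "carbonate": {"conditions": []},
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Merge user config over the defaults, rejecting unknown keys."""
    merged = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    for key, value in (config or {}).items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown configuration key {key!r}")
        allowed = _SCHEMA[key]
        if allowed is None:
            merged[key] = value
        else:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            for sub in value:
                if sub not in allowed:
                    raise ConfigError(f"unknown key {key}.{sub}")
            merged[key].update(value)
    return merged


def run_pipeline(config: dict | None = None,
                 outdir: str | Path | None = None,
                 seed: int | None = None) -> dict:
    """Execute every stage in order; returns the machine-readable report."""
    cfg = validate_config(config or {})
    if outdir is not None:
        cfg["outdir"] = str(outdir)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    children = np.random.SeedSequence(cfg["seed"]).spawn(2)
    sim_seed = int(children[0].generate_state(1)[0] % (2 ** 31))
    perm_rng = np.random.default_rng(children[1])
    report: dict = {"seed": cfg["seed"], "stages": {}}
    extract = cfg["extract"]

    stage = "simulate"
    try:
        sim_cfg = cfg["simulate"]
        library = syn.default_library()
        effects = syn.default_effect_model(
            library, seed=sim_cfg.get("effect_seed", sim_seed),
            intensity_cv=sim_cfg["intensity_cv"],
            dilution_sd=sim_cfg["dilution_sd"],
            dropout_threshold=sim_cfg["dropout_threshold"])
        windows = (syn.polar_windows() if extract == "polar"
                   else syn.nonpolar_windows())
        acq = syn.AcquisitionConfig(windows=windows,
                                    ppm_error_sd=sim_cfg["ppm_error_sd"],
                                    n_tech_reps=sim_cfg["n_tech_reps"],
                                    seed=sim_seed)
        design = syn.build_design(sim_cfg["n_reps"],
                                  sim_cfg.get("groups"), sim_cfg["n_qc"])
        exp = syn.simulate_peaklists(library, effects, acq, design, extract)
        syn.write_experiment(exp, out / "peaklists")
        report["stages"][stage] = {
            "n_samples": int(len(design)),
            "n_biological": int((~design["qc"]).sum()),
            "n_peaklists": len(exp.peaklists),
        }

        stage = "stitch"
        stitch_cfg = st.StitchConfig(**cfg["stitch"])
        window_ids = [f"w{i:02d}" for i in range(len(windows))]
        filtered = []
        for sid in design["sample_id"]:
            stitched_reps = []
            for r in range(1, acq.n_tech_reps + 1):
                rid = f"tr{r}"
                pls = [exp.peaklists[(sid, rid, w)] for w in window_ids]
                stitched_reps.append(st.stitch_windows(pls, windows, stitch_cfg))
            filtered.append(st.replicate_filter(stitched_reps, stitch_cfg))
        groups = dict(zip(design["sample_id"], design["group"]))
        fm = st.align_features(filtered, stitch_cfg, groups)
        write_matrix(fm, out / "feature_matrix.csv")
        report["stages"][stage] = {"n_features": fm.n_features,
                                   "n_samples": fm.n_samples}

        stage = "preprocess"
        qc_ids = list(design.loc[design["qc"], "sample_id"])
        pp_cfg = pp.PreprocessConfig(**cfg["preprocess"])
        result = pp.preprocess(fm, pp_cfg, qc_ids=qc_ids or None)
        write_matrix(result.matrix, out / "transformed_matrix.csv")
        imputed = result.provenance["imputed_matrix"]
        write_matrix(imputed, out / "normalized_matrix.csv")
        pd.DataFrame({"sample_id": fm.sample_ids,
                      "dilution_factor": result.dilution_factors}
                     ).to_csv(out / "dilution_factors.csv", index=False)
        report["stages"][stage] = {"lambda": result.lambda_used}

        stage = "stats"
        bio = design[~design["qc"]]
        bio_ids = list(bio["sample_id"])
        X = result.matrix.subset_samples(bio_ids)
        labels = bio["timepoint"].to_numpy()
        pca = mv.run_pca(X, groups=bio["group"].to_numpy())
        pd.DataFrame(pca.scores, index=bio_ids).to_csv(out / "pca_scores.csv")
        s_cfg = cfg["stats"]
        model = mv.plsda_analysis(X, labels, max_lv=s_cfg["max_lv"],
                                  n_folds=s_cfg["n_folds"],
                                  n_perm=s_cfg["n_perm"], seed=perm_rng)
        report["stages"][stage] = {
            "pc1_pct_variance": float(pca.pct_variance[0]),
            "pc1_anova_p": pca.pc_tests[0]["anova_p"] if pca.pc_tests else None,
            "plsda_contrast": "t0 vs t5",
            "n_lv": model.n_lv,
            "cv_error_pct": model.cv_error,
            "perm_p": model.perm_p,
            "n_important_signals": int(model.important_signals.size),
        }

        stage = "univariate"
        u_cfg = cfg["univariate"]
        imputed_bio = imputed.subset_samples(bio_ids)
        uni = uv.compare_groups(imputed_bio, labels, "t0", "t5",
                                equal_var=u_cfg["equal_var"])
        uni.table.to_csv(out / "univariate.csv", index=False)
        sig = uni.significant(u_cfg["q_threshold"])
        report["stages"][stage] = {"n_significant": int(sig.size)}

        stage = "annotate"
        a_cfg = cfg["annotate"]
        table = ann.load_compound_table()
        rows = []
        ranked = uni.table.iloc[np.argsort(uni.table["q"].to_numpy(),
                                           kind="stable")]
        for _, r in ranked.head(a_cfg["max_features"]).iterrows():
            cands = ann.enumerate_formulas(r["feature_mz"],
                                           tol_ppm=a_cfg["tol_ppm"])
            ann.match_database(cands, table)
            for c in cands[:5]:
                rows.append({"feature_mz": r["feature_mz"], "q": r["q"],
                             "formula": ann.format_formula(c.formula),
                             "adduct": c.adduct.name,
                             "ppm_error": c.ppm_error,
                             "db_hits": ";".join(c.db_hits)})
        pd.DataFrame(rows).to_csv(out / "annotations.csv", index=False)
        report["stages"][stage] = {"n_annotated_features": int(
            len({row["feature_mz"] for row in rows}))}

        stage = "carbonate"
        carb_rows = []
        for cond in cfg["carbonate"]["conditions"]:
            state = carb.solve_from_ph_pco2(carb.CarbonateInput(**cond))
            carb_rows.append({**cond, "ta_umol_kg": state.ta,
                              "omega_ar": state.omega_ar,
                              "omega_cal": state.omega_cal,
                              "dic_umol_kg": state.dic * 1e6})
        if carb_rows:
            pd.DataFrame(carb_rows).to_csv(out / "carbonate.csv", index=False)
        report["stages"][stage] = {"n_conditions": len(carb_rows)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
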