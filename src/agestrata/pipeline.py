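"""End-to-end orchestration: coding -> LCA composites -> OLS/PSM -> MAIHDA.

A single :class:`PipelineConfig` drives the whole analysis from either a
raw survey CSV (with a column-mapping block translating arbitrary
headers) or a named synthetic preset. Stages run in order; each stage's
tables are written as CSV and collected into a JSON-serializable
:class:`RunReport`.

Listwise deletion happens once, after coding, separately per analysis:
the regression uses income and therefore a smaller analysis sample,
while the intersectional models do not use income directly (it enters
only through the latent SES class, where missingness is an explicit
indicator level) and keep the full coded sample.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lca, maihda, regression_psm, scoring, synthetic

__all__ = ["PipelineConfig", "RunReport", "read_survey", "run_pipeline", "write_report"]

logger = logging.getLogger(__name__)

RAW_REQUIRED_COLUMNS = [
    "id", "gender", "age", "married", "hukou", "education_raw", "income_rmb",
    "self_rated_health_raw", "cesd_total", "iadl_score",
    "parent_care_hours", "grandchild_care_any", "housework_freq",
] + [f"sp_{nm}" for nm in scoring.SP_ITEM_NAMES]


@dataclass
class PipelineConfig:
    """Everything one run needs. Exactly one of ``input_path`` / ``preset``."""

    input_path: str | None = None
    preset: str | None = None
    n_override: int | None = None  # preset sample-size override
    column_mapping: dict = field(default_factory=dict)  # canonical -> file header
    cesd_cuts: tuple = (10, 18)
    income_cuts: tuple = (2300.0, 5000.0, 10000.0)
    standardize_outcome: bool = True
    fp_fixed_coding: str = "binary"  # fixed-effect FP contrast in the main model
    lca_max_classes: int = 3
    lca_n_starts: int = 20
    psm_k: int = 1
    psm_bandwidth: float = 0.06
    psm_caliper: float | None = None
    psm_n_boot: int = 200
    mcmc_warmup: int = 5000
    mcmc_total: int = 10000
    mcmc_chains: int = 2
    outdir: str = "agestrata_out"
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.preset is None):
            raise ValueError("set exactly one of input_path / preset")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mcmc_warmup" not in d or "mcmc_total" not in d:
            logger.info("MCMC settings not fully specified; using defaults 5000 warmup / 10000 total")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def coding_config(self) -> scoring.CodingConfig:
        return scoring.CodingConfig(
            cesd_cuts=tuple(self.cesd_cuts), income_cuts=tuple(self.income_cuts)
        )

    def mcmc_settings(self) -> maihda.MCMCSettings:
        return maihda.MCMCSettings(
            warmup=self.mcmc_warmup, total=self.mcmc_total,
            n_chains=self.mcmc_chains, seed=self.seed,
        )


@dataclass
class RunReport:
    """Per-stage status, headline numbers and tables of one run."""

    config: dict
    stages: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)  # name -> DataFrame

    def to_json_dict(self) -> dict:
        return {"config": _jsonable(self.config), "stages": _jsonable(self.stages)}


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        return float(x)
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, (np.bool_, bool)):
        return bool(x)
    if isinstance(x, np.ndarray):
        return _jsonable(x.tolist())
    if x is None or isinstance(x, str):
        return x
    return str(x)


# ---------------------------------------------------------------------------
# Input
# ---------------------------------------------------------------------------

def read_survey(
    path: str | Path, column_mapping: dict | None = None
) -> tuple[pd.DataFrame, dict]:
    """Read a raw survey CSV, remap headers, validate value domains.

    ``column_mapping`` maps canonical names to the file's headers.
    Rows violating a range rule (CES-D outside 0-27, IADL outside 0-10,
    non-binary activity items, age < 60, negative care hours) are dropped
    and counted in the returned validation report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    mapping = {v: k for k, v in (column_mapping or {}).items()}
    df = df.rename(columns=mapping)
    missing = [c for c in RAW_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"missing required columns {missing}; available: {sorted(df.columns)}; "
            "use the column_mapping config block to translate headers"
        )
    df = df[RAW_REQUIRED_COLUMNS].copy()

    n_in = len(df)
    ok = (
        df["cesd_total"].between(0, 27)
        & df["iadl_score"].between(0, 10)
        & (df["age"] >= 60)
        & (df["parent_care_hours"] >= 0)
        & df["gender"].isin(["male", "female"])
        & df["hukou"].isin(["agricultural", "nonagricultural"])
        & df["education_raw"].isin(scoring.EDU_LEVELS)
        & df["self_rated_health_raw"].isin(scoring.SRH_LEVELS)
        & df["housework_freq"].isin(scoring.HOUSEWORK_LEVELS)
    )
    for nm in scoring.SP_ITEM_NAMES:
        ok &= df[f"sp_{nm}"].isin([0, 1])
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("read_survey rejected %d invalid rows (of %d)", n_rejected, n_in)
    df = df.loc[ok].reset_index(drop=True)
    report = {
        "n_read": n_in,
        "n_rejected": n_rejected,
        "n_kept": len(df),
        "missing_per_column": {c: int(df[c].isna().sum()) for c in df.columns},
    }
    return df, report


_PRESETS = {"paper_like": synthetic.paper_like_scenario}


def _load_data(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    if config.preset is not None:
        if config.preset not in _PRESETS:
            raise ValueError(f"unknown preset {config.preset!r}; have {sorted(_PRESETS)}")
        overrides = {"seed": config.seed}
        if config.n_override is not None:
            overrides["n"] = config.n_override
        params = _PRESETS[config.preset](**overrides)
        raw, _truth = synthetic.generate_survey(params)
        return raw, {"source": f"preset:{config.preset}", "n_read": len(raw),
                     "n_rejected": 0, "n_kept": len(raw)}
    raw, rep = read_survey(config.input_path, config.column_mapping)
    rep["source"] = str(config.input_path)
    return raw, rep


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _fit_lca_composite(
    data: np.ndarray, config: PipelineConfig, seed: int
) -> tuple[lca.LCAFit, pd.DataFrame, int]:
    fits = [
        lca.em_fit(
            data,
            lca.LCASpec(n_classes=k, n_starts=config.lca_n_starts, seed=seed + k),
        )
        for k in range(1, config.lca_max_classes + 1)
    ]
    chosen = lca.select_k(fits)
    table = lca.comparison_table(fits)
    fit = next(f for f in fits if f.n_classes == chosen)
    if chosen != 2:
        # the composite indices are binary by design; fall back to K=2
        logger.warning("BIC chose K=%d; composite uses the K=2 fit", chosen)
        fit = next(f for f in fits if f.n_classes == 2)
    return fit, table, chosen


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage in order and assemble the report.

    Identical config and seed give an identical report (all stage seeds
    derive from ``config.seed``).
    """
    logging.basicConfig(level=logging.DEBUG if config.verbose else logging.INFO)
    report = RunReport(config=dataclasses.asdict(config))

    logger.info("=== stage: data ===")
    raw, data_rep = _load_data(config)
    report.stages["data"] = data_rep
    if len(raw) == 0:
        raise RuntimeError("data stage produced no records")

    logger.info("=== stage: coding ===")
    coded = scoring.code_records(raw, config.coding_config())
    report.tables["coded"] = coded
    report.stages["coding"] = {
        "n": len(coded),
        "sp_score_mean": float(coded["sp_score"].mean()),
        "sp_score_sd": float(coded["sp_score"].std(ddof=1)),
        "fp_counts": coded["fp_category"].value_counts().sort_index().tolist(),
        "n_missing_income": int(coded["income_code"].isna().sum()),
    }

    logger.info("=== stage: lca (health) ===")
    health_data = coded[["srh_code", "dep_code", "iadl_code"]].to_numpy()
    fit_h, table_h, chosen_h = _fit_lca_composite(health_data, config, config.seed + 101)
    coded["health_class"] = lca.modal_assignment(fit_h, ("healthy", "unhealthy"), better="lower")
    report.tables["lca_health_comparison"] = table_h
    report.stages["lca_health"] = {
        "selected_k": chosen_h,
        "class_weights": fit_h.class_weights.tolist(),
        "n_healthy": int((coded["health_class"] == "healthy").sum()),
    }

    logger.info("=== stage: lca (ses) ===")
    # missing income becomes an explicit fifth indicator level so every
    # respondent is classified (no imputation)
    income_ind = (coded["income_code"].astype("float") - 1).fillna(4).astype(int)
    ses_data = np.column_stack(
        [coded["hukou_code"].to_numpy() - 1, coded["edu_code"].to_numpy() - 1, income_ind]
    )
    fit_s, table_s, chosen_s = _fit_lca_composite(ses_data, config, config.seed + 202)
    # neutral score for the "missing" income level keeps class orientation
    # driven by the substantive levels
    ses_scores = [np.array([0.0, 1.0]), np.arange(4.0), np.array([0.0, 1.0, 2.0, 3.0, 1.5])]
    coded["ses_class"] = lca.modal_assignment(
        fit_s, ("high", "low"), better="higher", level_scores=ses_scores
    )
    report.tables["lca_ses_comparison"] = table_s
    report.stages["lca_ses"] = {
        "selected_k": chosen_s,
        "class_weights": fit_s.class_weights.tolist(),
        "n_high_ses": int((coded["ses_class"] == "high").sum()),
    }

    logger.info("=== stage: regression ===")
    Xreg = pd.DataFrame(
        {
            "fp_category": coded["fp_category"],
            "male": (coded["gender"] == "male").astype(float),
            "age": coded["age"].astype(float),
            "married": coded["married"].astype(float),
            "edu_code": coded["edu_code"].astype(float),
            "hukou_code": coded["hukou_code"].astype(float),
            "income_code": coded["income_code"].astype("float"),
            "srh_code": coded["srh_code"].astype(float),
            "iadl_code": coded["iadl_code"].astype(float),
        }
    )
    ols = regression_psm.fit_ols(coded["sp_score"].astype(float), Xreg)
    report.tables["regression"] = ols.table().reset_index(names="term")
    report.stages["regression"] = {
        "n_used": ols.n_used,
        "r_squared": ols.r_squared,
        "fp_coefficient": float(ols.params["fp_category"]),
        "fp_p_value": float(ols.pvalues["fp_category"]),
    }

    logger.info("=== stage: psm ===")
    treatment = (coded["fp_category"] >= 1).astype(int).to_numpy()
    Xps = Xreg.drop(columns=["fp_category", "income_code"])
    ps = regression_psm.fit_logit(treatment, Xps.to_numpy())
    y = coded["sp_score"].astype(float).to_numpy()
    att_rows, bal_rows = [], []
    psm_stage = {}
    matchers = {
        "nn_k1": lambda p, t: regression_psm.match_nn(
            p, t, k=config.psm_k, caliper=config.psm_caliper
        ),
        "kernel": lambda p, t: regression_psm.match_kernel(
            p, t, bandwidth=config.psm_bandwidth
        ),
    }
    for method, matcher in matchers.items():
        matches = matcher(ps, treatment)
        res = regression_psm.att_analysis(
            y, ps, treatment, matches, method,
            n_boot=config.psm_n_boot, seed=config.seed + 303, matcher=matcher,
        )
        bal = regression_psm.balance_report(Xps, treatment, matches)
        att_rows.append(
            {
                "method": method,
                "treated_mean": res.mean_matched_treated,
                "control_matched_mean": res.mean_matched_control,
                "att": res.att, "se": res.se, "t_value": res.t_value,
                "n_treated_on_support": res.n_treated_on_support,
                "att_unmatched": res.mean_unmatched_treated - res.mean_unmatched_control,
            }
        )
        bal_rows.append(
            {
                "method": method,
                "mean_bias_before": bal.mean_bias_before,
                "mean_bias_after": bal.mean_bias_after,
                "med_bias_before": bal.med_bias_before,
                "med_bias_after": bal.med_bias_after,
                "pseudo_r2_after": bal.pseudo_r2_after,
                "lr_chi2_after": bal.lr_chi2_after,
                "p_value_after": bal.p_value_after,
            }
        )
        psm_stage[method] = {"att": res.att, "se": res.se,
                             "mean_bias_after": bal.mean_bias_after}
        report.tables[f"balance_{method}"] = bal.table()
    report.tables["att"] = pd.DataFrame(att_rows)
    report.tables["balance_summary"] = pd.DataFrame(bal_rows)
    report.stages["psm"] = psm_stage

    logger.info("=== stage: maihda ===")
    mdat = coded.copy()
    y_m = (
        scoring.standardize(mdat["sp_score"].to_numpy(dtype=float))
        if config.standardize_outcome
        else mdat["sp_score"].to_numpy(dtype=float)
    )
    ids, strata, n_excluded = maihda.build_strata(mdat)
    keep = ids > 0
    settings = config.mcmc_settings()
    fit_null = maihda.fit_two_level(y_m[keep], ids[keep], settings=settings)
    design, names = maihda.stratum_design(config.fp_fixed_coding)
    fit_main = maihda.fit_two_level(
        y_m[keep], ids[keep], design=design[:, 1:], design_names=names[1:],
        settings=settings,
    )
    decomp = maihda.variance_decomposition(fit_null, fit_main)
    summ_null = maihda.stratum_summaries(fit_null)
    summ_main = maihda.stratum_summaries(fit_main)
    flagged = maihda.flag_interactions(summ_main)

    params_rows = []
    for model, fit in (("null", fit_null), ("main", fit_main)):
        t = fit.summary()
        t.insert(0, "model", model)
        params_rows.append(t)
    report.tables["maihda_params"] = pd.concat(params_rows, ignore_index=True)
    report.tables["strata_null"] = summ_null
    report.tables["strata_main"] = summ_main
    report.tables["flagged_strata"] = flagged
    report.tables["caterpillar_predicted"] = maihda.caterpillar_data(summ_main, "predicted")
    report.tables["caterpillar_random"] = maihda.caterpillar_data(summ_main, "random")
    report.stages["maihda"] = {
        "n_used": int(keep.sum()),
        "n_excluded": n_excluded,
        "vpc_null_pct": decomp.vpc_null,
        "vpc_adjusted_pct": decomp.vpc_adjusted,
        "pcv_pct": decomp.pcv,
        "interaction_share_pct": decomp.interaction_share,
        "sigma2_u_null": float(fit_null.sigma2_u.mean()),
        "sigma2_e_null": float(fit_null.sigma2_e.mean()),
        "sigma2_u_main": float(fit_main.sigma2_u.mean()),
        "sigma2_e_main": float(fit_main.sigma2_e.mean()),
        "n_flagged_strata": int(len(flagged)),
        "flagged_stratum_ids": flagged["stratum_id"].tolist(),
        "converged_null": fit_null.converged,
        "converged_main": fit_main.converged,
        "rhat_max_main": max(fit_main.rhat.values()) if fit_main.rhat else None,
    }
    report.stages["provenance"] = {"seed": config.seed, "package": "agestrata"}
    return report


def write_report(report: RunReport, outdir: str | Path) -> Path:
    """Write report.json, every stage table as CSV, and a text summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
    for name, tab in report.tables.items():
        tab.to_csv(out / f"{name}.csv", index=False)

    s = report.stages
    lines = ["agestrata run summary", "====================="]
    lines.append(f"records analyzed: {s['coding']['n']}")
    lines.append(
        f"participation score: mean {s['coding']['sp_score_mean']:.3f} "
        f"(sd {s['coding']['sp_score_sd']:.3f})"
    )
    lines.append(
        f"regression: FP coefficient {s['regression']['fp_coefficient']:.4f} "
        f"(p = {s['regression']['fp_p_value']:.3g}, n = {s['regression']['n_used']})"
    )
    for m, v in s["psm"].items():
        lines.append(
            f"psm[{m}]: ATT {v['att']:.4f} (se {v['se']:.4f}), "
            f"post-match mean bias {v['mean_bias_after']:.2f}%"
        )
    mh = s["maihda"]
    lines.append(
        f"maihda: VPC {mh['vpc_null_pct']:.2f}% -> adjusted {mh['vpc_adjusted_pct']:.2f}%, "
        f"PCV {mh['pcv_pct']:.2f}% (interaction share {mh['interaction_share_pct']:.2f}%)"
    )
    lines.append(
        f"flagged strata ({mh['n_flagged_strata']}): {mh['flagged_stratum_ids']}"
    )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return out / "report.json"
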