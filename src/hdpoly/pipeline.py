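"""End-to-end experiment orchestration.

``run_experiment`` executes the full analysis in dependency order —
simulate (or load) a cohort, estimate couplings, screen edges and build
composites, run the univariate statistical battery, evaluate every
feature set x contrast cell with a permutation-tested LOO SVM, and
derive the hyperplane-distance conversion prediction — and
``render_report`` persists markdown/CSV/JSON renderings of the result.
All randomness flows from one master seed via spawned child streams, so
a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, coupling, stats
from .classify import ClassificationReport, FeatureMatrix
from .cohort import CohortBundle, SimulationConfig, read_bundle, simulate_cohort

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "render_report"]

log = logging.getLogger("hdpoly")

CONTRASTS = ("prehd-vs-control", "near-vs-control", "far-vs-control",
             "converted-vs-control")
FEATURE_SETS = ("rest", "ct", "scv", "polymarker")


@dataclass
class ExperimentConfig:
    """Everything needed to rerun one experiment deterministically."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    data_dir: str | None = None  # load a written bundle instead of simulating
    alpha: float = 0.02
    n_perm: int = 1000
    C: float = 1.0
    paper_mode: bool = False
    feature_sets: tuple[str, ...] = FEATURE_SETS
    contrasts: tuple[str, ...] = CONTRASTS
    run_stats: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "sim"}
        d["feature_sets"] = list(self.feature_sets)
        d["contrasts"] = list(self.contrasts)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        sim = SimulationConfig.from_dict(d.pop("sim", {}))
        if "feature_sets" in d:
            d["feature_sets"] = tuple(d["feature_sets"])
        if "contrasts" in d:
            d["contrasts"] = tuple(d["contrasts"])
        return cls(sim=sim, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True)
                              .encode()).hexdigest()[:12]


@dataclass
class ExperimentReport:
    """Collected outputs of one experiment run."""

    config: ExperimentConfig
    classification: pd.DataFrame  # feature_set x contrast -> f1, p
    reports: dict[tuple[str, str], ClassificationReport]
    edges: coupling.EdgeSet
    composites: pd.DataFrame
    composite_group_means: pd.DataFrame
    stats_results: dict
    conversion: dict

    def classification_table(self) -> pd.DataFrame:
        return self.classification

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "classification": self.classification.reset_index().to_dict(orient="records"),
            "edges": self.edges.to_frame().to_dict(orient="records"),
            "composite_group_means": self.composite_group_means.reset_index()
                                          .to_dict(orient="records"),
            "stats": self.stats_results,
            "conversion": {k: v for k, v in self.conversion.items()
                           if k != "hyperplane_table"},
        }


def _contrast_subjects(df: pd.DataFrame, contrast: str) -> pd.Index:
    ctl = df.index[df["group"] == "control"]
    if contrast == "prehd-vs-control":
        pat = df.index[df["group"] == "prehd"]
    elif contrast == "near-vs-control":
        pat = df.index[df["subgroup"] == "near"]
    elif contrast == "far-vs-control":
        pat = df.index[df["subgroup"] == "far"]
    elif contrast == "converted-vs-control":
        pat = df.index[df["converted_within_followup"] == True]  # noqa: E712
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return pat.append(ctl)


def _feature_blocks(bundle: CohortBundle, couplings: pd.DataFrame
                    ) -> dict[str, FeatureMatrix]:
    cov = bundle.covariates()
    rest = FeatureMatrix(values=couplings, feature_set="rest", covariates=cov)
    blocks = {"rest": rest, "ct": bundle.ct, "scv": bundle.scv}
    blocks["polymarker"] = FeatureMatrix.concat([rest, bundle.ct, bundle.scv])
    return blocks


def _stats_battery(bundle: CohortBundle, couplings: pd.DataFrame,
                   composites: pd.DataFrame) -> dict:
    """The univariate battery: mixed ANOVAs, post-hocs, correlations, ranks."""
    sf = bundle.subjects_frame()
    out: dict = {}

    long = couplings.reset_index().melt(id_vars="subject_id", var_name="connection",
                                        value_name="value")
    long["group"] = sf["group"].reindex(long["subject_id"]).to_numpy()
    res = stats.rm_anova(long, dv="value", subject="subject_id",
                         within="connection", between="group")
    out["rsn_rm_anova"] = _anova_dict(res)

    scv_long = bundle.scv.values.reset_index().melt(
        id_vars="subject_id", var_name="structure", value_name="value")
    scv_long["group"] = sf["group"].reindex(scv_long["subject_id"]).to_numpy()
    scv_long["age"] = sf["age"].reindex(scv_long["subject_id"]).to_numpy()
    res = stats.rm_anova(scv_long, dv="value", subject="subject_id",
                         within="structure", between="group", covariate="age")
    out["scv_rm_anova"] = _anova_dict(res)

    sub3 = sf.copy()
    sub3["group3"] = np.where(sf["group"] == "control", "control", sf["subgroup"])
    hypo = composites["hypo"]
    if hypo.notna().all():
        ow = stats.oneway_anova(hypo.to_numpy(), sub3["group3"].to_numpy())
        out["hypo_oneway"] = _anova_dict(ow)
        out["hypo_tukey"] = stats.tukey_hsd(hypo.to_numpy(), sub3["group3"].to_numpy()
                                            ).table.to_dict(orient="records")
        pre = sf["group"] == "prehd"
        est = sf.loc[pre, "est_years_to_dx"].to_numpy(dtype=float)
        hv = hypo[pre].to_numpy()
        ks = stats.ks_normality(est)
        out["est_years_ks"] = {"statistic": ks[0], "p": ks[1], "reject": ks[2]}
        sp = stats.spearman(hv, est)
        out["hypo_vs_est_years"] = sp.__dict__
        cap = sf.loc[pre, "caps"].to_numpy(dtype=float)
        sp_caps = stats.spearman(hv, cap)
        out["hypo_vs_caps"] = sp_caps.__dict__
        r_yz = stats.spearman(est, cap).rho
        z, pz = stats.steiger_z(sp.rho, sp_caps.rho, r_yz, n=int(pre.sum()))
        out["steiger_est_vs_caps"] = {"z": z, "p": pz}
        age = sf.loc[pre, "age"].to_numpy(dtype=float)
        out["hypo_vs_est_years_partial_age"] = stats.partial_spearman(hv, est, age).__dict__
        conv = sf.loc[pre, "converted_within_followup"].astype(bool)
        if 1 <= conv.sum() < len(conv):
            mw = stats.mann_whitney_hl(hv[~conv.to_numpy()], hv[conv.to_numpy()])
            out["hypo_converters_mw"] = mw.__dict__
    else:
        out["hypo_oneway"] = "no composite defined"
    return out


def _anova_dict(res: stats.AnovaResult) -> dict:
    return {"design": res.design, "table": res.table.to_dict(orient="records")}


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute every stage in dependency order (deterministic under seed)."""
    cfg = config
    stage = "simulate"
    try:
        bundle = read_bundle(cfg.data_dir) if cfg.data_dir else simulate_cohort(cfg.sim)
        log.info("cohort ready: %d subjects, config %s", len(bundle.subjects),
                 cfg.config_hash())

        stage = "couple"
        couplings = coupling.coupling_table(bundle.timecourses)
        sf = bundle.subjects_frame()

        stage = "screen"
        edges = coupling.edge_group_screen(couplings, sf["group"].to_numpy(),
                                           alpha=cfg.alpha)
        composites = coupling.composite_table(couplings, edges)
        grp3 = np.where(sf["group"] == "control", "control",
                        "prehd-" + sf["subgroup"].astype(str))
        comp_means = composites.groupby(grp3).mean()

        stage = "stats"
        stats_results = (_stats_battery(bundle, couplings, composites)
                         if cfg.run_stats else {})

        stage = "classify"
        blocks = _feature_blocks(bundle, couplings)
        seeds = np.random.SeedSequence(cfg.seed).spawn(
            len(cfg.feature_sets) * len(cfg.contrasts) + 1)
        rows, reports = [], {}
        k = 0
        for fs in cfg.feature_sets:
            for contrast in cfg.contrasts:
                idx = _contrast_subjects(sf, contrast)
                fm = blocks[fs]
                sub = FeatureMatrix(values=fm.values.loc[idx], feature_set=fs,
                                    covariates=fm.covariates.loc[idx])
                labels = (sf.loc[idx, "group"] == "prehd").map(
                    {True: "patient", False: "control"}).to_numpy()
                rep = classify.permutation_test(
                    sub, labels, n_perm=cfg.n_perm,
                    seed=int(seeds[k].generate_state(1)[0] % (2**31)),
                    C=cfg.C, positive_label="patient", paper_mode=cfg.paper_mode)
                rows.append(dict(feature_set=fs, contrast=contrast, f1=rep.f1,
                                 p=rep.p_value, n=len(labels)))
                reports[(fs, contrast)] = rep
                k += 1
        table = pd.DataFrame(rows).set_index(["feature_set", "contrast"])

        stage = "conversion"
        conversion = _conversion_prediction(bundle, blocks, sf, cfg)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    return ExperimentReport(config=cfg, classification=table, reports=reports,
                            edges=edges, composites=composites,
                            composite_group_means=comp_means,
                            stats_results=stats_results, conversion=conversion)


def _conversion_prediction(bundle: CohortBundle, blocks: dict, sf: pd.DataFrame,
                           cfg: ExperimentConfig) -> dict:
    """Hyperplane-distance prognosis from the preHD-vs-control polymarker SVM.

    Distances are the held-out (LOO) hyperplane distances: the scored
    subject never constrains the margin of the model scoring it, so the
    score stays graded even when features outnumber subjects (training
    points then pile up exactly on the margin).
    """
    fs = "polymarker" if "polymarker" in blocks else list(blocks)[-1]
    fm = blocks[fs]
    labels = np.where(sf["group"] == "prehd", "patient", "control")
    rep = classify.loo_f1(fm, labels, C=cfg.C, positive_label="patient",
                          paper_mode=cfg.paper_mode)
    pre = sf["group"] == "prehd"
    table = pd.DataFrame({"distance": rep.decision, "is_patient": pre.to_numpy()},
                         index=sf.index)
    pdist = table.loc[pre, "distance"]
    table["patient_rank"] = np.nan
    table.loc[pre, "patient_rank"] = pdist.rank(ascending=False, method="average")
    med = float(pdist.median())
    table["median_split"] = pd.NA
    table.loc[pre, "median_split"] = np.where(
        pdist >= med, "predicted_converter", "predicted_nonconverter")
    conv = sf.loc[pre, "converted_within_followup"].astype(bool)
    dist = table.loc[pre.index[pre], "distance"]
    out: dict = {"feature_set": fs, "hyperplane_table": table}
    if 0 < conv.sum() < len(conv):
        mw = stats.mann_whitney_hl(dist[~conv].to_numpy(), dist[conv].to_numpy())
        out["converter_mw"] = mw.__dict__
        call = table.loc[pre.index[pre], "median_split"] == "predicted_converter"
        out["median_split_confusion"] = {
            "tp": int((call & conv).sum()), "fp": int((call & ~conv).sum()),
            "fn": int((~call & conv).sum()), "tn": int((~call & ~conv).sum()),
        }
    return out


def render_report(report: ExperimentReport, outdir: str | Path) -> list[Path]:
    """Persist markdown + CSV + JSON renderings of an experiment report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    p = out / "report.json"
    with open(p, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=_json_default)
    written.append(p)

    p = out / "classification.csv"
    report.classification.to_csv(p)
    written.append(p)

    p = out / "edges.csv"  # schema-ball analogue: edge, direction, weight
    edf = report.edges.to_frame()
    edf["weight"] = edf["t"].abs()
    edf.to_csv(p, index=False)
    written.append(p)

    p = out / "composites.csv"
    report.composites.to_csv(p)
    written.append(p)

    for (fs, contrast), rep in report.reports.items():
        if rep.null_f1 is not None:
            q = out / f"null_f1_{fs}_{contrast}.csv"
            pd.Series(rep.null_f1, name="null_f1").to_csv(q, index=False)
            written.append(q)

    if "hyperplane_table" in report.conversion:
        p = out / "decisions.csv"
        report.conversion["hyperplane_table"].to_csv(p)
        written.append(p)

    p = out / "report.md"
    with open(p, "w") as fh:
        fh.write(_markdown(report))
    written.append(p)
    return written


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if o is pd.NA or (isinstance(o, float) and np.isnan(o)):
        return None
    return str(o)


def _table_md(df: pd.DataFrame, index: bool = False) -> str:
    try:
        return df.to_markdown(index=index)
    except ImportError:  # tabulate unavailable: fall back to plain text
        return df.to_string(index=index)


def _markdown(report: ExperimentReport) -> str:
    lines = [
        "# hdpoly experiment report",
        f"config hash: `{report.config.config_hash()}` | seed: {report.config.seed} "
        f"| n_perm: {report.config.n_perm}",
        "",
        "## Classification (F1 vs permutation null)",
        "",
        _table_md(report.classification.reset_index()),
        "",
        "## Screened edges",
        "",
    ]
    if report.edges.edges:
        lines.append(_table_md(report.edges.to_frame()))
    else:
        lines.append("no edges survived the screen")
    lines += ["", "## Composite group means", ""]
    if report.composite_group_means.isna().all().any():
        nan_cols = [c for c in report.composite_group_means
                    if report.composite_group_means[c].isna().all()]
        lines.append(f"no composite defined for: {', '.join(nan_cols)}")
    lines.append(_table_md(report.composite_group_means, index=True))
    if "converter_mw" in report.conversion:
        mw = report.conversion["converter_mw"]
        lines += ["", "## Conversion prediction (hyperplane distance)", "",
                  f"Mann-Whitney converters vs nonconverters: "
                  f"U_max = {mw['u_max']:.0f}, p = {mw['p']:.4g}, "
                  f"HL = {mw['hl_shift']:.3f}",
                  f"median-split confusion: {report.conversion['median_split_confusion']}"]
    return "\n".join(lines) + "\n"
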