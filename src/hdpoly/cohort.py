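"""Synthetic premanifest-HD cohort generator.

Emulates the statistical structure the downstream analysis assumes, for
a cohort of healthy controls and premanifest gene carriers (preHD):

* demographics and genetics: age, CAG repeat length, imaging site, the
  derived clock scores (estimated years to diagnosis, disease burden,
  CAPs) and a median-split near/far subgroup label;
* a latent true time-to-onset equal to the Langbehn estimate plus a
  heavy-tailed (Student-t, df 3) individual deviation, so that some
  carriers convert "unexpectedly" early relative to the model estimate;
  conversion within follow-up is latent onset <= follow-up years;
* subcortical volumes (6 structures, hemispheres summed, mm^3) and
  cortical thickness (74 parcels x 2 hemispheres, mm) generated as
  baseline - slope * g(proximity) + age effect + site shift + noise,
  where the proximity ramp g is 0 for controls and grows as the latent
  years-to-onset shrink;
* per-subject network time courses (default 19 networks x 300
  timepoints, TR 2 s) drawn from a subject-specific target correlation
  structure with planted hypo-/hyper-coupled edges scaled by the same
  proximity ramp, plus additively mixed nuisance series (6 motion-like
  AR(1) regressors and one white-matter-like series).

Everything is driven by one :class:`SimulationConfig` and a single seed;
regenerating with the same config and seed reproduces the bundle
bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import FeatureMatrix
from .coupling import TimecourseSet, canonical_pairs, pair_label
from .genetics import assign_subgroups, caps_score, disease_burden_score, langbehn_years_to_dx

__all__ = [
    "SubjectRecord",
    "SimulationConfig",
    "CohortBundle",
    "proximity_ramp",
    "simulate_timecourses",
    "simulate_cohort",
    "write_bundle",
    "read_bundle",
    "SCV_STRUCTURES",
]

#: Subcortical structures (hemispheres summed); the analysis needs six
#: levels, the canonical basal-ganglia/limbic set is used.
SCV_STRUCTURES = ("caudate", "putamen", "pallidum", "thalamus", "hippocampus", "amygdala")

#: Per-structure (baseline mm^3, atrophy slope mm^3 per unit proximity ramp).
_SCV_PARAMS = {
    "caudate": (7400.0, 2000.0),
    "putamen": (10500.0, 2600.0),
    "pallidum": (3700.0, 700.0),
    "thalamus": (15500.0, 600.0),
    "hippocampus": (8800.0, 400.0),
    "amygdala": (3500.0, 250.0),
}


@dataclass
class SubjectRecord:
    """Demographics, genetics, site and outcome for one participant."""

    subject_id: str
    group: str  # "control" | "prehd"
    age: float
    site: str
    cag: int | None = None
    est_years_to_dx: float | None = None
    dbs: float | None = None
    caps: float | None = None
    latent_years_to_onset: float | None = None  # simulation ground truth
    converted_within_followup: bool | None = None
    subgroup: str | None = None  # "near" | "far" (preHD only)

    def __post_init__(self) -> None:
        if self.group not in ("control", "prehd"):
            raise ValueError(f"group must be 'control' or 'prehd', got {self.group!r}")
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.group == "prehd":
            if self.cag is None or self.cag < 36:
                raise ValueError(f"preHD subject {self.subject_id} needs CAG >= 36")
        else:
            for f in ("cag", "est_years_to_dx", "subgroup", "converted_within_followup"):
                if getattr(self, f) is not None:
                    raise ValueError(f"control {self.subject_id} must not carry {f}")
        if self.cag is not None and self.dbs is not None:
            if abs(self.dbs - self.age * (self.cag - 35.5)) > 1e-6:
                raise ValueError("dbs inconsistent with age x (CAG - 35.5)")


@dataclass
class SimulationConfig:
    """Full parameter set for one synthetic cohort.

    Effect sizes are expressed on the measurement scale (mm^3 slopes per
    unit proximity ramp for volumes, mm for thickness, correlation units
    for the coupling deficit).  ``onset_deviation_scale`` spreads the
    latent true onset around the Langbehn estimate (Student-t, df 3), in
    years; larger values produce more unexpected converters.
    """

    n_control: int = 21
    n_prehd: int = 19
    n_networks: int = 19
    n_timepoints: int = 300
    tr_seconds: float = 2.0
    followup_years: float = 5.0
    n_sites: int = 2
    # genetics / demographics
    age_mean: float = 45.0
    age_sd: float = 11.0
    age_range: tuple[float, float] = (26.0, 68.0)
    cag_choices: tuple[int, ...] = (39, 40, 41, 42, 43, 44, 45)
    onset_deviation_scale: float = 4.0
    # proximity ramp: g = clip((ramp_years - latent)/ramp_years, 0, ramp_max)
    ramp_years: float = 15.0
    ramp_max: float = 1.5
    # coupling structure
    n_hypo_edges: int = 10
    n_hyper_edges: int = 5
    hypo_base: float = 0.45
    hyper_base: float = 0.10
    coupling_deficit: float = 0.25
    hyper_effect: float = 0.15
    background_coupling: float = 0.08
    nuisance_scale: float = 1.0
    # structural features
    scv_noise_frac: float = 0.07  # noise SD as a fraction of baseline
    scv_age_slope: float = -15.0  # mm^3 per year
    scv_effect_scale: float = 1.0  # multiplies every structure's atrophy slope
    n_ct_parcels: int = 74
    ct_base_mean: float = 2.55
    ct_base_sd: float = 0.25
    ct_noise_sd: float = 0.08
    ct_age_slope: float = -0.004  # mm per year
    ct_global_thinning: float = 0.05  # mm per unit ramp, all parcels
    ct_focal_thinning: float = 0.12  # mm per unit ramp, focal parcels
    n_ct_focal: int = 40
    site_shift_scale: float = 0.5  # site offsets, in units of each feature's noise SD
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 2 or self.n_prehd < 2:
            raise ValueError("need at least 2 subjects per group")
        for name in ("onset_deviation_scale", "coupling_deficit", "hyper_effect",
                     "nuisance_scale", "scv_noise_frac", "ct_noise_sd",
                     "site_shift_scale", "ct_global_thinning", "ct_focal_thinning"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_networks < 2 or self.n_timepoints < 10:
            raise ValueError("need >= 2 networks and >= 10 timepoints")
        n_pairs = self.n_networks * (self.n_networks - 1) // 2
        if self.n_hypo_edges + self.n_hyper_edges > n_pairs:
            raise ValueError("more planted edges than network pairs")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(d["age_range"])
        d["cag_choices"] = list(d["cag_choices"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "cag_choices" in d:
            d["cag_choices"] = tuple(int(c) for c in d["cag_choices"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class CohortBundle:
    """One simulated cohort: subjects, time courses and feature tables."""

    subjects: list[SubjectRecord]
    timecourses: dict[str, TimecourseSet]
    scv: FeatureMatrix
    ct: FeatureMatrix
    config: SimulationConfig
    planted_hypo: list[str] = field(default_factory=list)
    planted_hyper: list[str] = field(default_factory=list)

    def subjects_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append({
                "subject_id": s.subject_id, "group": s.group, "age": s.age,
                "cag": s.cag, "site": s.site, "est_years_to_dx": s.est_years_to_dx,
                "dbs": s.dbs, "caps": s.caps,
                "latent_years_to_onset": s.latent_years_to_onset,
                "subgroup": s.subgroup,
                "converted_within_followup": s.converted_within_followup,
            })
        return pd.DataFrame(rows).set_index("subject_id")

    def covariates(self) -> pd.DataFrame:
        df = self.subjects_frame()
        return df[["age", "site"]]

    def labels(self) -> pd.Series:
        return self.subjects_frame()["group"]


def proximity_ramp(latent_years: float | np.ndarray, ramp_years: float = 15.0,
                   ramp_max: float = 1.5) -> np.ndarray:
    """Disease-proximity ramp g: 0 far from onset, growing as onset nears.

    ``g = clip((ramp_years - latent)/ramp_years, 0, ramp_max)`` — zero for
    anyone more than ``ramp_years`` from onset, 1 at onset, saturating at
    ``ramp_max`` for overdue individuals.  Controls always get g = 0.
    """
    g = (ramp_years - np.asarray(latent_years, dtype=float)) / ramp_years
    return np.clip(g, 0.0, ramp_max)


def _ar1(rng: np.random.Generator, T: int, phi: float = 0.9) -> np.ndarray:
    """Unit-variance AR(1) series (motion/physiology-like nuisance)."""
    e = rng.standard_normal(T)
    innov_sd = (1 - phi**2) ** 0.5
    out = np.empty(T)
    out[0] = e[0]
    for t in range(1, T):
        out[t] = phi * out[t - 1] + innov_sd * e[t]
    return out


def simulate_timecourses(n_networks: int, n_timepoints: int,
                         coupling_targets: np.ndarray, nuisance_scale: float,
                         seed_or_rng) -> TimecourseSet:
    """Draw network time courses with a target coupling structure.

    Latent network series are multivariate normal with correlation matrix
    ``coupling_targets`` (must be symmetric positive definite), so the
    empirical pairwise couplings converge to the targets as the number of
    timepoints grows.  Seven nuisance series (6 motion-like AR(1) + 1
    white-matter-like) are mixed additively into the observed signals
    with random loadings scaled by ``nuisance_scale`` and returned in the
    nuisance matrix so the coupling GLMs can regress them out.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    Sigma = np.asarray(coupling_targets, dtype=float)
    if Sigma.shape != (n_networks, n_networks) or not np.allclose(Sigma, Sigma.T):
        raise ValueError("coupling_targets must be a symmetric n x n matrix")
    eig = np.linalg.eigvalsh(Sigma)
    if eig.min() <= 0:
        raise ValueError(
            f"coupling_targets not positive definite (min eigenvalue {eig.min():.3g})"
        )
    L = np.linalg.cholesky(Sigma)
    latent = rng.standard_normal((n_timepoints, n_networks)) @ L.T
    nuis = np.column_stack([_ar1(rng, n_timepoints) for _ in range(6)]
                           + [_ar1(rng, n_timepoints, phi=0.8)])
    loadings = rng.normal(0.0, 0.3, size=(n_networks, 7))
    signals = latent.T + nuisance_scale * (loadings @ nuis.T)
    return TimecourseSet(signals=signals, nuisance=nuis,
                         network_labels=[f"net{i:02d}" for i in range(n_networks)])


def _base_sigma(cfg: SimulationConfig) -> np.ndarray:
    n = cfg.n_networks
    S = np.full((n, n), cfg.background_coupling)
    np.fill_diagonal(S, 1.0)
    return S


def _planted_edges(cfg: SimulationConfig, rng: np.random.Generator
                   ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    pairs = canonical_pairs(cfg.n_networks)
    chosen = rng.choice(len(pairs), size=cfg.n_hypo_edges + cfg.n_hyper_edges,
                        replace=False)
    hypo = [pairs[i] for i in chosen[: cfg.n_hypo_edges]]
    hyper = [pairs[i] for i in chosen[cfg.n_hypo_edges:]]
    return hypo, hyper


def _subject_sigma(cfg: SimulationConfig, hypo, hyper, g: float) -> np.ndarray:
    S = _base_sigma(cfg)
    for i, j in hypo:
        S[i, j] = S[j, i] = cfg.hypo_base - cfg.coupling_deficit * g
    for i, j in hyper:
        S[i, j] = S[j, i] = cfg.hyper_base + cfg.hyper_effect * g
    # guarantee positive definiteness by shrinking off-diagonals if needed
    for _ in range(60):
        if np.linalg.eigvalsh(S).min() > 1e-3:
            break
        off = S - np.diag(np.diag(S))
        S = np.diag(np.diag(S)) + 0.95 * off
    return S


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a full cohort bundle under one config and seed.

    With zero effect sizes the control and carrier feature distributions
    are identical up to noise; with the defaults, carriers near latent
    onset show planted coupling deficits, striatal atrophy and cortical
    thinning that scale with the proximity ramp, while carriers far from
    onset remain control-like.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sites = [f"site{i + 1}" for i in range(cfg.n_sites)]

    subjects: list[SubjectRecord] = []
    latents: dict[str, float] = {}
    for k in range(cfg.n_control):
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), *cfg.age_range))
        subjects.append(SubjectRecord(
            subject_id=f"c{k + 1:03d}", group="control", age=round(age, 1),
            site=str(rng.choice(sites))))
        latents[subjects[-1].subject_id] = np.inf
    for k in range(cfg.n_prehd):
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), *cfg.age_range))
        age = round(age, 1)
        cag = int(rng.choice(cfg.cag_choices))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = langbehn_years_to_dx(age, cag)
            cap = caps_score(age, cag)
        latent = est + cfg.onset_deviation_scale * float(rng.standard_t(3))
        subjects.append(SubjectRecord(
            subject_id=f"p{k + 1:03d}", group="prehd", age=age, site=str(rng.choice(sites)),
            cag=cag, est_years_to_dx=est, dbs=disease_burden_score(age, cag),
            caps=cap, latent_years_to_onset=latent,
            converted_within_followup=bool(latent <= cfg.followup_years)))
        latents[subjects[-1].subject_id] = latent
    subjects = assign_subgroups(subjects)

    ids = [s.subject_id for s in subjects]
    ages = np.array([s.age for s in subjects])
    site_of = {s.subject_id: s.site for s in subjects}
    g = np.array([0.0 if s.group == "control"
                  else float(proximity_ramp(latents[s.subject_id],
                                            cfg.ramp_years, cfg.ramp_max))
                  for s in subjects])

    # ---- subcortical volumes (6 structures, hemispheres summed)
    scv_cols = list(SCV_STRUCTURES)
    scv_noise_sd = np.array([_SCV_PARAMS[c][0] * cfg.scv_noise_frac for c in scv_cols])
    site_shift_scv = {s: rng.normal(0.0, cfg.site_shift_scale * scv_noise_sd)
                      for s in sites}
    scv = np.empty((len(ids), len(scv_cols)))
    for j, c in enumerate(scv_cols):
        base, slope = _SCV_PARAMS[c]
        scv[:, j] = (base - cfg.scv_effect_scale * slope * g
                     + cfg.scv_age_slope * (ages - cfg.age_mean)
                     + rng.normal(0.0, scv_noise_sd[j], size=len(ids)))
    for i, sid in enumerate(ids):
        scv[i] += site_shift_scv[site_of[sid]]

    # ---- cortical thickness (74 parcels x 2 hemispheres)
    parcel_base = rng.normal(cfg.ct_base_mean, cfg.ct_base_sd, size=cfg.n_ct_parcels)
    focal = rng.choice(cfg.n_ct_parcels, size=min(cfg.n_ct_focal, cfg.n_ct_parcels),
                       replace=False)
    ct_cols = [f"parcel{p + 1:02d}_{h}" for p in range(cfg.n_ct_parcels) for h in ("lh", "rh")]
    site_shift_ct = {s: rng.normal(0.0, cfg.site_shift_scale * cfg.ct_noise_sd,
                                   size=len(ct_cols)) for s in sites}
    ct = np.empty((len(ids), len(ct_cols)))
    for j, col in enumerate(ct_cols):
        p = j // 2
        thin = cfg.ct_global_thinning + (cfg.ct_focal_thinning if p in focal else 0.0)
        ct[:, j] = (parcel_base[p] - thin * g
                    + cfg.ct_age_slope * (ages - cfg.age_mean)
                    + rng.normal(0.0, cfg.ct_noise_sd, size=len(ids)))
    for i, sid in enumerate(ids):
        ct[i] += site_shift_ct[site_of[sid]]

    # ---- time courses with planted coupling deficits
    hypo, hyper = _planted_edges(cfg, rng)
    timecourses: dict[str, TimecourseSet] = {}
    for i, sid in enumerate(ids):
        Sigma = _subject_sigma(cfg, hypo, hyper, g[i])
        timecourses[sid] = simulate_timecourses(
            cfg.n_networks, cfg.n_timepoints, Sigma, cfg.nuisance_scale, rng)

    covariates = pd.DataFrame({"age": ages, "site": [site_of[s] for s in ids]},
                              index=pd.Index(ids, name="subject_id"))
    scv_fm = FeatureMatrix(values=pd.DataFrame(scv, index=covariates.index, columns=scv_cols),
                           feature_set="scv", covariates=covariates)
    ct_fm = FeatureMatrix(values=pd.DataFrame(ct, index=covariates.index, columns=ct_cols),
                          feature_set="ct", covariates=covariates)
    return CohortBundle(
        subjects=subjects, timecourses=timecourses, scv=scv_fm, ct=ct_fm, config=cfg,
        planted_hypo=[pair_label(f"net{i:02d}", f"net{j:02d}") for i, j in hypo],
        planted_hyper=[pair_label(f"net{i:02d}", f"net{j:02d}") for i, j in hyper])


# ---------------------------------------------------------------------------
# on-disk interchange (plain-text CSV/TSV with a provenance header)


def _header(cfg: SimulationConfig) -> str:
    return f"# hdpoly synthetic cohort | config_hash={cfg.config_hash()} | seed={cfg.seed}\n"


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> Path:
    """Write a cohort bundle as CSV/TSV files plus config.yaml."""
    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = _header(bundle.config)
    df = bundle.subjects_frame().drop(columns=["latent_years_to_onset"])
    with open(out / "cohort.csv", "w") as fh:
        fh.write(hdr)
        df.to_csv(fh)
    for name, fm in (("scv", bundle.scv), ("ct", bundle.ct)):
        with open(out / f"{name}.csv", "w") as fh:
            fh.write(hdr)
            fm.values.to_csv(fh)
    tc_dir = out / "timecourses"
    tc_dir.mkdir(exist_ok=True)
    for sid, tc in bundle.timecourses.items():
        with open(tc_dir / f"timecourse_{sid}.tsv", "w") as fh:
            fh.write(hdr)
            pd.DataFrame(tc.signals, index=tc.network_labels).to_csv(fh, sep="\t")
        with open(tc_dir / f"nuisance_{sid}.tsv", "w") as fh:
            fh.write(hdr)
            pd.DataFrame(tc.nuisance).to_csv(fh, sep="\t")
    with open(out / "config.yaml", "w") as fh:
        fh.write(hdr)
        yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=True)
    return out


def read_bundle(indir: str | Path) -> CohortBundle:
    """Read a bundle written by :func:`write_bundle` (or matching real data)."""
    import yaml

    indir = Path(indir)
    with open(indir / "config.yaml") as fh:
        cfg = SimulationConfig.from_dict(yaml.safe_load(fh))
    cohort = pd.read_csv(indir / "cohort.csv", comment="#", index_col="subject_id")
    subjects = []
    for sid, r in cohort.iterrows():
        is_ctl = r["group"] == "control"
        subjects.append(SubjectRecord(
            subject_id=str(sid), group=r["group"], age=float(r["age"]),
            site=str(r["site"]),
            cag=None if is_ctl else int(r["cag"]),
            est_years_to_dx=None if is_ctl else float(r["est_years_to_dx"]),
            dbs=None if is_ctl else float(r["dbs"]),
            caps=None if is_ctl else float(r["caps"]),
            converted_within_followup=None if is_ctl else bool(r["converted_within_followup"]),
            subgroup=None if is_ctl else str(r["subgroup"])))
    ids = [s.subject_id for s in subjects]
    cov = cohort.loc[ids, ["age", "site"]]
    scv = pd.read_csv(indir / "scv.csv", comment="#", index_col="subject_id").loc[ids]
    ct = pd.read_csv(indir / "ct.csv", comment="#", index_col="subject_id").loc[ids]
    timecourses = {}
    for sid in ids:
        sig = pd.read_csv(indir / "timecourses" / f"timecourse_{sid}.tsv",
                          comment="#", sep="\t", index_col=0)
        nui = pd.read_csv(indir / "timecourses" / f"nuisance_{sid}.tsv",
                          comment="#", sep="\t", index_col=0)
        timecourses[sid] = TimecourseSet(signals=sig.to_numpy(), nuisance=nui.to_numpy(),
                                         network_labels=list(sig.index))
    return CohortBundle(
        subjects=subjects, timecourses=timecourses,
        scv=FeatureMatrix(values=scv, feature_set="scv", covariates=cov),
        ct=FeatureMatrix(values=ct, feature_set="ct", covariates=cov),
        config=cfg)
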