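"""Pairwise resting-state network coupling via a dual-GLM procedure.

For every unordered pair of network time courses (x, y), two general
linear models are fitted after z-scoring both series: one with y as the
dependent variable and x as a regressor, one with the roles swapped.
Nuisance series (motion parameters, white-matter signal) enter both
models as covariates, and an intercept is always included.  The coupling
strength for the pair is the average of the two slope coefficients.
With no nuisance regressors this average equals the Pearson correlation
exactly; with nuisance regressors it is a symmetrised partial
association.

A 19-network time-course set therefore yields 19*18/2 = 171 coupling
strengths per subject.  Group screening applies an uncorrected
two-sample t test per edge (the screening threshold is deliberately
liberal and uncorrected, mirroring the composite-building procedure it
feeds), and composites average a subject's couplings over the screened
hypo- or hyper-connected edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TimecourseSet",
    "CouplingVector",
    "Edge",
    "EdgeSet",
    "estimate_pair_coupling",
    "coupling_vector",
    "coupling_table",
    "edge_group_screen",
    "composite_score",
    "composite_table",
    "canonical_pairs",
    "pair_label",
]


def canonical_pairs(n: int) -> list[tuple[int, int]]:
    """Unordered index pairs (i, j), i < j, in canonical row-major order."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def pair_label(a: str, b: str) -> str:
    return f"{a}__{b}"


@dataclass
class TimecourseSet:
    """Per-subject network time courses plus nuisance series.

    Attributes
    ----------
    signals : ndarray, shape (n_networks, n_timepoints)
        One row per network, in ``network_labels`` order.
    nuisance : ndarray, shape (n_timepoints, k)
        Nuisance regressors (e.g. 6 motion-like + 1 white-matter series).
        May have k = 0.
    network_labels : list of str
    """

    signals: np.ndarray
    nuisance: np.ndarray
    network_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.nuisance = np.asarray(self.nuisance, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D (networks x time) array")
        if self.nuisance.size == 0:
            self.nuisance = np.empty((self.signals.shape[1], 0))
        if self.nuisance.ndim != 2:
            raise ValueError("nuisance must be a 2-D (time x k) array")
        if not self.network_labels:
            self.network_labels = [f"net{i:02d}" for i in range(self.signals.shape[0])]
        if len(self.network_labels) != self.signals.shape[0]:
            raise ValueError("network_labels length does not match signals rows")
        if self.nuisance.shape[0] != self.signals.shape[1]:
            raise ValueError(
                f"time dimension mismatch: signals have {self.signals.shape[1]} "
                f"timepoints, nuisance has {self.nuisance.shape[0]}"
            )
        if not (np.isfinite(self.signals).all() and np.isfinite(self.nuisance).all()):
            raise ValueError("non-finite values in time courses")
        if self.signals.shape[1] < self.nuisance.shape[1] + 3:
            raise ValueError("need at least 3 more timepoints than nuisance regressors")

    @property
    def n_networks(self) -> int:
        return self.signals.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signals.shape[1]


@dataclass
class CouplingVector:
    """Vector of unordered network-pair coupling strengths for one subject."""

    values: np.ndarray
    n_networks: int
    pair_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.n_networks
        if self.values.shape != (n * (n - 1) // 2,):
            raise ValueError(
                f"expected {n * (n - 1) // 2} couplings for {n} networks, "
                f"got {self.values.shape}"
            )

    @property
    def pair_index(self) -> dict[tuple[int, int], int]:
        """Canonical map (i, j) with i < j -> position in ``values``."""
        return {p: k for k, p in enumerate(canonical_pairs(self.n_networks))}


@dataclass
class Edge:
    pair: str
    direction: str  # "hypo" | "hyper"
    t: float
    p: float


@dataclass
class EdgeSet:
    """Edges surviving an uncorrected group screen at threshold ``alpha``."""

    edges: list[Edge]
    alpha: float
    two_tailed: bool = True

    def pairs(self, direction: str | None = None) -> list[str]:
        return [e.pair for e in self.edges if direction is None or e.direction == direction]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.pair, e.direction, e.t, e.p) for e in self.edges],
            columns=["pair", "direction", "t", "p"],
        )


def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"{name} series is constant (zero variance)")
    return (v - v.mean()) / sd


def estimate_pair_coupling(
    x: np.ndarray, y: np.ndarray, nuisance: np.ndarray | None = None
) -> float:
    """Average of the two GLM slopes between a pair of time series.

    x and y are z-scored internally, then ``y ~ 1 + x + nuisance`` and
    ``x ~ 1 + y + nuisance`` are fitted by least squares; the returned
    coupling is the mean of the two slope coefficients for the partner
    series.  Equals the Pearson correlation when ``nuisance`` is empty.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    xz = _zscore(x, "x")
    yz = _zscore(y, "y")
    T = x.size
    if nuisance is None:
        nuisance = np.empty((T, 0))
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim == 1:
        nuisance = nuisance[:, None]
    if nuisance.shape[0] != T:
        raise ValueError("nuisance rows must match the series length")

    def _slope(dep: np.ndarray, ind: np.ndarray) -> float:
        design = np.column_stack([np.ones(T), ind, nuisance])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            bad = _collinear_columns(design, ["intercept", "partner"] +
                                     [f"nuisance[{k}]" for k in range(nuisance.shape[1])])
            raise ValueError(f"rank-deficient GLM design; collinear regressors: {bad}")
        beta, *_ = np.linalg.lstsq(design, dep, rcond=None)
        return float(beta[1])

    return 0.5 * (_slope(yz, xz) + _slope(xz, yz))


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns involved in a rank deficiency (smallest singular directions)."""
    _, s, vt = np.linalg.svd(design, full_matrices=False)
    tol = s.max() * max(design.shape) * np.finfo(float).eps
    bad: set[str] = set()
    for k in range(len(s)):
        if s[k] <= tol:
            involved = np.flatnonzero(np.abs(vt[k]) > 1e-8)
            bad.update(names[i] for i in involved)
    return sorted(bad)


def coupling_vector(tc: TimecourseSet) -> CouplingVector:
    """All unordered pairwise couplings of a time-course set, canonical order.

    Uses the Frisch-Waugh identity: z-scored signals are residualised on
    [1, nuisance] once, after which the average of the two GLM slopes for
    a pair is ``C_ij * (1/C_ii + 1/C_jj) / 2`` with C the residual
    cross-product matrix.  This is algebraically identical to calling
    :func:`estimate_pair_coupling` per pair (and tested as such) but
    needs one pooled residualisation instead of O(n^2) regressions.
    """
    S = tc.signals
    n, T = S.shape
    sds = S.std(axis=1, ddof=1)
    if np.any(sds == 0):
        dead = [tc.network_labels[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant (zero-variance) network series: {dead}")
    Z = (S - S.mean(axis=1, keepdims=True)) / sds[:, None]
    D = np.column_stack([np.ones(T), tc.nuisance])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        bad = _collinear_columns(
            D, ["intercept"] + [f"nuisance[{k}]" for k in range(tc.nuisance.shape[1])]
        )
        raise ValueError(f"rank-deficient nuisance design; collinear regressors: {bad}")
    beta, *_ = np.linalg.lstsq(D, Z.T, rcond=None)
    R = Z.T - D @ beta  # time x networks residuals
    C = R.T @ R
    diag = np.diag(C)
    if np.any(diag <= 0):
        dead = [tc.network_labels[i] for i in np.flatnonzero(diag <= 0)]
        raise ValueError(f"network series fully explained by nuisance: {dead}")
    inv = 1.0 / diag
    avg_beta = C * (inv[None, :] + inv[:, None]) / 2.0
    pairs = canonical_pairs(n)
    values = np.array([avg_beta[i, j] for i, j in pairs])
    labels = [pair_label(tc.network_labels[i], tc.network_labels[j]) for i, j in pairs]
    return CouplingVector(values=values, n_networks=n, pair_labels=labels)


def coupling_table(timecourses: dict[str, TimecourseSet]) -> pd.DataFrame:
    """Subjects x pairs coupling matrix (rows indexed by subject id)."""
    rows, index = [], []
    labels: list[str] | None = None
    for sid, tc in timecourses.items():
        try:
            cv = coupling_vector(tc)
        except ValueError as err:
            raise ValueError(f"subject {sid}: {err}") from err
        if labels is None:
            labels = cv.pair_labels
        elif labels != cv.pair_labels:
            raise ValueError(f"subject {sid} has a different network-pair layout")
        rows.append(cv.values)
        index.append(sid)
    return pd.DataFrame(rows, index=pd.Index(index, name="subject_id"), columns=labels)


def edge_group_screen(
    couplings: pd.DataFrame,
    labels: Sequence[str],
    alpha: float = 0.02,
    patient_label: str = "prehd",
) -> EdgeSet:
    """Screen edges for group differences with uncorrected two-sample t tests.

    Per edge a pooled-variance (Student) two-sample t test compares
    patients against the remaining subjects; edges with two-tailed
    p < alpha are kept and split by sign of the patient-minus-control
    mean difference into ``hypo`` (lower in patients) and ``hyper``.
    No multiple-comparison correction is applied, by design.
    """
    labels = np.asarray(labels)
    if len(labels) != len(couplings):
        raise ValueError("labels length must match the number of subjects")
    pat = couplings.values[labels == patient_label]
    ctl = couplings.values[labels != patient_label]
    if len(pat) < 2 or len(ctl) < 2:
        raise ValueError(
            f"need >= 2 subjects per group, got {len(pat)} patients / {len(ctl)} others"
        )
    t, p = stats.ttest_ind(pat, ctl, axis=0, equal_var=True)
    diff = pat.mean(axis=0) - ctl.mean(axis=0)
    edges = [
        Edge(pair=col, direction="hypo" if diff[k] < 0 else "hyper",
             t=float(t[k]), p=float(p[k]))
        for k, col in enumerate(couplings.columns)
        if p[k] < alpha
    ]
    return EdgeSet(edges=edges, alpha=alpha)


def composite_score(
    cv: "CouplingVector | pd.Series", edges: EdgeSet, direction: str
) -> float | None:
    """Unweighted mean coupling over the screened edges of one direction.

    Returns ``None`` (an explicit "no composite defined" result, never
    zero) when the edge set contains no edge of the requested direction.
    """
    if direction not in ("hypo", "hyper"):
        raise ValueError(f"direction must be 'hypo' or 'hyper', got {direction!r}")
    pairs = edges.pairs(direction)
    if not pairs:
        return None
    if isinstance(cv, CouplingVector):
        series = pd.Series(cv.values, index=cv.pair_labels)
    else:
        series = cv
    missing = [p for p in pairs if p not in series.index]
    if missing:
        raise KeyError(f"couplings missing screened pairs: {missing}")
    return float(series.loc[pairs].mean())


def composite_table(couplings: pd.DataFrame, edges: EdgeSet) -> pd.DataFrame:
    """Per-subject hypo/hyper composite scores (columns of NaN if undefined)."""
    out = {}
    for direction in ("hypo", "hyper"):
        pairs = edges.pairs(direction)
        out[direction] = couplings[pairs].mean(axis=1) if pairs else np.nan
    return pd.DataFrame(out, index=couplings.index)
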