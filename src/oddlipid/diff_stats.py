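"""Differential-lipid statistics: preprocessing, Welch tests, PCA, PLS-DA/VIP.

The statistical pipeline mirrors common metabolomics practice: species are
filtered by interquartile range, log-transformed and Pareto-scaled; group
differences are assessed by two-sided Welch t-tests with Bonferroni
correction and raw-scale fold changes; multivariate structure is summarized
by PCA and by a two-class PLS-DA (NIPALS) whose variable importance in
projection (VIP) scores rank species, with S-plot and shared-and-unique-
structures (SUS) plot coordinates for visual triage.

Discriminant analysis here is PLS-DA with a single predictive interpretation
of the first component; for two-class problems its VIP ranking matches the
orthogonalized (OPLS-style) variant in practice, so selection thresholds
carry over.  Species are called differential when raw P < 0.05, VIP > 1 and
the direction-agnostic fold change is at least 20 %; the volcano rule uses
FC >= 2 and P < 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PreprocessResult",
    "PLSModel",
    "preprocess",
    "welch_fc",
    "pca_scores",
    "plsda_vip",
    "splot",
    "sus_plot",
    "select_differential",
    "volcano",
    "venn_sets",
]

DEFAULT_CV_SEED = 20230529
_EPS = 1e-12


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PreprocessResult:
    matrix: pd.DataFrame                 # species x samples, scaled
    dropped: pd.DataFrame                # component, reason
    state: tuple[str, ...] = ("iqr-filtered", "logged", "pareto-scaled")


def preprocess(
    matrix: pd.DataFrame,
    iqr_drop_fraction: float = 0.10,
    log_base: float = 10.0,
    scaling: str = "pareto",
) -> PreprocessResult:
    """IQR filter, log transform and Pareto scaling of an abundance matrix.

    The lowest-IQR fraction of species is dropped (low-information features),
    abundances are log-transformed, and each species row is centered and
    divided by the square root of its standard deviation (Pareto scaling) —
    a compromise between unit variance and no scaling that keeps large fold
    changes visible without letting noise dominate.  Rows are mean-zero
    afterwards; constant species are dropped.
    """
    if (matrix <= 0).any().any() or matrix.isna().any().any():
        raise ValueError("preprocess expects strictly positive, complete abundances")
    dropped: list[dict] = []
    work = matrix.copy()
    if iqr_drop_fraction > 0 and len(work) > 1:
        iqr = work.quantile(0.75, axis=1) - work.quantile(0.25, axis=1)
        n_drop = int(np.floor(iqr_drop_fraction * len(work)))
        if n_drop:
            low = iqr.nsmallest(n_drop).index
            dropped += [{"component": c, "reason": "low IQR"} for c in low]
            work = work.drop(index=low)
    logged = np.log(work) / np.log(log_base)
    sd = logged.std(axis=1, ddof=1)
    constant = sd.index[sd <= _EPS]
    dropped += [{"component": c, "reason": "zero variance"} for c in constant]
    logged = logged.drop(index=constant)
    sd = sd.drop(index=constant)
    centered = logged.sub(logged.mean(axis=1), axis=0)
    if scaling == "pareto":
        scaled = centered.div(np.sqrt(sd), axis=0)
    elif scaling == "unit":
        scaled = centered.div(sd, axis=0)
    elif scaling in (None, "none"):
        scaled = centered
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return PreprocessResult(
        matrix=scaled,
        dropped=pd.DataFrame(dropped, columns=["component", "reason"]),
    )


# ---------------------------------------------------------------------------
# Univariate: Welch test + fold change
# ---------------------------------------------------------------------------

def _group_columns(design: Mapping[str, str] | pd.Series, group: str) -> list[str]:
    if isinstance(design, pd.Series):
        return list(design.index[design == group])
    return [s for s, g in design.items() if g == group]


def welch_fc(
    matrix_raw: pd.DataFrame,
    matrix_processed: pd.DataFrame,
    design: Mapping[str, str] | pd.Series,
    group1: str,
    group2: str,
) -> pd.DataFrame:
    """Welch t-test on processed data plus raw-scale fold change group2/group1.

    Two-sided unequal-variance t-test with Welch-Satterthwaite degrees of
    freedom; Bonferroni adjustment P_adj = min(1, m*P); fold change computed
    on the raw (pre-log) group means.  Species with zero variance in both
    groups and equal means get P = 1.
    """
    s1 = [s for s in _group_columns(design, group1) if s in matrix_processed.columns]
    s2 = [s for s in _group_columns(design, group2) if s in matrix_processed.columns]
    if len(s1) < 3 or len(s2) < 3:
        raise ValueError("both groups need >= 3 samples")
    x1 = matrix_processed[s1].to_numpy(dtype=float)
    x2 = matrix_processed[s2].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(x1, x2, axis=1, equal_var=False)
    degenerate = np.isnan(p)
    equal_means = np.isclose(x1.mean(axis=1), x2.mean(axis=1))
    t = np.where(degenerate & equal_means, 0.0, t)
    p = np.where(degenerate & equal_means, 1.0, p)
    m = len(matrix_processed)
    raw = matrix_raw.reindex(matrix_processed.index)
    fc = raw[s2].mean(axis=1) / raw[s1].mean(axis=1)
    out = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "p_adj": np.minimum(1.0, np.asarray(p) * m),
            "fc": fc.to_numpy(),
        },
        index=matrix_processed.index,
    )
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame                 # samples x components
    loadings: pd.DataFrame               # species x components
    explained_variance_ratio: np.ndarray


def pca_scores(matrix_processed: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Sample scores from a centered SVD of the samples x species matrix.

    The sign convention fixes each component so its largest-magnitude
    loading is positive.  ``n_components`` above the matrix rank is capped
    with a warning.
    """
    X = matrix_processed.to_numpy(dtype=float).T  # samples x species
    X = X - X.mean(axis=0, keepdims=True)
    rank = int(np.linalg.matrix_rank(X))
    if n_components > rank:
        warnings.warn(f"n_components capped at rank {rank}")
        n_components = rank
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    for k in range(n_components):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    scores = u[:, :n_components] * s[:n_components]
    total_var = float((s ** 2).sum())
    evr = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    comp = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix_processed.columns, columns=comp),
        loadings=pd.DataFrame(vt[:n_components].T, index=matrix_processed.index,
                              columns=comp),
        explained_variance_ratio=evr,
    )


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS) + VIP
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Two-class PLS-DA fitted by NIPALS against a centered +/-1 response."""

    n_components: int
    weights: pd.DataFrame        # species x A, unit-norm columns
    scores: pd.DataFrame         # samples x A
    x_loadings: pd.DataFrame     # species x A
    y_loadings: np.ndarray       # q per component
    ss_y: np.ndarray             # explained Y sum of squares per component
    r2y: float
    q2: float | None
    group1: str
    group2: str
    samples: tuple[str, ...] = field(default_factory=tuple)

    @property
    def t1(self) -> pd.Series:
        return self.scores.iloc[:, 0]


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS PLS1: returns (W, T, P, q, ss_y), possibly fewer components."""
    n, p = X.shape
    Xd = X.copy()
    yd = y.copy()
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    ss = np.zeros(n_components)
    achieved = 0
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm <= _EPS:
            warnings.warn(f"singular deflation: stopping at {achieved} components")
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _EPS:
            warnings.warn(f"singular deflation: stopping at {achieved} components")
            break
        p_load = Xd.T @ t / tt
        q_a = float(yd @ t) / tt
        Xd -= np.outer(t, p_load)
        yd = yd - q_a * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p_load, q_a
        ss[a] = q_a ** 2 * tt
        achieved += 1
    k = achieved
    return W[:, :k], T[:, :k], P[:, :k], q[:k], ss[:k]


def _pls_coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    return W @ np.linalg.solve(P.T @ W, q)


def _stratified_folds(
    labels: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for value in np.unique(labels):
        idx = np.flatnonzero(labels == value)
        rng.shuffle(idx)
        for i, sample in enumerate(idx):
            folds[i % n_folds].append(sample)
    return [np.array(sorted(f)) for f in folds if len(f)]


def plsda_vip(
    matrix_processed: pd.DataFrame,
    design: Mapping[str, str] | pd.Series,
    group1: str,
    group2: str,
    n_components: int = 2,
    cv_folds: int = 7,
    cv_seed: int = DEFAULT_CV_SEED,
) -> tuple[PLSModel, pd.Series]:
    """Fit two-class PLS-DA and compute per-species VIP scores.

    The response is +1 for ``group2``, -1 for ``group1`` (centered), so a
    positive first-component score means "up in group2".  VIP_j =
    sqrt(p * sum_a SS_a w_ja^2 / sum_a SS_a) with unit-norm weights, which
    makes sum_j VIP_j^2 = p exactly.  Q2 comes from seeded, group-stratified
    7-fold cross-validation.
    """
    s1 = [s for s in _group_columns(design, group1) if s in matrix_processed.columns]
    s2 = [s for s in _group_columns(design, group2) if s in matrix_processed.columns]
    samples = s1 + s2
    X = matrix_processed[samples].to_numpy(dtype=float).T  # samples x species
    y = np.array([-1.0] * len(s1) + [1.0] * len(s2))
    n, p = X.shape
    n_components = min(n_components, n - 1, p)
    Xc = X - X.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    W, T, P, q, ss = _nipals_pls1(Xc, yc, n_components)
    k = W.shape[1]
    ss_total = float(yc @ yc)
    r2y = float(ss.sum() / ss_total) if ss_total > 0 else 0.0

    q2: float | None = None
    if cv_folds >= 2 and n >= cv_folds:
        labels = np.array([0] * len(s1) + [1] * len(s2))
        press = 0.0
        for fold in _stratified_folds(labels, cv_folds, cv_seed):
            train = np.setdiff1d(np.arange(n), fold)
            Xt = X[train] - X[train].mean(axis=0, keepdims=True)
            yt = y[train] - y[train].mean()
            Wt, Tt, Pt, qt, _ = _nipals_pls1(Xt, yt, k)
            if Wt.shape[1] == 0:
                continue
            beta = _pls_coefficients(Wt, Pt, qt)
            Xv = X[fold] - X[train].mean(axis=0, keepdims=True)
            pred = Xv @ beta + y[train].mean()
            press += float(((y[fold] - pred) ** 2).sum())
        q2 = 1.0 - press / float(((y - y.mean()) ** 2).sum())

    ss_sum = ss.sum()
    if ss_sum <= 0:
        vip = np.zeros(p)
    else:
        vip = np.sqrt(p * (W ** 2 @ ss) / ss_sum)
    comp = [f"C{a + 1}" for a in range(k)]
    model = PLSModel(
        n_components=k,
        weights=pd.DataFrame(W, index=matrix_processed.index, columns=comp),
        scores=pd.DataFrame(T, index=samples, columns=comp),
        x_loadings=pd.DataFrame(P, index=matrix_processed.index, columns=comp),
        y_loadings=q,
        ss_y=ss,
        r2y=r2y,
        q2=q2,
        group1=group1,
        group2=group2,
        samples=tuple(samples),
    )
    return model, pd.Series(vip, index=matrix_processed.index, name="vip")


# ---------------------------------------------------------------------------
# S-plot and SUS-plot
# ---------------------------------------------------------------------------

def splot(model: PLSModel, matrix_processed: pd.DataFrame) -> pd.DataFrame:
    """S-plot coordinates: covariance and correlation of each species with t1.

    Zero-variance species are excluded.  High |cov| with high |corr| marks
    reliable, strongly changing species.
    """
    t1 = model.t1.to_numpy(dtype=float)
    X = matrix_processed[list(model.samples)].to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    t1c = t1 - t1.mean()
    n = len(t1)
    cov = Xc @ t1c / (n - 1)
    sx = Xc.std(axis=1, ddof=1)
    st = t1c.std(ddof=1)
    keep = sx > _EPS
    corr = np.full_like(cov, np.nan)
    corr[keep] = cov[keep] / (sx[keep] * st)
    out = pd.DataFrame(
        {"cov": cov, "corr": np.clip(corr, -1.0, 1.0)},
        index=matrix_processed.index,
    )
    return out[keep]


def sus_plot(
    model1: PLSModel,
    model2: PLSModel,
    matrix_processed: pd.DataFrame,
) -> pd.DataFrame:
    """SUS-plot: corr(t1, x) of comparison 1 against comparison 2, per species.

    Species unique to one comparison fall near an axis (second/fourth
    quadrant when regulated in opposite directions); shared species lie on
    the diagonal.
    """
    c1 = splot(model1, matrix_processed)["corr"].rename("corr_1")
    c2 = splot(model2, matrix_processed)["corr"].rename("corr_2")
    return pd.concat([c1, c2], axis=1, join="inner")


# ---------------------------------------------------------------------------
# Selection rules
# ---------------------------------------------------------------------------

def select_differential(
    results: pd.DataFrame,
    p_max: float = 0.05,
    vip_min: float = 1.0,
    fc_min: float = 1.2,
    use_adjusted: bool = False,
) -> pd.Series:
    """Differential verdict: P below threshold, VIP above 1, |FC| >= 20 %.

    The fold-change criterion is direction-agnostic: max(FC, 1/FC) >= fc_min.
    Raw P is used by default; set ``use_adjusted`` for Bonferroni-adjusted P.
    """
    p = results["p_adj"] if use_adjusted else results["p"]
    fc = results["fc"]
    return (
        (p < p_max)
        & (results["vip"] > vip_min)
        & (np.maximum(fc, 1.0 / fc) >= fc_min)
    ).rename("differential")


def volcano(
    results: pd.DataFrame, fc_min: float = 2.0, p_max: float = 0.1
) -> pd.Series:
    """Volcano verdict: 'up' / 'down' for |FC| >= fc_min and P < p_max, else 'ns'."""
    fc = results["fc"]
    sig = (np.maximum(fc, 1.0 / fc) >= fc_min) & (results["p"] < p_max)
    out = pd.Series("ns", index=results.index, name="volcano")
    out[sig & (fc > 1)] = "up"
    out[sig & (fc < 1)] = "down"
    return out


def venn_sets(named_sets: Mapping[str, Sequence[str]]) -> dict[str, set[str]]:
    """Named sets, their pairwise-style intersection and per-set unique members."""
    sets = {name: set(v) for name, v in named_sets.items()}
    inter = set.intersection(*sets.values()) if sets else set()
    out: dict[str, set[str]] = {"intersection": inter}
    for name, members in sets.items():
        out[f"unique:{name}"] = members - inter
    return out
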