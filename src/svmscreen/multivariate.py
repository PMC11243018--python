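"""Multivariate chemometrics: PCA, hierarchical clustering, OPLS-DA.

OPLS-DA is implemented as a regression-mode PLS1 on a -1/+1 class
encoding, preceded by removal of y-orthogonal components (orthogonal
signal correction).  For each orthogonal component the candidate loading
is the part of the X-loading orthogonal to the predictive weight; the
corresponding score/loading pair is deflated from X before the single
predictive component is extracted.  R2Y measures the class-label variance
explained on the training data; Q2 the variance explained under k-fold
cross-validation with deterministic interleaved ("venetian blind") folds.

Model validity is diagnosed by a label-permutation test: the model is
refitted under randomly permuted labels, R2Y and Q2Y are plotted against
the absolute correlation between permuted and original labels, and
regression lines (including the unpermuted point at correlation 1) are
fitted through each set of points.  Low intercepts — R2Y-intercept below
0.4 (0.3 as a stricter warning bound) and Q2Y-intercept below 0.05 —
together with an empirical Q2 p-value below 0.05 indicate a model free of
over-fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ScaledMatrix",
    "PcaModel",
    "OplsModel",
    "PermResult",
    "scale",
    "pca",
    "hcluster",
    "oplsda_fit",
    "vip",
    "permutation_test",
]


@dataclass
class ScaledMatrix:
    """Centered (and optionally scaled) samples x variables matrix."""

    x: np.ndarray
    means: np.ndarray
    scales: np.ndarray
    mode: str
    columns: pd.Index | None = None

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]

    @property
    def n_variables(self) -> int:
        return self.x.shape[1]

    def apply(self, raw: np.ndarray) -> np.ndarray:
        """Project new raw rows into the fitted centred/scaled space."""
        return (np.asarray(raw, dtype=float) - self.means) / self.scales


def scale(matrix, mode: str = "uv") -> ScaledMatrix:
    """Center and scale a samples x variables matrix.

    Modes: ``uv`` (unit variance), ``pareto`` (divide by sqrt of sd) and
    ``none`` (centering only).  Constant columns are centered and given a
    unit scale factor.
    """
    columns = matrix.columns if isinstance(matrix, pd.DataFrame) else None
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.size == 0:
        raise ValueError("need a 2-D matrix with at least two samples")
    means = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if mode == "uv":
        scales = np.where(sd > 0, sd, 1.0)
    elif mode == "pareto":
        scales = np.where(sd > 0, np.sqrt(sd), 1.0)
    elif mode == "none":
        scales = np.ones_like(sd)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return ScaledMatrix((x - means) / scales, means, scales, mode, columns)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaModel:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # variables x components
    r2x: np.ndarray  # explained variance fraction per component
    ellipse: tuple[float, float]  # 95% Hotelling semi-axes on (t1, t2)


def pca(xs: ScaledMatrix, n_components: int = 2) -> PcaModel:
    """Principal components of a scaled matrix, via SVD.

    The 95% confidence ellipse on the first two score dimensions follows
    Hotelling's T2 with an F-distribution quantile.
    """
    n, p = xs.x.shape
    if n_components > min(n - 1, p):
        raise ValueError("n_components exceeds matrix rank bound")
    u, s, vt = np.linalg.svd(xs.x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    r2x = (s[:n_components] ** 2) / np.sum(xs.x**2)

    if n_components >= 2 and n > 2:
        t2_lim = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(0.95, 2, n - 2)
        semi = tuple(
            float(np.sqrt(scores[:, i].var(ddof=1) * t2_lim)) for i in range(2)
        )
    else:
        semi = (np.nan, np.nan)
    return PcaModel(scores, loadings, r2x, semi)


def hcluster(
    xs: ScaledMatrix, linkage: str = "ward", metric: str = "euclidean", k: int | None = None
):
    """Agglomerative clustering of samples.

    Returns the scipy merge tree, and flat labels when ``k`` is given.
    """
    if xs.n_samples < 2:
        raise ValueError("clustering needs at least two samples")
    if linkage not in ("single", "complete", "average", "ward"):
        raise ValueError(f"unknown linkage {linkage!r}")
    try:
        dist = pdist(xs.x, metric=metric)
    except ValueError as exc:
        raise ValueError(f"unknown metric {metric!r}") from exc
    tree = hierarchy.linkage(dist, method=linkage)
    labels = hierarchy.fcluster(tree, k, criterion="maxclust") if k else None
    return tree, labels


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


def _encode_labels(y) -> tuple[np.ndarray, np.ndarray]:
    """Map a two-class label vector onto -1/+1."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {len(classes)}")
    return np.where(y == classes[1], 1.0, -1.0), classes


def _osc_deflate(x: np.ndarray, y: np.ndarray, n_orthogonal: int):
    """Remove up to n_orthogonal y-orthogonal components from x."""
    x = x.copy()
    w_os, p_os, t_os = [], [], []
    for _ in range(n_orthogonal):
        w = x.T @ y
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w = w / nw
        t = x @ w
        p = x.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break
        w_o = w_o / n_o
        t_o = x @ w_o
        p_o = x.T @ t_o / (t_o @ t_o)
        x = x - np.outer(t_o, p_o)
        w_os.append(w_o)
        p_os.append(p_o)
        t_os.append(t_o)
    return x, w_os, p_os, t_os


def _predictive_component(x: np.ndarray, y: np.ndarray):
    w = x.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("response carries no covariance with the matrix")
    w = w / nw
    t = x @ w
    p = x.T @ t / (t @ t)
    q = (y @ t) / (t @ t)
    return w, t, p, q


@dataclass
class OplsModel:
    """Fitted one-predictive-component OPLS-DA model."""

    weights: np.ndarray  # predictive weights w (unit norm)
    scores: np.ndarray  # predictive scores t
    loadings: np.ndarray  # predictive loadings p
    q_coef: float  # inner regression coefficient
    ortho_weights: list = field(default_factory=list)
    ortho_loadings: list = field(default_factory=list)
    ortho_scores: list = field(default_factory=list)
    r2y: float = np.nan
    q2: float = np.nan
    vip: np.ndarray | None = None
    splot: pd.DataFrame | None = None
    classes: np.ndarray | None = None
    y_mean: float = 0.0
    columns: pd.Index | None = None

    def predict_scores(self, x_new: np.ndarray) -> np.ndarray:
        """Predictive scores for new (already scaled) rows."""
        x = np.asarray(x_new, dtype=float).copy()
        for w_o, p_o in zip(self.ortho_weights, self.ortho_loadings):
            t_o = x @ w_o
            x = x - np.outer(t_o, p_o)
        return x @ self.weights


def _fit_core(x: np.ndarray, y_enc: np.ndarray, n_orthogonal: int):
    y_c = y_enc - y_enc.mean()
    x_def, w_os, p_os, t_os = _osc_deflate(x, y_c, n_orthogonal)
    w, t, p, q = _predictive_component(x_def, y_c)
    return y_c, x_def, w_os, p_os, t_os, w, t, p, q


def _q2_cross_val(
    x: np.ndarray, y_enc: np.ndarray, n_orthogonal: int, cv_folds: int
) -> float:
    n = len(y_enc)
    folds = min(cv_folds, n)
    press = 0.0
    ss = np.sum((y_enc - y_enc.mean()) ** 2)
    for k in range(folds):
        test = np.arange(n) % folds == k
        train = ~test
        if len(np.unique(y_enc[train])) < 2:
            continue
        mu = x[train].mean(axis=0)  # re-center per training fold
        y_c, _, w_os, p_os, _, w, t, p, q = _fit_core(
            x[train] - mu, y_enc[train], n_orthogonal
        )
        x_test = x[test] - mu
        for w_o, p_o in zip(w_os, p_os):
            t_o = x_test @ w_o
            x_test = x_test - np.outer(t_o, p_o)
        y_hat = (x_test @ w) * q + y_enc[train].mean()
        press += np.sum((y_enc[test] - y_hat) ** 2)
    return 1.0 - press / ss


def oplsda_fit(
    xs: ScaledMatrix, y, n_orthogonal: int = 1, cv_folds: int = 7
) -> OplsModel:
    """Fit a two-class OPLS-DA model with one predictive component.

    ``n_orthogonal`` y-orthogonal components are deflated before the
    predictive component is extracted.  Q2 comes from deterministic
    interleaved k-fold cross-validation on the scaled matrix.
    """
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be non-negative")
    y_enc, classes = _encode_labels(y)
    x = xs.x
    y_c, x_def, w_os, p_os, t_os, w, t, p, q = _fit_core(x, y_enc, n_orthogonal)

    y_hat = t * q
    r2y = 1.0 - np.sum((y_c - y_hat) ** 2) / np.sum(y_c**2)
    q2 = _q2_cross_val(x, y_enc, n_orthogonal, cv_folds)

    # S-plot statistics against the predictive score
    n = len(y_enc)
    tc = t - t.mean()
    xc = x_def - x_def.mean(axis=0)
    p1 = (tc @ xc) / (n - 1)
    sd_t = tc.std(ddof=1)
    sd_x = xc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pcorr1 = np.where(sd_x > 0, p1 / (sd_t * sd_x), 0.0)
    splot = pd.DataFrame({"p1": p1, "pcorr1": pcorr1}, index=xs.columns)

    model = OplsModel(
        weights=w,
        scores=t,
        loadings=p,
        q_coef=q,
        ortho_weights=w_os,
        ortho_loadings=p_os,
        ortho_scores=t_os,
        r2y=float(r2y),
        q2=float(q2),
        splot=splot,
        classes=classes,
        y_mean=float(y_enc.mean()),
        columns=xs.columns,
    )
    model.vip = vip(model)
    return model


def vip(model: OplsModel) -> np.ndarray:
    """Variable importance in projection over the predictive component(s).

    VIP_j = sqrt(p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a); the
    mean of VIP^2 over variables is 1 by construction.
    """
    if model.weights is None:
        raise ValueError("model is not fitted")
    w = model.weights
    p_vars = len(w)
    frac = (w / np.linalg.norm(w)) ** 2  # single predictive component
    return np.sqrt(p_vars * frac)


@dataclass
class PermResult:
    """Label-permutation diagnostics of an OPLS-DA model."""

    iterations: pd.DataFrame  # columns: correlation, r2y, q2
    r2_intercept: float
    q2_intercept: float
    p_value: float
    r2y_original: float
    q2_original: float
    valid: bool
    r2_warning: bool  # True when the stricter 0.3 bound is exceeded

    @property
    def overfit_free(self) -> bool:
        """The operative over-fitting judgment: Q2Y intercept and p-value.

        The R2Y-intercept bound is an experience range rather than a sharp
        decision rule; over-fitting is diagnosed from the Q2Y intercept
        (<= 0.05) and the empirical significance of Q2 (p < 0.05).
        """
        return self.q2_intercept <= 0.05 and self.p_value < 0.05


def permutation_test(
    xs: ScaledMatrix,
    y,
    n_iter: int = 200,
    seed: int = 0,
    n_orthogonal: int = 1,
    cv_folds: int = 7,
) -> PermResult:
    """Refit the model under permuted labels and fit intercept diagnostics.

    For each iteration the labels are permuted, the model refitted, and
    (|corr(y_perm, y)|, R2Y, Q2Y) recorded.  Least-squares lines through
    the permuted points plus the unpermuted point (correlation 1) give the
    background intercepts.  The empirical p-value of Q2 is
    (1 + #{permuted Q2 >= original Q2}) / (n_iter + 1).
    """
    if n_iter < 10:
        raise ValueError("permutation test needs at least 10 iterations")
    rng = np.random.default_rng(seed)
    y_enc, _ = _encode_labels(y)

    original = oplsda_fit(xs, y_enc, n_orthogonal, cv_folds)
    rows = []
    for _ in range(n_iter):
        y_perm = rng.permutation(y_enc)
        corr = abs(float(np.corrcoef(y_perm, y_enc)[0, 1]))
        try:
            m = oplsda_fit(xs, y_perm, n_orthogonal, cv_folds)
            rows.append((corr, m.r2y, m.q2))
        except ValueError:  # degenerate permutation (all-equal encoded y)
            continue
    perm = pd.DataFrame(rows, columns=["correlation", "r2y", "q2"])

    cx = np.append(perm["correlation"].to_numpy(), 1.0)
    r2_line = np.polyfit(cx, np.append(perm["r2y"].to_numpy(), original.r2y), 1)
    q2_line = np.polyfit(cx, np.append(perm["q2"].to_numpy(), original.q2), 1)
    r2_intercept = float(r2_line[1])
    q2_intercept = float(q2_line[1])
    p_value = (1 + int((perm["q2"] >= original.q2).sum())) / (len(perm) + 1)

    valid = r2_intercept <= 0.4 and q2_intercept <= 0.05 and p_value < 0.05
    return PermResult(
        iterations=perm,
        r2_intercept=r2_intercept,
        q2_intercept=q2_intercept,
        p_value=float(p_value),
        r2y_original=original.r2y,
        q2_original=original.q2,
        valid=valid,
        r2_warning=r2_intercept > 0.3,
    )
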