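"""Genomic prediction models mapping SNP genotypes to shape descriptors.

Four model families are provided:

* ``RR``   — ridge regression / GBLUP: a mixed model with the realized
  additive relationship matrix as genetic covariance, one descriptor at
  a time, variance ratio estimated by REML.
* ``KRR``  — the same machinery with a Gaussian kernel (bandwidth from
  the median heuristic h = 2 / d_m^2).
* ``PLS``  — multi-response linear partial least squares (NIPALS),
  predicting all descriptors jointly.
* ``KPLS`` — kernel PLS with the Rosipal–Trejo deflation scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh as scipy_eigh

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "KernelMatrix",
    "FittedModel",
    "RRModel",
    "PLSModel",
    "KPLSModel",
    "additive_relationship",
    "additive_cross",
    "gaussian_kernel",
    "gaussian_cross",
    "median_heuristic_bandwidth",
    "fit_rr",
    "fit_krr",
    "predict_rr_krr",
    "fit_pls",
    "predict_pls",
    "fit_kpls",
    "predict_kpls",
    "select_ncomp",
    "make_folds",
]

MAX_PLS_COMPONENTS = 30


@dataclass
class GenotypeMatrix:
    """Accessions x markers genotype scores in [-1, 1].

    Observed biallelic genotypes of inbred accessions are coded 1 / -1;
    fractional values are mean-imputation scores and are used as-is.
    """

    scores: np.ndarray
    accession_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("genotype scores must be a 2-D array")
        n, m = self.scores.shape
        if n < 2 or m < 1:
            raise ValueError("need at least 2 accessions and 1 marker")
        if len(self.accession_ids) != n or len(self.marker_ids) != m:
            raise ValueError("id lists must match the score matrix shape")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("genotype scores contain missing values; impute first")
        if np.any(np.abs(self.scores) > 1.0 + 1e-9):
            raise ValueError("genotype scores must lie in [-1, 1]")

    @property
    def n_accessions(self) -> int:
        return self.scores.shape[0]

    @property
    def n_markers(self) -> int:
        return self.scores.shape[1]

    def subset(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.scores[idx],
            [self.accession_ids[i] for i in np.atleast_1d(idx)],
            list(self.marker_ids),
        )


@dataclass
class KernelMatrix:
    """Symmetric accessions x accessions kernel."""

    values: np.ndarray
    kind: str  # "additive-relationship", "gaussian" or "linear"
    bandwidth: float | None = None
    accession_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kernel matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kernel matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def mean_impute(scores: np.ndarray) -> np.ndarray:
    """Replace missing genotype scores (NaN) with their marker mean.

    A deliberately simple stand-in for model-based imputation; columns
    that are entirely missing become 0 (the mid-point of the coding).
    """
    scores = np.array(scores, dtype=float)
    col_mean = np.nanmean(np.where(np.isnan(scores), np.nan, scores), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    nan_r, nan_c = np.nonzero(np.isnan(scores))
    scores[nan_r, nan_c] = col_mean[nan_c]
    return scores


# ---------------------------------------------------------------------------
# kernels


def _additive_parts(train_scores: np.ndarray) -> tuple[np.ndarray, float]:
    """Column centering vector and normalizer of the realized relationship.

    On the -1/1 coding the allele frequency p of the '+' allele gives a
    column mean of 2p - 1 and a column variance of 4p(1-p); the
    relationship is the centered cross-product divided by the summed
    column variances, which puts the diagonal near 1.
    """
    mu = train_scores.mean(axis=0)
    p = (mu + 1.0) / 2.0
    norm = float(np.sum(4.0 * p * (1.0 - p)))
    if norm <= 0.0:
        raise ValueError("all markers are monomorphic; relationship undefined")
    return mu, norm


def additive_relationship(G: GenotypeMatrix) -> KernelMatrix:
    """VanRaden-type realized additive relationship matrix."""
    mu, norm = _additive_parts(G.scores)
    W = G.scores - mu
    A = (W @ W.T) / norm
    A = 0.5 * (A + A.T)
    return KernelMatrix(A, kind="additive-relationship", accession_ids=list(G.accession_ids))


def additive_cross(
    test_scores: np.ndarray, train_scores: np.ndarray
) -> np.ndarray:
    """Test x train additive relationship rows, centered on the training set."""
    mu, norm = _additive_parts(train_scores)
    return ((test_scores - mu) @ (train_scores - mu).T) / norm


def median_heuristic_bandwidth(rows: np.ndarray) -> float:
    """h = 2 / d_m^2 with d_m the median Euclidean distance over distinct pairs."""
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    if n < 2:
        raise ValueError("median heuristic needs at least 2 accessions")
    sq = np.sum(rows**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * rows @ rows.T
    iu = np.triu_indices(n, k=1)
    dm = float(np.median(np.sqrt(np.maximum(d2[iu], 0.0))))
    if dm <= 0.0:
        raise ValueError("all accessions identical; median distance is zero")
    return 2.0 / dm**2


def gaussian_cross(
    rows_a: np.ndarray, rows_b: np.ndarray, h: float
) -> np.ndarray:
    """Gaussian kernel block exp(-h ||x - x'||^2) between two sets of rows."""
    a = np.asarray(rows_a, dtype=float)
    b = np.asarray(rows_b, dtype=float)
    d2 = (
        np.sum(a**2, axis=1)[:, None]
        + np.sum(b**2, axis=1)[None, :]
        - 2.0 * a @ b.T
    )
    return np.exp(-h * np.maximum(d2, 0.0))


def gaussian_kernel(
    G_rows: np.ndarray | GenotypeMatrix, h: float | str = "median-heuristic"
) -> KernelMatrix:
    """Gaussian kernel matrix over genotype rows.

    ``h`` may be an explicit bandwidth or "median-heuristic", in which
    case h = 2 / d_m^2 with d_m the median pairwise distance (distinct
    unordered pairs only; self-distances are excluded).
    """
    ids = None
    if isinstance(G_rows, GenotypeMatrix):
        ids = list(G_rows.accession_ids)
        G_rows = G_rows.scores
    rows = np.asarray(G_rows, dtype=float)
    if rows.shape[0] < 2:
        raise ValueError("need at least 2 accessions")
    if isinstance(h, str):
        if h != "median-heuristic":
            raise ValueError(f"unknown bandwidth rule {h!r}")
        h = median_heuristic_bandwidth(rows)
    K = gaussian_cross(rows, rows, float(h))
    np.fill_diagonal(K, 1.0)
    K = 0.5 * (K + K.T)
    return KernelMatrix(K, kind="gaussian", bandwidth=float(h), accession_ids=ids)


# ---------------------------------------------------------------------------
# RR / KRR: mixed model y = mu + g + e,  g ~ N(0, sg^2 K),  e ~ N(0, se^2 I)


@dataclass
class FittedModel:
    """Base class for fitted prediction models."""

    method: str
    accession_ids: list[str] | None = None


@dataclass
class RRModel(FittedModel):
    """Kernel mixed model with REML-estimated variance ratio.

    ``lambda_`` holds se^2/sg^2 per response; ``alpha`` the BLUP dual
    coefficients (K + lambda I)^-1 (y - mu); predictions for new kernel
    rows k are mu + k @ alpha.
    """

    mu: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lambda_: np.ndarray = field(default_factory=lambda: np.zeros(0))
    alpha: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    kernel_kind: str = ""
    bandwidth: float | None = None


_LAMBDA_GRID = np.logspace(-6.0, 6.0, 121)


def _reml_profile(
    s: np.ndarray, yt: np.ndarray, xt: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Profiled REML log-likelihood for all responses at one variance ratio.

    Works in the eigenbasis of K: marginal variances are sg^2 (s + lam).
    Returns (loglik per response, GLS intercept, residual sum of squares).
    """
    w = 1.0 / (s + lam)
    xwx = float(np.sum(w * xt**2))
    mu = (xt * w) @ yt / xwx
    r = yt - np.outer(xt, mu)
    rss = np.einsum("i,ij,ij->j", w, r, r)
    n = s.size
    df = n - 1
    sigma_g2 = np.maximum(rss / df, 1e-300)
    ll = -0.5 * (
        df * np.log(2.0 * np.pi * sigma_g2)
        + np.sum(np.log(s + lam))
        + np.log(xwx)
        + df
    )
    return ll, mu, rss


def _fit_kernel_mixed(K: KernelMatrix, Y: np.ndarray, method: str) -> RRModel:
    Y = np.asarray(Y, dtype=float)
    single = Y.ndim == 1
    Y2 = Y[:, None] if single else Y
    n, q = Y2.shape
    if K.n != n:
        raise ValueError("kernel and response dimensions disagree")

    s, U = np.linalg.eigh(K.values)
    tol = 1e-8 * max(1.0, float(s.max()))
    if s.min() < -tol:
        jitter = 1e-8 * float(np.trace(K.values)) / n
        logger.warning(
            "kernel not PSD (min eig %.3g); adding ridge jitter %.3g", s.min(), jitter
        )
        s = s + jitter
        if s.min() < -tol:
            raise ValueError("kernel matrix is not positive semi-definite")
    s = np.maximum(s, 0.0)

    yt = U.T @ Y2
    xt = U.T @ np.ones(n)

    col_var = Y2.var(axis=0)
    active = col_var > 1e-28 * max(1.0, float(np.max(col_var, initial=0.0)))

    grid = _LAMBDA_GRID
    ll = np.full((grid.size, q), -np.inf)
    for i, lam in enumerate(grid):
        ll[i], _, _ = _reml_profile(s, yt, xt, lam)
    best = np.argmax(ll, axis=0)

    # parabolic refinement in log-lambda around the grid optimum
    lam_hat = grid[best].astype(float)
    interior = (best > 0) & (best < grid.size - 1)
    if np.any(interior):
        idx = np.nonzero(interior)[0]
        b = best[idx]
        lg = np.log(grid)
        y0, y1, y2 = ll[b - 1, idx], ll[b, idx], ll[b + 1, idx]
        denom = y0 - 2.0 * y1 + y2
        ok = denom < -1e-12
        shift = np.where(ok, 0.5 * (y0 - y2) / denom, 0.0)
        step = lg[1] - lg[0]
        lam_hat[idx] = np.exp(lg[b] + np.clip(shift, -1.0, 1.0) * step)

    mu = np.empty(q)
    alpha = np.zeros((n, q))
    for j in range(q):
        if not active[j]:
            mu[j] = Y2[:, j].mean()
            continue
        w = 1.0 / (s + lam_hat[j])
        xwx = float(np.sum(w * xt**2))
        mu[j] = float((xt * w) @ yt[:, j] / xwx)
        alpha[:, j] = U @ (w * (yt[:, j] - xt * mu[j]))
    lam_hat[~active] = np.inf

    model = RRModel(
        method=method,
        accession_ids=K.accession_ids,
        mu=mu if not single else mu,
        lambda_=lam_hat,
        alpha=alpha,
        kernel_kind=K.kind,
        bandwidth=K.bandwidth,
    )
    return model


def fit_rr(K: KernelMatrix, y: np.ndarray) -> RRModel:
    """Ridge regression / GBLUP with an additive relationship matrix.

    ``y`` may be a vector (one descriptor) or a matrix whose columns are
    fitted independently but share the kernel eigendecomposition.
    """
    if K.kind != "additive-relationship":
        raise ValueError("fit_rr expects an additive-relationship kernel")
    return _fit_kernel_mixed(K, y, "RR")


def fit_krr(K: KernelMatrix, y: np.ndarray) -> RRModel:
    """Gaussian kernel ridge regression (same mixed model, Gaussian kernel)."""
    if K.kind != "gaussian":
        raise ValueError("fit_krr expects a gaussian kernel")
    return _fit_kernel_mixed(K, y, "KRR")


def predict_rr_krr(model: RRModel, K_cross: np.ndarray) -> np.ndarray:
    """Predict responses from test x train kernel rows: mu + K_cross alpha."""
    K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
    if K_cross.shape[1] != model.alpha.shape[0]:
        raise ValueError(
            f"K_cross has {K_cross.shape[1]} columns but the model was trained "
            f"on {model.alpha.shape[0]} accessions"
        )
    return model.mu + K_cross @ model.alpha


# ---------------------------------------------------------------------------
# PLS / KPLS


@dataclass
class PLSModel(FittedModel):
    """Multi-response NIPALS PLS fit (scores normalized to unit length)."""

    x_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    y_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    W: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))  # X weights
    P: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))  # X loadings
    C: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))  # Y weights
    ncomp: int = 0


@dataclass
class KPLSModel(FittedModel):
    """Kernel PLS fit storing the factors needed for out-of-sample prediction.

    ``A`` = T' Kc0 U and ``G`` = T' Yc are cached so that predictions at
    any truncated component count need only a small triangular solve.
    """

    y_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    T: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))  # scores
    U: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))  # Y-space scores
    K_train: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    Yc: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    A: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    G: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    kernel_kind: str = ""
    bandwidth: float | None = None
    ncomp: int = 0


def _dominant_eigvec(B: np.ndarray) -> tuple[np.ndarray, float]:
    """Dominant eigenpair of a symmetric PSD matrix (only that pair is computed)."""
    q = B.shape[0]
    if q == 1:
        return np.ones(1), float(B[0, 0])
    evals, evecs = scipy_eigh(B, subset_by_index=[q - 1, q - 1], check_finite=False)
    return evecs[:, 0].copy(), float(evals[0])


def _dominant_left_singular(S: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading left singular vector and value of S (the NIPALS fixed point)."""
    if S.shape[1] == 1:
        sv = float(np.linalg.norm(S[:, 0]))
        return (S[:, 0] / sv if sv > 0 else S[:, 0].copy()), sv
    # Gram trick on the smaller side: only the dominant pair is needed
    if S.shape[1] <= S.shape[0]:
        v, lam = _dominant_eigvec(S.T @ S)
        sv = float(np.sqrt(max(lam, 0.0)))
        w = S @ v
        nw = np.linalg.norm(w)
        return (w / nw if nw > 0 else w), sv
    w, lam = _dominant_eigvec(S @ S.T)
    return w, float(np.sqrt(max(lam, 0.0)))


def fit_pls(X: np.ndarray, Y: np.ndarray, ncomp: int) -> PLSModel:
    """Multi-response linear PLS (PLS2) with Y deflation.

    Each component's X-weight w is the leading left singular vector of
    the cross-covariance Xc' Yc — the fixed point of the NIPALS power
    iteration, computed directly for determinism — and both blocks are
    deflated by the unit-norm score t = Xc w.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    rank_bound = min(n - 1, X.shape[1])
    if not (1 <= ncomp <= MAX_PLS_COMPONENTS):
        raise ValueError(f"ncomp must be in 1..{MAX_PLS_COMPONENTS}")
    if ncomp > rank_bound:
        raise ValueError(f"ncomp {ncomp} exceeds admissible rank {rank_bound}")

    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xm, Y - ym
    y_scale = float(np.linalg.norm(Yc))
    x_scale = float(np.linalg.norm(Xc))

    W = np.zeros((X.shape[1], ncomp))
    P = np.zeros((X.shape[1], ncomp))
    C = np.zeros((Y.shape[1], ncomp))
    achieved = 0
    for k in range(ncomp):
        if np.linalg.norm(Yc) <= 1e-14 * max(1.0, y_scale):
            break  # Y fully explained (or constant); no further components
        w, sv = _dominant_left_singular(Xc.T @ Yc)
        if sv <= 1e-14 * max(1.0, x_scale * y_scale):
            raise ValueError(
                f"ncomp {ncomp} exceeds admissible rank (component {k + 1})"
            )
        t = Xc @ w
        nt = np.linalg.norm(t)
        if nt <= 1e-14 * max(1.0, x_scale):
            raise ValueError(
                f"ncomp {ncomp} exceeds admissible rank (component {k + 1})"
            )
        t /= nt
        c = Yc.T @ t
        p = Xc.T @ t
        W[:, k], P[:, k], C[:, k] = w, p, c
        Xc = Xc - np.outer(t, p)
        Yc = Yc - np.outer(t, c)
        achieved += 1

    return PLSModel(
        method="PLS",
        x_mean=xm,
        y_mean=ym,
        W=W[:, :achieved],
        P=P[:, :achieved],
        C=C[:, :achieved],
        ncomp=achieved,
    )


def predict_pls(
    model: PLSModel, X_new: np.ndarray, ncomp: int | None = None
) -> np.ndarray:
    """Predict responses; ``ncomp`` may truncate the fitted components."""
    r = model.ncomp if ncomp is None else int(ncomp)
    if not (0 <= r <= model.ncomp):
        raise ValueError(f"ncomp must be in 0..{model.ncomp}")
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.W.shape[0]:
        raise ValueError("marker dimension mismatch between model and new data")
    if r == 0:
        return np.broadcast_to(model.y_mean, (X_new.shape[0], model.y_mean.size)).copy()
    W, P, C = model.W[:, :r], model.P[:, :r], model.C[:, :r]
    B = W @ np.linalg.solve(P.T @ W, C.T)
    return (X_new - model.x_mean) @ B + model.y_mean


def _center_kernel_train(K: np.ndarray) -> np.ndarray:
    n = K.shape[0]
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    return H @ K @ H


def _center_kernel_test(K_t: np.ndarray, K_train: np.ndarray) -> np.ndarray:
    """Center test x train kernel rows with the training statistics.

    K~_t = (K_t - (1/n) 1_t 1_n' K)(I - (1/n) 1_n 1_n')
    """
    col = K_train.mean(axis=0)
    M = K_t - col[None, :]
    return M - M.mean(axis=1, keepdims=True)


def fit_kpls(K: KernelMatrix | np.ndarray, Y: np.ndarray, ncomp: int) -> KPLSModel:
    """Kernel PLS with score-based deflation of the centered kernel.

    Mirrors the linear NIPALS loop in feature space: scores t come from
    the double-centered kernel, Y weights from regressing Y on t, and
    both the kernel and Y are deflated by (I - t t'). With a linear
    kernel K = X X' the predictions coincide with :func:`fit_pls`.
    """
    kind, bw, ids = "linear", None, None
    if isinstance(K, KernelMatrix):
        kind, bw, ids = K.kind, K.bandwidth, K.accession_ids
        K = K.values
    K = np.asarray(K, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = K.shape[0]
    if not (1 <= ncomp <= MAX_PLS_COMPONENTS):
        raise ValueError(f"ncomp must be in 1..{MAX_PLS_COMPONENTS}")
    if ncomp > n - 1:
        raise ValueError(f"ncomp {ncomp} exceeds admissible rank {n - 1}")

    ym = Y.mean(axis=0)
    Yc0 = Y - ym
    Kc0 = _center_kernel_train(K)

    Kc, Yc = Kc0.copy(), Yc0.copy()
    y_scale = float(np.linalg.norm(Yc0))
    k_scale = max(1.0, float(np.abs(Kc0).max()))
    T = np.zeros((n, ncomp))
    U = np.zeros((n, ncomp))
    achieved = 0
    for k in range(ncomp):
        if np.linalg.norm(Yc) <= 1e-14 * max(1.0, y_scale):
            break
        # fixed point of the kernel NIPALS loop: u is the dominant
        # eigenvector of Yc Yc' Kc, obtained from the small symmetric
        # problem Yc' Kc Yc v = mu v with u = Yc v
        KY = Kc @ Yc
        B = Yc.T @ KY
        v, _ = _dominant_eigvec(0.5 * (B + B.T))
        u = Yc @ v
        nu = np.linalg.norm(u)
        if nu <= 1e-14 * max(1.0, y_scale):
            break
        u /= nu
        t = Kc @ u
        nt = np.linalg.norm(t)
        if nt <= 1e-12 * k_scale:
            raise ValueError(
                f"ncomp {ncomp} exceeds admissible rank (component {k + 1})"
            )
        t /= nt
        T[:, k], U[:, k] = t, u
        # deflate: Kc <- (I - t t') Kc (I - t t'), Yc <- (I - t t') Yc
        Kt = Kc @ t
        Kc = Kc - np.outer(t, Kt) - np.outer(Kt, t) + float(t @ Kt) * np.outer(t, t)
        Yc = Yc - np.outer(t, t @ Yc)
        achieved += 1

    T, U = T[:, :achieved], U[:, :achieved]
    return KPLSModel(
        method="KPLS",
        accession_ids=ids,
        y_mean=ym,
        T=T,
        U=U,
        K_train=K,
        Yc=Yc0,
        A=T.T @ Kc0 @ U,
        G=T.T @ Yc0,
        kernel_kind=kind,
        bandwidth=bw,
        ncomp=achieved,
    )


def predict_kpls(
    model: KPLSModel, K_cross: np.ndarray, ncomp: int | None = None
) -> np.ndarray:
    """Predict from uncentered test x train kernel rows.

    The rows are centered with the training kernel statistics before the
    Rosipal–Trejo regression formula is applied.
    """
    r = model.ncomp if ncomp is None else int(ncomp)
    if not (0 <= r <= model.ncomp):
        raise ValueError(f"ncomp must be in 0..{model.ncomp}")
    K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
    n = model.K_train.shape[0]
    if K_cross.shape[1] != n:
        raise ValueError("K_cross has wrong training dimension")
    if r == 0:
        return np.broadcast_to(model.y_mean, (K_cross.shape[0], model.y_mean.size)).copy()
    Kt_c = _center_kernel_test(K_cross, model.K_train)
    M = np.linalg.solve(model.A[:r, :r], model.G[:r])
    return (Kt_c @ model.U[:, :r]) @ M + model.y_mean


# ---------------------------------------------------------------------------
# cross-validation plumbing shared with the evaluation layer


def make_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of range(n) into k folds with sizes differing by <= 1."""
    if k > n:
        logger.warning("reducing fold count from %d to %d (too few accessions)", k, n)
        k = n
    perm = rng.permutation(n)
    return [np.sort(block) for block in np.array_split(perm, k)]


def _cv_press_pls(
    X: np.ndarray, Y: np.ndarray, max_ncomp: int, folds: list[np.ndarray]
) -> np.ndarray:
    n = X.shape[0]
    press = np.zeros(max_ncomp)
    for te in folds:
        tr = np.setdiff1d(np.arange(n), te)
        cap = min(max_ncomp, tr.size - 1, X.shape[1])
        model = fit_pls(X[tr], Y[tr], cap)
        S_new = (X[te] - model.x_mean) @ model.W  # scores of held-out rows
        PW = model.P.T @ model.W
        for r in range(1, max_ncomp + 1):
            rr = min(r, model.ncomp)
            M = np.linalg.solve(PW[:rr, :rr], model.C[:, :rr].T)
            pred = S_new[:, :rr] @ M + model.y_mean
            press[r - 1] += 0.5 * float(np.sum((Y[te] - pred) ** 2))
    return press


def _cv_press_kpls(
    K: np.ndarray, Y: np.ndarray, max_ncomp: int, folds: list[np.ndarray]
) -> np.ndarray:
    n = K.shape[0]
    press = np.zeros(max_ncomp)
    for te in folds:
        tr = np.setdiff1d(np.arange(n), te)
        cap = min(max_ncomp, tr.size - 1)
        model = fit_kpls(K[np.ix_(tr, tr)], Y[tr], cap)
        S_new = _center_kernel_test(K[np.ix_(te, tr)], model.K_train) @ model.U
        for r in range(1, max_ncomp + 1):
            rr = min(r, model.ncomp)
            M = np.linalg.solve(model.A[:rr, :rr], model.G[:rr])
            pred = S_new[:, :rr] @ M + model.y_mean
            press[r - 1] += 0.5 * float(np.sum((Y[te] - pred) ** 2))
    return press


def select_ncomp(
    K_or_X: KernelMatrix | np.ndarray,
    Y: np.ndarray,
    max_ncomp: int = MAX_PLS_COMPONENTS,
    folds: int = 10,
    seed: int | np.random.Generator = 0,
) -> int:
    """Choose the PLS / KPLS component count by inner ten-fold CV.

    The criterion is the shape-space PRESS (T/2 times the summed squared
    descriptor error over held-out accessions, T = 1). The smallest
    component count within numerical tolerance of the minimum is
    returned, which breaks exact ties toward parsimony.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    is_kernel = isinstance(K_or_X, KernelMatrix)
    M = K_or_X.values if is_kernel else np.asarray(K_or_X, dtype=float)
    n = M.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fold_list = make_folds(n, folds, rng)
    min_tr = min(n - len(f) for f in fold_list)
    cap = min(max_ncomp, min_tr - 1, n - 1)
    if not is_kernel:
        cap = min(cap, M.shape[1])
    if cap < 1:
        return 1
    press = (
        _cv_press_kpls(M, Y, cap, fold_list)
        if is_kernel
        else _cv_press_pls(M, Y, cap, fold_list)
    )
    best = float(press.min())
    tol = 1e-9 * max(best, 1e-300)
    return int(np.argmax(press <= best + tol)) + 1
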