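"""Prediction-accuracy machinery: shape error, PRESS, Q2, cross-validation.

The squared prediction error of an accession's shape is the integral of
the squared displacement between the predicted and the average contour
over one period.  Because the coordinate functions are Fourier series,
that integral collapses to a closed form in the descriptor differences:

    (T/2) * sum_n [(a_n - a'_n)^2 + (b_n - b'_n)^2
                   + (c_n - c'_n)^2 + (d_n - d'_n)^2]

PRESS sums this over accessions and Q2 = 1 - PRESS / (total
among-accession shape sum of squares), the cross-validated proportion of
shape variation explained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .efd import ShapeVector
from .models import (
    GenotypeMatrix,
    additive_cross,
    additive_relationship,
    KernelMatrix,
    fit_kpls,
    fit_pls,
    fit_rr,
    fit_krr,
    gaussian_cross,
    gaussian_kernel,
    make_folds,
    median_heuristic_bandwidth,
    predict_kpls,
    predict_pls,
    predict_rr_krr,
    select_ncomp,
    MAX_PLS_COMPONENTS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CVReport",
    "shape_squared_error",
    "press",
    "q_squared",
    "run_cv",
    "paired_wilcoxon",
    "METHODS",
]

METHODS = ("RR", "KRR", "PLS", "KPLS")


def _values(v) -> np.ndarray:
    return v.values if isinstance(v, ShapeVector) else np.asarray(v, dtype=float)


def shape_squared_error(f_avg, f_pred, T: float = 1.0) -> float:
    """Integrated squared contour displacement between two shape vectors.

    Equals the integral over t in [0, T) of the squared x plus squared y
    displacement between the two reconstructed contours; the constant
    first-harmonic entries (a1, b1, c1) are shared and contribute zero.
    """
    if isinstance(f_avg, ShapeVector) and isinstance(f_pred, ShapeVector):
        if f_avg.N != f_pred.N:
            raise ValueError("shape vectors have different harmonic counts")
    a, b = _values(f_avg), _values(f_pred)
    if a.shape != b.shape:
        raise ValueError("shape vectors have different lengths")
    if T <= 0:
        raise ValueError("period T must be positive")
    return 0.5 * T * float(np.sum((a - b) ** 2))


def press(errors) -> float:
    """Predicted residual sum of squares: total of per-accession shape errors."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("no per-accession errors supplied")
    return float(errors.sum())


def q_squared(f_avg_all, f_pred_all, T: float = 1.0) -> float:
    """Cross-validated proportion of shape variation explained (Eq. with PRESS).

    Q2 = 1 - PRESS / [(T/2) * sum_l ||f_l - grand mean||^2].  Equals 1
    iff predictions match the per-accession averages exactly, 0 when
    every prediction is the grand-mean shape, and may be negative.
    """
    A = np.stack([_values(v) for v in f_avg_all])
    P = np.stack([_values(v) for v in f_pred_all])
    if A.shape != P.shape:
        raise ValueError("average and predicted tables have different shapes")
    if A.shape[0] < 2:
        raise ValueError("Q2 needs at least 2 accessions")
    denom = 0.5 * T * float(np.sum((A - A.mean(axis=0)) ** 2))
    if denom <= 0.0:
        raise ValueError("zero among-accession shape variation; Q2 undefined")
    num = 0.5 * T * float(np.sum((A - P) ** 2))
    return 1.0 - num / denom


@dataclass
class CVReport:
    """Cross-validation accuracy report for one method.

    For the ten-fold scheme, ``per_rep_q2`` holds the Q2 of each
    replication (held-out predictions pooled within a replication) and
    the headline ``q2``/``press_value``/``per_accession_errors`` are
    means over replications.
    """

    method: str
    scheme: str  # "loocv" or "tenfold"
    accession_ids: list[str]
    per_accession_errors: np.ndarray
    press_value: float
    q2: float
    seed: int | None = None
    n_folds: int | None = None
    per_rep_q2: list[float] | None = None
    per_rep_press: list[float] | None = None

    def __post_init__(self) -> None:
        self.per_accession_errors = np.asarray(self.per_accession_errors, dtype=float)
        if self.per_accession_errors.size != len(self.accession_ids):
            raise ValueError("one error per accession required")


def _fit_predict(
    method: str,
    G: GenotypeMatrix,
    Y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    max_ncomp: int,
    inner_folds: int,
    inner_rng: np.random.Generator,
) -> np.ndarray:
    """Train one method on the training accessions and predict the held-out ones.

    Everything data-dependent — additive-relationship centering, the
    Gaussian bandwidth, REML variance ratios and the nested component
    count — is recomputed from the training split only.
    """
    Xtr, Xte = G.scores[train], G.scores[test]
    Ytr = Y[train]
    if method == "RR":
        Gtr = G.subset(train)
        K = additive_relationship(Gtr)
        model = fit_rr(K, Ytr)
        return predict_rr_krr(model, additive_cross(Xte, Xtr))
    if method == "KRR":
        h = median_heuristic_bandwidth(Xtr)
        K = gaussian_kernel(Xtr, h)
        model = fit_krr(K, Ytr)
        return predict_rr_krr(model, gaussian_cross(Xte, Xtr, h))
    if method == "PLS":
        nc = select_ncomp(Xtr, Ytr, max_ncomp=max_ncomp, folds=inner_folds, seed=inner_rng)
        model = fit_pls(Xtr, Ytr, nc)
        return predict_pls(model, Xte, ncomp=model.ncomp)
    if method == "KPLS":
        h = median_heuristic_bandwidth(Xtr)
        K = gaussian_kernel(Xtr, h)
        nc = select_ncomp(K, Ytr, max_ncomp=max_ncomp, folds=inner_folds, seed=inner_rng)
        model = fit_kpls(K, Ytr, nc)
        return predict_kpls(model, gaussian_cross(Xte, Xtr, h), ncomp=model.ncomp)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def run_cv(
    dataset,
    method: str,
    scheme: str = "loocv",
    n_reps: int = 10,
    seed: int = 0,
    T: float = 1.0,
    max_ncomp: int = MAX_PLS_COMPONENTS,
    inner_folds: int = 10,
    n_folds: int = 10,
) -> CVReport:
    """Leave-one-out or repeated ten-fold cross-validation of one method.

    The fold splits are a deterministic function of ``seed`` alone, so
    calling run_cv for several methods with the same seed evaluates them
    on identical splits, enabling paired comparisons.  All model
    ingredients are re-estimated within each training fold (no leakage
    from held-out accessions).
    """
    G: GenotypeMatrix = dataset.genotypes
    Y = np.asarray(dataset.shape_values, dtype=float)
    n = G.n_accessions
    if Y.shape[0] != n:
        raise ValueError("genotype and shape tables have different accession counts")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if scheme not in ("loocv", "tenfold"):
        raise ValueError("scheme must be 'loocv' or 'tenfold'")

    ss = np.random.SeedSequence(seed)
    split_seeds, inner_seed = ss.spawn(2)
    # inner-CV fold randomness is independent of the outer splits but
    # deterministic given the seed
    inner_rng_master = np.random.default_rng(inner_seed)

    grand = Y.mean(axis=0)
    denom = 0.5 * T * float(np.sum((Y - grand) ** 2))
    if denom <= 0.0:
        raise ValueError("zero among-accession shape variation")

    if scheme == "loocv":
        errors = np.zeros(n)
        preds = np.zeros_like(Y)
        for i in range(n):
            train = np.delete(np.arange(n), i)
            pred = _fit_predict(
                method, G, Y, train, np.array([i]), max_ncomp, inner_folds,
                np.random.default_rng(inner_rng_master.integers(2**31)),
            )
            preds[i] = pred[0]
            errors[i] = shape_squared_error(Y[i], pred[0], T=T)
        pr = press(errors)
        return CVReport(
            method=method,
            scheme="loocv",
            accession_ids=list(G.accession_ids),
            per_accession_errors=errors,
            press_value=pr,
            q2=1.0 - pr / denom,
            seed=seed,
        )

    if n < 11:
        logger.warning("only %d accessions; ten-fold reduced to %d folds", n, n)
    rep_rngs = [np.random.default_rng(s) for s in split_seeds.spawn(n_reps)]
    err_matrix = np.zeros((n_reps, n))
    rep_q2, rep_press = [], []
    for rep in range(n_reps):
        folds = make_folds(n, n_folds, rep_rngs[rep])
        preds = np.zeros_like(Y)
        for te in folds:
            train = np.setdiff1d(np.arange(n), te)
            preds[te] = _fit_predict(
                method, G, Y, train, te, max_ncomp, inner_folds,
                np.random.default_rng(inner_rng_master.integers(2**31)),
            )
        errs = 0.5 * T * np.sum((Y - preds) ** 2, axis=1)
        err_matrix[rep] = errs
        pr = press(errs)
        rep_press.append(pr)
        rep_q2.append(1.0 - pr / denom)
    return CVReport(
        method=method,
        scheme="tenfold",
        accession_ids=list(G.accession_ids),
        per_accession_errors=err_matrix.mean(axis=0),
        press_value=float(np.mean(rep_press)),
        q2=float(np.mean(rep_q2)),
        seed=seed,
        n_folds=n_folds,
        per_rep_q2=[float(v) for v in rep_q2],
        per_rep_press=[float(v) for v in rep_press],
    )


def paired_wilcoxon(q2_a, q2_b) -> float:
    """Exact two-sided Wilcoxon signed-rank p-value for paired accuracies.

    Pairs with zero difference are dropped (with a log message); if all
    differences are zero the methods are indistinguishable and p = 1.
    """
    a = np.asarray(q2_a, dtype=float)
    b = np.asarray(q2_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D sequences")
    if a.size < 5:
        raise ValueError("need at least 5 pairs for the signed-rank test")
    d = a - b
    n_zero = int(np.sum(d == 0.0))
    if n_zero == d.size:
        logger.warning("all paired differences are zero; p = 1")
        return 1.0
    if n_zero:
        logger.info("dropping %d zero differences before the signed-rank test", n_zero)
        d = d[d != 0.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="exact")
    return float(res.pvalue)
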