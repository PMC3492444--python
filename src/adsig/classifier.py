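"""Small-sample linear 3-gene classifiers ranked by bolstered error.

With a dozen samples per contrast, cross-validated error estimates are too
variable to rank classifiers; the *bolstered resubstitution* estimate
replaces each training point by a spherical Gaussian kernel and integrates
the probability mass falling on the wrong side of the decision surface.
For a linear classifier ``sign(w.x + b)`` the integral has the closed form

    epsilon = (1/n) * sum_i  Phi( -y_i (w.x_i + b) / (||w|| sigma_c(i)) )

where ``Phi`` is the standard normal CDF and the per-class kernel width is
``sigma_c = dbar_c / alpha_D``: ``dbar_c`` the mean nearest-neighbor
distance among class-c points and ``alpha_D`` the radius enclosing
probability 1/2 of a standard D-dimensional Gaussian (the square root of
the chi-square-D median).  A Monte-Carlo path serves as an internal
cross-check of the closed form.

The search space is first reduced to ~200 genes by SVM-based recursive
feature elimination (halving by linear-SVM weight magnitude), then every
3-gene combination is scored and ranked by (bolstered error ascending,
margin descending), margin being the minimum distance of a training point
to the decision surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

__all__ = [
    "LinearClassifier",
    "BolsteredErrorEstimate",
    "TripletCandidate",
    "alpha_d",
    "preselect_features",
    "fit_linear_classifier",
    "kernel_widths",
    "bolstered_error",
    "search_triplets",
    "classify",
]


@dataclass(frozen=True)
class LinearClassifier:
    """Linear decision rule ``sign(w.x + b)`` over a fixed gene triple."""

    genes: tuple[str, ...]
    w: np.ndarray
    b: float
    method: str = "least_squares"  # or "max_margin"

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if np.linalg.norm(w) == 0:
            raise ValueError("classifier weight vector must be non-zero")
        object.__setattr__(self, "w", w)

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.b


@dataclass(frozen=True)
class BolsteredErrorEstimate:
    """Bolstered resubstitution error with its per-class kernel widths."""

    epsilon: float
    sigma: dict
    method: str
    mc_draws: int = 0


@dataclass(frozen=True)
class TripletCandidate:
    genes: tuple[str, str, str]
    classifier: LinearClassifier
    bolstered_error: float
    margin: float
    resubstitution_error: float


def alpha_d(d: int) -> float:
    """Radius enclosing probability 1/2 of a standard d-dim Gaussian."""
    return float(np.sqrt(stats.chi2.ppf(0.5, d)))


def _as_signed(labels) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(labels)
    classes = tuple(sorted(pd.unique(labels)))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    return np.where(labels == classes[1], 1.0, -1.0), classes


def preselect_features(
    values: pd.DataFrame,
    labels,
    target_count: int = 200,
    *,
    C: float = 1.0,
    standardize: bool = True,
) -> list[str]:
    """SVM-RFE gene preselection: halve by |weight| until <= target_count.

    ``values`` is genes x samples; returns the retained gene ids ranked by
    final linear-SVM weight magnitude (deterministic for a fixed solver
    tolerance).
    """
    y, _ = _as_signed(labels)
    if (y > 0).sum() < 2 or (y < 0).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    X = values.to_numpy(float).T  # samples x genes
    if np.isnan(X).any():
        # rank on complete genes only
        keep = ~np.isnan(X).any(axis=0)
        values = values.loc[values.index[keep]]
        X = X[:, keep]
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    genes = np.asarray(values.index)
    idx = np.arange(X.shape[1])
    while True:
        svm = SVC(kernel="linear", C=C, tol=1e-5)
        svm.fit(X[:, idx], y)
        w = np.abs(svm.coef_.ravel())
        order = np.argsort(-w, kind="stable")
        if idx.size <= target_count:
            return [str(g) for g in genes[idx[order]]]
        keep = max(target_count, idx.size // 2)
        idx = np.sort(idx[order[:keep]])


def fit_linear_classifier(X: np.ndarray, y: np.ndarray, genes=("x0", "x1", "x2")) -> LinearClassifier:
    """Maximum-margin separator when separable, least-squares otherwise."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    svm = SVC(kernel="linear", C=1e6, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svm.fit(X, y)
    w = svm.coef_.ravel()
    b = float(svm.intercept_[0])
    pred = np.where(X @ w + b >= 0, 1.0, -1.0)
    if np.all(pred == np.sign(y)) and np.linalg.norm(w) > 0:
        return LinearClassifier(tuple(genes), w, b, method="max_margin")
    wls, bls = _lstsq_fit(X, y)
    return LinearClassifier(tuple(genes), wls, bls, method="least_squares")


def _lstsq_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    Xh = np.column_stack([X, np.ones(len(X))])
    beta, *_ = np.linalg.lstsq(Xh, y, rcond=None)
    w, b = beta[:-1], float(beta[-1])
    if np.linalg.norm(w) == 0:
        w = w + 1e-12
    return w, b


def kernel_widths(X: np.ndarray, y: np.ndarray, *, floor_scale: float = 1e-8) -> dict:
    """Per-class bolstering kernel width sigma_c = dbar_c / alpha_D.

    ``dbar_c`` is the mean nearest-neighbor distance among class-c points.
    Coincident same-class points would give sigma = 0; such classes are
    floored at ``floor_scale`` times the data range, with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    a = alpha_d(X.shape[1])
    scale = float(np.ptp(X)) or 1.0
    out = {}
    for c in np.unique(y):
        P = X[y == c]
        if len(P) < 2:
            raise ValueError(f"class {c!r} needs at least 2 points")
        d = np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        dbar = float(d.min(axis=1).mean())
        sigma = dbar / a
        if sigma <= 0:
            warnings.warn(f"coincident points in class {c!r}; flooring kernel width")
            sigma = floor_scale * scale
        out[c] = sigma
    return out


def bolstered_error(
    classifier: LinearClassifier,
    X: np.ndarray,
    y: np.ndarray,
    *,
    method: str = "closed_form",
    mc_draws: int = 100_000,
    seed: int | None = 0,
    sigma: dict | None = None,
) -> BolsteredErrorEstimate:
    """Bolstered resubstitution error of a linear classifier.

    ``y`` may hold any two class labels; the *larger* (sorted) label is the
    positive class.  ``sigma`` overrides the per-class kernel widths.
    """
    X = np.asarray(X, dtype=float)
    ysgn, classes = _as_signed(y)
    if sigma is None:
        sigma = kernel_widths(X, np.asarray(y))
    sig = np.array([sigma[c] for c in np.asarray(y)])
    f = classifier.decision(X)
    wnorm = float(np.linalg.norm(classifier.w))
    if method == "closed_form":
        eps = float(np.mean(stats.norm.cdf(-ysgn * f / (wnorm * sig))))
        return BolsteredErrorEstimate(eps, dict(sigma), "closed_form")
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        per_point = max(1, mc_draws // len(X))
        errs = np.empty(len(X))
        for i, (xi, yi, si) in enumerate(zip(X, ysgn, sig)):
            draws = rng.normal(xi, si, size=(per_point, X.shape[1]))
            fi = draws @ classifier.w + classifier.b
            pred = np.where(fi >= 0, 1.0, -1.0)
            errs[i] = np.mean(pred != yi)
        return BolsteredErrorEstimate(float(errs.mean()), dict(sigma), "monte_carlo", per_point * len(X))
    raise ValueError(f"unknown method {method!r}")


def _batch_screen(D: np.ndarray, ysgn: np.ndarray, combos: np.ndarray, sig_rows: np.ndarray):
    """Least-squares discriminant + bolstered error for a batch of triplets.

    ``D`` is samples x genes, ``combos`` m x 3 column indices, ``sig_rows``
    the per-sample kernel widths (precomputed per triplet below).  Returns
    (eps, margin, resub, W, bvec).
    """
    n = D.shape[0]
    Xc = D[:, combos]  # n x m x 3
    Xh = np.concatenate([Xc, np.ones((n, combos.shape[0], 1))], axis=2)  # n x m x 4
    G = np.einsum("nmi,nmj->mij", Xh, Xh)
    G += 1e-10 * np.eye(4)[None]
    rhs = np.einsum("nmi,n->mi", Xh, ysgn)
    beta = np.linalg.solve(G, rhs[..., None])[..., 0]  # m x 4
    W, bvec = beta[:, :3], beta[:, 3]
    wnorm = np.linalg.norm(W, axis=1)
    wnorm = np.where(wnorm == 0, 1e-12, wnorm)
    f = np.einsum("nmi,mi->nm", Xh, beta)  # n x m decision values
    margin = np.abs(f).min(axis=0) / wnorm
    pred = np.where(f >= 0, 1.0, -1.0)
    resub = (pred != ysgn[:, None]).mean(axis=0)
    eps = stats.norm.cdf(-(ysgn[:, None] * f) / (wnorm[None, :] * sig_rows)).mean(axis=0)
    return eps, margin, resub, W, bvec


def _batch_kernel_widths(D: np.ndarray, y: np.ndarray, combos: np.ndarray) -> np.ndarray:
    """Per-sample sigma for each triplet (n x m), vectorized per class."""
    n, m = D.shape[0], combos.shape[0]
    a = alpha_d(3)
    scale = float(np.ptp(D)) or 1.0
    sig = np.empty((n, m))
    for c in np.unique(y):
        rows = np.flatnonzero(y == c)
        P = D[rows][:, combos]  # k x m x 3
        diff = P[:, None, :, :] - P[None, :, :, :]  # k x k x m x 3
        d = np.sqrt((diff**2).sum(-1))
        d[np.arange(len(rows)), np.arange(len(rows))] = np.inf
        dbar = d.min(axis=1).mean(axis=0)  # m
        s = dbar / a
        s = np.where(s <= 0, 1e-8 * scale, s)
        sig[rows, :] = s[None, :]
    return sig


def search_triplets(
    values: pd.DataFrame,
    labels,
    candidate_genes=None,
    top_k: int = 10,
    *,
    max_combinations: int = 10_000_000,
    allow_large: bool = False,
    refine_pool: int = 50,
    chunk: int = 20_000,
) -> list[TripletCandidate]:
    """Exhaustive 3-gene search ranked by (bolstered error, margin).

    Every 3-combination of the candidate genes is screened with a
    least-squares linear discriminant (batched closed-form solves); the top
    ``refine_pool`` candidates are refit with a hard-margin SVM where
    separable and re-ranked before returning ``top_k`` results.
    """
    genes = list(candidate_genes) if candidate_genes is not None else list(values.index)
    if len(genes) < 3:
        raise ValueError("need at least 3 candidate genes")
    n_comb = comb(len(genes), 3)
    if n_comb > max_combinations and not allow_large:
        raise ValueError(
            f"search too large: {n_comb} combinations exceeds {max_combinations}; "
            "pass allow_large=True to override"
        )
    ysgn, classes = _as_signed(labels)
    if (ysgn > 0).sum() < 2 or (ysgn < 0).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    sub = values.loc[genes]
    if sub.isna().any().any():
        raise ValueError("triplet search requires a complete matrix for candidate genes")
    D = sub.to_numpy(float).T  # samples x genes
    y = np.asarray(labels)

    all_combos = np.array(list(combinations(range(len(genes)), 3)), dtype=int)
    best: list[tuple[float, float, int]] = []  # (eps, -margin, combo_row)
    stats_by_row: dict[int, tuple[float, float, float]] = {}
    for start in range(0, len(all_combos), chunk):
        cm = all_combos[start:start + chunk]
        sig = _batch_kernel_widths(D, y, cm)
        eps, margin, resub, _, _ = _batch_screen(D, ysgn, cm, sig)
        order = np.lexsort((-margin, eps))[: max(refine_pool, top_k)]
        for o in order:
            row = start + int(o)
            best.append((float(eps[o]), -float(margin[o]), row))
            stats_by_row[row] = (float(eps[o]), float(margin[o]), float(resub[o]))
    best.sort()
    pool = [row for _, _, row in best[: max(refine_pool, top_k)]]

    results = []
    for row in pool:
        cidx = all_combos[row]
        triple = tuple(genes[i] for i in cidx)
        Xt = D[:, cidx]
        clf = fit_linear_classifier(Xt, ysgn, genes=triple)
        est = bolstered_error(clf, Xt, y, method="closed_form")
        f = clf.decision(Xt)
        margin = float(np.min(np.abs(f)) / np.linalg.norm(clf.w))
        pred = np.where(f >= 0, 1.0, -1.0)
        resub = float((pred != ysgn).mean())
        results.append(TripletCandidate(triple, clf, est.epsilon, margin, resub))
    results.sort(key=lambda c: (c.bolstered_error, -c.margin, c.genes))
    return results[:top_k]


def classify(classifier: LinearClassifier, samples: pd.DataFrame) -> pd.Series:
    """Apply the sign rule to new samples (genes x samples frame).

    Points exactly on the surface go to the positive class.  Raises when a
    classifier gene is missing from the input.
    """
    missing = [g for g in classifier.genes if g not in samples.index]
    if missing:
        raise ValueError(f"missing gene value(s): {missing}")
    X = samples.loc[list(classifier.genes)].to_numpy(float).T
    if np.isnan(X).any():
        raise ValueError("missing gene value(s) in sample columns")
    f = classifier.decision(X)
    return pd.Series(np.where(f >= 0, 1, -1), index=samples.columns)


def candidates_table(cands: list[TripletCandidate]) -> pd.DataFrame:
    """Flatten ranked candidates into the report table layout."""
    rows = []
    for c in cands:
        rows.append(
            {
                "gene_1": c.genes[0], "gene_2": c.genes[1], "gene_3": c.genes[2],
                "w_1": c.classifier.w[0], "w_2": c.classifier.w[1], "w_3": c.classifier.w[2],
                "b": c.classifier.b, "fit": c.classifier.method,
                "bolstered_error": c.bolstered_error, "margin": c.margin,
                "resubstitution_error": c.resubstitution_error,
            }
        )
    return pd.DataFrame(rows)
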