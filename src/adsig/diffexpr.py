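"""Per-gene two-sample tests with permutation p-values and FDR control.

The permutation test follows the MultiExperiment-Viewer convention: the
observed (Welch or pooled) t statistic per gene is referred to the
distribution of t under group-size-preserving relabelings of the sample
columns.  When the number of distinct label assignments C(n, n_A) does not
exceed ``n_perm`` the null is enumerated exhaustively (the p-value is then
exact and the identity assignment is one of the enumerated terms);
otherwise ``n_perm`` relabelings are sampled uniformly and the p-value is
the plain exceedance frequency.  Two operating points are conventional for
DEG selection: permutation P <= 0.01 and P <= 0.005; Benjamini–Hochberg
q-values are attached so an FDR < 0.05 criterion can be attempted first.

Missing entries (spots removed by filtering) are handled pairwise-complete;
a gene with fewer than ``min_per_group`` observed values in either group is
reported with missing statistics.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["permutation_ttest", "bh_fdr", "select_degs"]


def _moments(X: np.ndarray, masks: np.ndarray):
    """Group means/variances/counts for each relabeling column in ``masks``.

    ``X`` is genes x samples with NaN for missing; ``masks`` is samples x P
    boolean (True = group A).  Returns per-group (n, mean, var) arrays of
    shape genes x P, NaN-aware.
    """
    finite = np.isfinite(X)
    Xz = np.where(finite, X, 0.0)
    Xz2 = Xz * Xz
    Mf = masks.astype(float)
    n1 = finite.astype(float) @ Mf
    s1 = Xz @ Mf
    ss1 = Xz2 @ Mf
    n_tot = finite.sum(axis=1, keepdims=True).astype(float)
    n2 = n_tot - n1
    s2 = Xz.sum(axis=1, keepdims=True) - s1
    ss2 = Xz2.sum(axis=1, keepdims=True) - ss1
    out = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for n, s, ss in ((n1, s1, ss1), (n2, s2, ss2)):
            mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
            var = (ss - np.where(n > 0, s * s / np.maximum(n, 1), 0.0)) / np.maximum(n - 1, 1)
            var = np.where(n >= 2, np.maximum(var, 0.0), np.nan)
            out.append((n, mean, var))
    return out


def _tstat(n1, m1, v1, n2, m2, v2, equal_var: bool):
    with np.errstate(invalid="ignore", divide="ignore"):
        num = m1 - m2
        if equal_var:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.maximum(n1 + n2 - 2, 1)
            se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        else:
            se2 = v1 / n1 + v2 / n2
        t = num / np.sqrt(se2)
        # degenerate genes: zero spread in both groups
        zero_se = se2 == 0
        t = np.where(zero_se & (num == 0), 0.0, t)
        t = np.where(zero_se & (num != 0), np.sign(num) * np.inf, t)
    return t, se2


def _relabelings(is_a: np.ndarray, n_perm: int, seed) -> tuple[np.ndarray, bool]:
    """Group-size-preserving label assignments as a samples x P boolean matrix.

    Enumerates all C(n, n_A) assignments when that count is <= n_perm,
    otherwise samples n_perm uniform permutations of the label vector.
    """
    n, na = is_a.size, int(is_a.sum())
    n_exact = comb(n, na)
    if n_exact <= n_perm:
        masks = np.zeros((n, n_exact), dtype=bool)
        for j, pos in enumerate(combinations(range(n), na)):
            masks[list(pos), j] = True
        return masks, True
    rng = np.random.default_rng(seed)
    masks = np.empty((n, n_perm), dtype=bool)
    for j in range(n_perm):
        masks[:, j] = rng.permutation(is_a)
    return masks, False


def permutation_ttest(
    values: pd.DataFrame,
    groups: pd.Series | dict,
    a: str,
    b: str,
    *,
    n_perm: int = 1000,
    seed: int | None = 0,
    equal_var: bool = False,
    min_per_group: int = 3,
    conservative: bool = False,
    chunk: int = 256,
) -> pd.DataFrame:
    """Permutation t-test of group ``a`` versus group ``b`` for every gene.

    Parameters
    ----------
    values
        Genes x samples log2-ratio matrix (NaN = missing).
    groups
        Label per column; columns outside ``{a, b}`` are ignored.
    equal_var
        Pooled-variance t instead of the default Welch t.  The permutation
        reference makes the choice second-order.
    min_per_group
        Genes observed fewer times than this in either group get NaN stats.
    conservative
        Add-one correction ((count+1)/(P+1)) on sampled permutations.

    Returns a DataFrame indexed by gene with columns ``t``, ``p_param``,
    ``p_perm``, ``q``, ``log2fc`` (mean_a - mean_b), ``direction``, ``n_a``,
    ``n_b`` and the boolean ``exhaustive`` flag in ``attrs``.
    """
    groups = pd.Series(groups)
    cols = [c for c in values.columns if groups.get(c) in (a, b)]
    if not any(groups.get(c) == a for c in cols):
        raise ValueError(f"group {a!r} absent from matrix columns")
    if not any(groups.get(c) == b for c in cols):
        raise ValueError(f"group {b!r} absent from matrix columns")
    X = values[cols].to_numpy(float)
    is_a = np.array([groups[c] == a for c in cols])

    # genes constant to machine precision are degenerate: t = 0, p = 1
    finite = np.isfinite(X)
    hi = np.where(finite, X, -np.inf).max(axis=1)
    lo = np.where(finite, X, np.inf).min(axis=1)
    constant = finite.any(axis=1) & ((hi - lo) <= 1e-9 * np.maximum(1.0, np.abs(hi)))
    X = np.where(constant[:, None] & finite, 0.0, X)

    (n1, m1, v1), (n2, m2, v2) = _moments(X, is_a[:, None])
    t_obs, _ = _tstat(n1, m1, v1, n2, m2, v2, equal_var)
    t_obs, m1, m2 = t_obs[:, 0], m1[:, 0], m2[:, 0]
    n1, n2, v1, v2 = n1[:, 0], n2[:, 0], v1[:, 0], v2[:, 0]
    valid = (n1 >= min_per_group) & (n2 >= min_per_group)
    t_obs = np.where(valid, t_obs, np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        if equal_var:
            df = n1 + n2 - 2
        else:  # Welch–Satterthwaite
            r1, r2 = v1 / n1, v2 / n2
            df = (r1 + r2) ** 2 / (r1**2 / np.maximum(n1 - 1, 1) + r2**2 / np.maximum(n2 - 1, 1))
        p_param = 2.0 * stats.t.sf(np.abs(t_obs), np.maximum(df, 1e-9))
        p_param = np.where(np.isinf(t_obs), 0.0, p_param)
        p_param = np.where(t_obs == 0, 1.0, p_param)

    masks, exhaustive = _relabelings(is_a, n_perm, seed)
    # tie threshold: |t*| equal to |t_obs| up to floating error counts as a hit
    abs_obs = np.abs(t_obs)[:, None]
    abs_obs = np.where(np.isfinite(abs_obs), abs_obs * (1 - 1e-10) - 1e-12, abs_obs)
    hits = np.zeros(X.shape[0])
    denom = np.zeros(X.shape[0])
    for start in range(0, masks.shape[1], chunk):
        mk = masks[:, start:start + chunk]
        (pn1, pm1, pv1), (pn2, pm2, pv2) = _moments(X, mk)
        t_perm, _ = _tstat(pn1, pm1, pv1, pn2, pm2, pv2, equal_var)
        ok = np.isfinite(t_perm) | np.isinf(t_perm)  # NaN only for undersized groups
        hits += np.nansum((np.abs(t_perm) >= abs_obs) & ok, axis=1)
        denom += ok.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        if conservative and not exhaustive:
            p_perm = (hits + 1) / (denom + 1)
        else:
            p_perm = hits / denom
    p_perm = np.where(valid & (denom > 0), p_perm, np.nan)

    log2fc = np.where(valid, m1 - m2, np.nan)
    out = pd.DataFrame(
        {
            "t": t_obs,
            "p_param": np.where(valid, p_param, np.nan),
            "p_perm": p_perm,
            "q": bh_fdr(p_perm),
            "log2fc": log2fc,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "n_a": n1.astype(int),
            "n_b": n2.astype(int),
        },
        index=values.index,
    )
    out.loc[~valid, "direction"] = ""
    out.attrs["exhaustive"] = exhaustive
    out.attrs["n_relabelings"] = masks.shape[1]
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values; NaN inputs stay NaN."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return q
    ps = p[ok]
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q


def select_degs(
    results: pd.DataFrame,
    alpha: float = 0.01,
    use_fdr: bool = False,
    p_column: str = "p_perm",
) -> tuple[pd.DataFrame, dict]:
    """Select differentially expressed genes at an inclusive threshold.

    With ``use_fdr`` the criterion is q < alpha; otherwise ``p_column`` <=
    alpha (inclusive, matching the conventional "P <= 0.01" statement).
    Returns the selected rows sorted by p, plus up/down counts.
    """
    crit = results["q"] < alpha if use_fdr else results[p_column] <= alpha
    sel = results.loc[crit.fillna(False)].sort_values(p_column)
    n_up = int((sel["direction"] == "up").sum())
    n_down = int((sel["direction"] == "down").sum())
    return sel, {"n_total": len(sel), "n_up": n_up, "n_down": n_down}
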