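"""Over-representation analysis of gene categories against a platform reference.

For each annotation category the 2x2 contingency table

====================  ============  ================
                      selected      not selected
====================  ============  ================
in category           k             K - k
not in category       n - k         N - K - n + k
====================  ============  ================

is scored with a one-sided Fisher's exact test (enrichment tail), where N
is the platform reference size, K the category size on the platform, and n
the selected-list size.  The full probe content of the array serves as the
reference set; raw p-values are reported by default (the conventional
cut-off is P <= 0.05), with an optional BH adjustment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr

__all__ = ["overrepresentation"]

logger = logging.getLogger(__name__)


def overrepresentation(
    selected,
    annotation: pd.DataFrame,
    reference,
    *,
    alternative: str = "greater",
    adjust: bool = False,
) -> pd.DataFrame:
    """Category over-representation among ``selected`` genes.

    Parameters
    ----------
    selected
        Gene ids of interest; must be a subset of ``reference``.
    annotation
        Two-column table (gene id, category id); genes may carry several
        categories.  Annotations for genes off the reference are ignored.
    reference
        Platform gene universe.
    alternative
        ``"greater"`` (enrichment tail, default) or ``"two-sided"``.
    adjust
        Attach BH-adjusted ``q`` values.

    Returns one row per non-empty category, sorted by p, with counts
    (k, K, n, N) and the selected member genes.
    """
    reference = set(reference)
    selected = set(selected)
    stray = selected - reference
    if stray:
        raise ValueError(f"selected gene(s) absent from reference: {sorted(stray)[:5]}")
    gcol, ccol = annotation.columns[:2]
    ann = annotation[annotation[gcol].isin(reference)]
    n_dropped = annotation[ccol].nunique() - ann[ccol].nunique()
    if n_dropped:
        logger.info("dropped %d categories with no platform members", n_dropped)
    N, n = len(reference), len(selected)
    rows = []
    for cat, members in ann.groupby(ccol)[gcol]:
        cat_genes = set(members)
        K = len(cat_genes)
        hit = sorted(cat_genes & selected)
        k = len(hit)
        table = [[k, n - k], [K - k, N - K - n + k]]
        p = float(stats.fisher_exact(table, alternative=alternative)[1])
        rows.append((cat, k, K, n, N, p, ",".join(hit)))
    out = pd.DataFrame(rows, columns=["category_id", "k", "K", "n", "N", "p", "members"])
    if adjust:
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values(["p", "category_id"], kind="stable").reset_index(drop=True)
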