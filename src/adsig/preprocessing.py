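"""Spot filtering and normalization of two-channel arrays.

The preprocessing chain mirrors classic two-color cDNA practice:

1. drop saturated spots (any channel foreground at or above the scanner
   ceiling, default 63,000 ~ 16 bits);
2. subtract the local background per channel and drop spots with a
   non-positive net signal in either channel;
3. per array, compute ``M = log2(ch2/ch1)`` and ``A = (log2 ch1 + log2 ch2)/2``
   on net signals, and center M by subtracting a lowess fit of M on A
   (intensity-dependent dye-bias removal);
4. sign-flip dye-swap arrays (orientation -1) to the common test-over-reference
   orientation;
5. match spread across arrays by rescaling each array's M to the cohort
   median of the per-array median absolute deviations.

Spots removed by filtering propagate as missing values; downstream per-gene
tests use pairwise-complete columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

__all__ = [
    "FilterReport",
    "ExpressionMatrix",
    "filter_spots",
    "normalize",
    "collapse_replicates",
    "preprocess_experiment",
    "read_spot_dir",
]

DEFAULT_SATURATION_CEILING = 63000.0


@dataclass
class FilterReport:
    """Removal bookkeeping for one array's spot filter pass."""

    n_input: int
    n_saturated: int
    n_nonpositive: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_saturated - self.n_nonpositive

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_saturated": self.n_saturated,
            "n_nonpositive": self.n_nonpositive,
            "n_kept": self.n_kept,
        }


@dataclass
class ExpressionMatrix:
    """Normalized log2-ratio matrix (genes x arrays) with its array manifest.

    ``values`` columns are array ids (or subject ids after collapsing);
    ``manifest`` is indexed likewise and carries ``subject_id``, ``group``
    and, before collapsing, ``orientation``.  Missing entries are NaN.
    """

    values: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self):
        if self.values.columns.duplicated().any() or self.values.index.duplicated().any():
            raise ValueError("gene and array labels must be unique")
        unknown = set(self.values.columns) - set(self.manifest.index)
        if unknown:
            raise ValueError(f"arrays missing from manifest: {sorted(unknown)[:5]}")

    @property
    def groups(self) -> pd.Series:
        """Group label per column."""
        return self.manifest.loc[self.values.columns, "group"]

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read_tsv(cls, path, manifest: pd.DataFrame) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(values=values, manifest=manifest)


def filter_spots(
    spots: pd.DataFrame,
    saturation_ceiling: float = DEFAULT_SATURATION_CEILING,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove saturated and background-dominated spots.

    A spot is *saturated* when either channel's foreground reaches the
    scanner ceiling, and *non-positive* when either background-subtracted
    channel is <= 0.  Returns the surviving rows (original columns, so the
    operation is idempotent) plus a :class:`FilterReport`.
    """
    fg1, bg1 = spots["ch1_fg"].to_numpy(float), spots["ch1_bg"].to_numpy(float)
    fg2, bg2 = spots["ch2_fg"].to_numpy(float), spots["ch2_bg"].to_numpy(float)
    saturated = (fg1 >= saturation_ceiling) | (fg2 >= saturation_ceiling)
    nonpositive = ~saturated & (((fg1 - bg1) <= 0) | ((fg2 - bg2) <= 0))
    keep = ~saturated & ~nonpositive
    report = FilterReport(
        n_input=len(spots),
        n_saturated=int(saturated.sum()),
        n_nonpositive=int(nonpositive.sum()),
    )
    if report.n_kept == 0:
        raise ValueError("no spots survive filtering")
    return spots.loc[keep].copy(), report


def _normalize_one(spots: pd.DataFrame, span: float) -> pd.Series:
    """Lowess-centered M values for one filtered array, indexed by probe."""
    net1 = spots["ch1_fg"].to_numpy(float) - spots["ch1_bg"].to_numpy(float)
    net2 = spots["ch2_fg"].to_numpy(float) - spots["ch2_bg"].to_numpy(float)
    if len(spots) < 10:
        raise ValueError(f"too few spots ({len(spots)}) for lowess normalization")
    m = np.log2(net2) - np.log2(net1)
    a = 0.5 * (np.log2(net2) + np.log2(net1))
    # plain (non-robust) local regression: robustifying iterations degenerate
    # when nearly all residuals are zero and can swallow lone true signals
    fit = _lowess(m, a, frac=span, it=0, return_sorted=False)
    return pd.Series(m - fit, index=pd.Index(spots["probe_id"], name="gene_id"))


def normalize(
    arrays: Mapping[str, pd.DataFrame],
    manifest: pd.DataFrame,
    span: float = 0.4,
    scale: bool = True,
) -> ExpressionMatrix:
    """Within-array lowess centering + across-array spread matching.

    ``arrays`` maps array id to a *filtered* spot table.  Orientation -1
    arrays are sign-flipped to the common test/reference orientation after
    the lowess step (the dye bias lives in raw orientation).  With
    ``scale``, each array's M is rescaled so its median absolute deviation
    equals the across-array median MAD.
    """
    man = manifest.set_index("array_id") if "array_id" in manifest.columns else manifest
    cols = {}
    for array_id, spots in arrays.items():
        m = _normalize_one(spots, span)
        if int(man.loc[array_id, "orientation"]) == -1:
            m = -m
        cols[array_id] = m
    values = pd.DataFrame(cols)
    if scale:
        med = values.median(axis=0, skipna=True)
        mad = (values - med).abs().median(axis=0, skipna=True)
        if (mad <= 0).any():
            bad = mad.index[mad <= 0].tolist()
            raise ValueError(f"zero spread on arrays {bad}; cannot MAD-scale")
        values = values * (float(np.median(mad)) / mad)
    return ExpressionMatrix(values=values, manifest=man.loc[list(arrays)])


def collapse_replicates(matrix: ExpressionMatrix, mode: str = "arrays") -> ExpressionMatrix:
    """Keep all arrays as columns or average each subject's dye-swap pair.

    ``arrays`` returns the matrix unchanged (the full hybridization design);
    ``subject_mean`` averages each subject's arrays (NaN-aware) into one
    column per subject.
    """
    if mode == "arrays":
        return ExpressionMatrix(values=matrix.values.copy(), manifest=matrix.manifest.copy())
    if mode != "subject_mean":
        raise ValueError(f"unknown collapse mode {mode!r}")
    man = matrix.manifest
    subj_of = man.loc[matrix.values.columns, "subject_id"]
    missing = set(man["subject_id"]) - set(subj_of)
    if missing:
        raise ValueError(f"subjects with zero arrays: {sorted(missing)}")
    values = matrix.values.T.groupby(subj_of).mean().T
    sub_man = (
        man.reset_index(drop=True)
        .groupby("subject_id", sort=False)
        .agg(group=("group", "first"))
    )
    return ExpressionMatrix(values=values, manifest=sub_man.loc[values.columns])


def preprocess_experiment(
    arrays: Mapping[str, pd.DataFrame],
    manifest: pd.DataFrame,
    *,
    saturation_ceiling: float = DEFAULT_SATURATION_CEILING,
    span: float = 0.4,
    scale: bool = True,
    collapse: str = "arrays",
) -> tuple[ExpressionMatrix, dict[str, FilterReport]]:
    """Filter + normalize + optionally collapse, returning matrix and reports."""
    filtered, reports = {}, {}
    for array_id, spots in arrays.items():
        filtered[array_id], reports[array_id] = filter_spots(spots, saturation_ceiling)
    matrix = normalize(filtered, manifest, span=span, scale=scale)
    return collapse_replicates(matrix, collapse), reports


def read_spot_dir(spot_dir) -> dict[str, pd.DataFrame]:
    """Read one spot table per array from a directory of TSV files."""
    out = {}
    for path in sorted(Path(spot_dir).glob("*.tsv")):
        out[path.stem] = pd.read_csv(path, sep="\t")
    if not out:
        raise ValueError(f"no spot tables found in {spot_dir}")
    return out
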