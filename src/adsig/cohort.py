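"""Clinico-neuropathological group assignment and hybridization design.

Autopsy cases are labelled from three standard instruments:

* **Braak stage** (0–VI): spread of neurofibrillary tangle pathology;
  stage IV or higher marks substantial tangle burden.
* **CERAD score** (0/A/B/C): semiquantitative neuritic-plaque density;
  B or C means moderate/frequent plaques.
* **CDR** (Clinical Dementia Rating): 0 = cognitively normal, >= 1 = dementia.

A case *meets AD-pathology criteria* when Braak >= IV **or** CERAD is B/C
(the default rule; an AND variant is available, see :func:`assign_group`),
and *control-pathology criteria* when Braak <= II **and** CERAD is 0/A.
Crossing the pathology flag with the CDR yields four labels:

========  =======================================================
CP-AD     clinic-pathological AD: AD pathology and dementia (CDR >= 1)
P-AD      preclinical AD: AD pathology, cognitively normal (CDR = 0)
N         normal older individual: no pathology, CDR = 0
Unclassified  everything else (intermediate pathology, CDR 0.5, ...)
========  =======================================================

Each subject is hybridized twice under a dye-swap reference design, so the
array manifest holds two arrays of opposite orientation per subject.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "BRAAK_LEVELS",
    "CERAD_LEVELS",
    "GROUPS",
    "assign_group",
    "assign_groups",
    "braak_rank",
    "cerad_rank",
    "build_design",
    "reference_cohort",
    "read_subject_table",
]

BRAAK_LEVELS = ("0", "I", "II", "III", "IV", "V", "VI")
CERAD_LEVELS = ("0", "A", "B", "C")
GROUPS = ("CP-AD", "P-AD", "N", "Unclassified")

_BRAAK_RANK = {tok: i for i, tok in enumerate(BRAAK_LEVELS)}
_CERAD_RANK = {tok: i for i, tok in enumerate(CERAD_LEVELS)}

# Published summary table of the 23 selected autopsy cases
# (subject id, sex, age at death, Braak stage, CERAD score, CDR, post-mortem
# interval in hours).  Used as the reference fixture for the bookkeeping
# checks and as a template for the synthetic cohort generator.
_REFERENCE_COHORT_TSV = """\
subject_id\tsex\tage\tbraak\tcerad\tcdr\tpmi
CP-AD1\tF\t99\tV\tB\t3\t18.3
CP-AD2\tF\t82\tIV\tB\t2\t13.5
CP-AD3\tF\t86\tIV\tC\t1\t10.1
CP-AD4\tF\t83\tV\tA\t3\t12.1
CP-AD5\tM\t69\tVI\tC\t2\t15.0
CP-AD6\tF\t87\tV\tB\t3\t17.7
CP-AD7\tF\t82\tV\tC\t2\t11.8
CP-AD8\tF\t77\tIV\tA\t3\t16.0
CP-AD9\tF\t83\tVI\tC\t3\t10.8
P-AD1\tF\t87\tV\tC\t0\t11.1
P-AD2\tF\t85\tV\tC\t0\t9.6
P-AD3\tM\t72\tVI\tC\t0\t11.7
P-AD4\tF\t86\tVI\tC\t0\t16.0
N1\tF\t71\t0\t0\t0\t16.1
N2\tM\t79\tI\t0\t0\t8.3
N3\tF\t81\tI\t0\t0\t11.9
N4\tM\t77\tI\tA\t0\t6.5
N5\tM\t57\t0\t0\t0\t9.8
N6\tF\t65\t0\t0\t0\t12.7
N7\tF\t59\t0\t0\t0\t14.0
N8\tM\t89\tII\t0\t0\t14.2
N9\tF\t82\t0\t0\t0\t14.8
N10\tF\t94\tII\t0\t0\t12.3
"""


def braak_rank(token: str) -> int:
    """Ordinal rank of a Braak stage token (``0`` < ``I`` < ... < ``VI``)."""
    try:
        return _BRAAK_RANK[str(token).strip().upper()]
    except KeyError:
        raise ValueError(f"unknown Braak stage token: {token!r}") from None


def cerad_rank(token: str) -> int:
    """Ordinal rank of a CERAD score token (``0`` < ``A`` < ``B`` < ``C``)."""
    try:
        return _CERAD_RANK[str(token).strip().upper()]
    except KeyError:
        raise ValueError(f"unknown CERAD score token: {token!r}") from None


def assign_group(
    braak: str,
    cerad: str,
    cdr: float,
    *,
    ad_pathology_rule: str = "or",
) -> str:
    """Assign one case to CP-AD, P-AD, N, or Unclassified.

    Parameters
    ----------
    braak, cerad
        Braak stage (``0``–``VI``) and CERAD score (``0``/``A``/``B``/``C``).
    cdr
        Clinical Dementia Rating (0, 0.5, 1, 2, 3).
    ad_pathology_rule
        ``"or"`` (default): AD pathology when Braak >= IV *or* CERAD in {B, C}.
        ``"and"``: require both.  The OR rule is normative here because it is
        the only one consistent with the published case table, which contains
        demented cases at Braak >= IV with CERAD A.

    Notes
    -----
    CDR 0.5 (questionable dementia) falls in neither the CDR = 0 nor the
    CDR >= 1 stratum and therefore maps to Unclassified.
    """
    if ad_pathology_rule not in ("or", "and"):
        raise ValueError(f"ad_pathology_rule must be 'or' or 'and', got {ad_pathology_rule!r}")
    b = braak_rank(braak)
    c = cerad_rank(cerad)
    cdr = float(cdr)
    if cdr < 0:
        raise ValueError(f"CDR must be >= 0, got {cdr}")
    high_braak = b >= _BRAAK_RANK["IV"]
    high_cerad = c >= _CERAD_RANK["B"]
    if ad_pathology_rule == "or":
        ad_pathology = high_braak or high_cerad
    else:
        ad_pathology = high_braak and high_cerad
    control_pathology = b <= _BRAAK_RANK["II"] and c <= _CERAD_RANK["A"]
    if ad_pathology and cdr >= 1:
        return "CP-AD"
    if ad_pathology and cdr == 0:
        return "P-AD"
    if control_pathology and cdr == 0:
        return "N"
    return "Unclassified"


def assign_groups(subjects: pd.DataFrame, *, ad_pathology_rule: str = "or") -> pd.DataFrame:
    """Return a copy of the subject table with a ``group`` column appended.

    Raises a :class:`ValueError` naming the offending row on unparseable
    Braak/CERAD tokens.
    """
    out = subjects.copy()
    labels = []
    for idx, row in out.iterrows():
        try:
            labels.append(
                assign_group(
                    row["braak"], row["cerad"], row["cdr"],
                    ad_pathology_rule=ad_pathology_rule,
                )
            )
        except ValueError as exc:
            sid = row.get("subject_id", idx)
            raise ValueError(f"subject {sid!r}: {exc}") from None
    out["group"] = labels
    return out


def reference_cohort() -> pd.DataFrame:
    """The published 23-case summary table with derived group labels."""
    df = pd.read_csv(io.StringIO(_REFERENCE_COHORT_TSV), sep="\t", dtype={"braak": str, "cerad": str})
    return assign_groups(df)


def read_subject_table(path) -> pd.DataFrame:
    """Read a delimited subject table, tolerating the published header names."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    rename = {
        "Sample ID": "subject_id", "sample_id": "subject_id", "ID": "subject_id",
        "Gender": "sex", "gender": "sex", "Sex": "sex",
        "Age": "age", "Braak": "braak", "CERAD": "cerad", "CDR": "cdr",
        "PMI": "pmi",
    }
    df = df.rename(columns={c: rename.get(c, c.lower()) for c in df.columns})
    required = {"subject_id", "braak", "cerad", "cdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    df["cdr"] = df["cdr"].astype(float)
    for col in ("age", "pmi"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    return df


def build_design(subjects: pd.DataFrame, dye_swap: bool = True) -> pd.DataFrame:
    """Expand subjects into an array manifest under the dye-swap design.

    With ``dye_swap`` each subject yields two arrays of opposite dye
    orientation (+1 and -1); group labels are carried through to arrays.
    The orientation sign says which channel holds the test sample: on a -1
    array the Cy labels were exchanged, so the raw log-ratio flips sign.
    """
    if len(subjects) == 0:
        raise ValueError("empty cohort: no subjects to expand into arrays")
    if "group" not in subjects.columns:
        subjects = assign_groups(subjects)
    rows = []
    for _, s in subjects.iterrows():
        sid = s["subject_id"]
        if dye_swap:
            rows.append((f"{sid}.1", sid, s["group"], 1))
            rows.append((f"{sid}.2", sid, s["group"], -1))
        else:
            rows.append((f"{sid}.1", sid, s["group"], 1))
    return pd.DataFrame(rows, columns=["array_id", "subject_id", "group", "orientation"])


def contrast_groups(contrast: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Group labels on each side of a named contrast.

    ``pathology``: cases with AD pathology (CP-AD + P-AD) vs. controls (N).
    ``manifestation``: demented vs. non-demented among pathology carriers
    (CP-AD vs. P-AD).
    """
    if contrast == "pathology":
        return ("CP-AD", "P-AD"), ("N",)
    if contrast == "manifestation":
        return ("CP-AD",), ("P-AD",)
    raise ValueError(f"unknown contrast {contrast!r} (expected 'pathology' or 'manifestation')")
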