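"""Synthetic two-channel microarray experiments with planted ground truth.

Everything downstream of image quantification can be exercised on data from
this module: a clinical cohort whose Braak/CERAD/CDR values are consistent
with intended group labels, spot-level two-channel intensity tables under a
dye-swap reference design, a protein-interaction edge list, and a
gene-to-category annotation table.  Planted structure (differentially
expressed genes, group-specific co-expression around hub genes, a 3-gene
class signature) is returned in a truth record so parameter-recovery tests
have exact ground truth.

Intensity model
---------------
Only the per-spot log-ratio ``M = log2(ch2/ch1)`` matters downstream, so the
mean log-intensity ``A`` is a free nuisance drawn independently.  For each
spot the background-subtracted channel signals are ``2**(A - M_raw/2)`` and
``2**(A + M_raw/2)`` with a log-normal additive background, where::

    M_raw = orientation * M_bio + dye_bias(A) + technical noise

``orientation`` is +1 on forward arrays and -1 on dye-swap arrays (the
channels were physically exchanged, flipping the biological ratio), while
the dye bias is a smooth function of A shared by all arrays — exactly what
within-array lowess normalization removes.

Group-specific co-expression is planted through a shared latent factor per
hub: with loading ``a = sqrt(|rho|)`` on the hub and ``sign(rho) * a`` on
each interactor, every hub–interactor pair has Pearson correlation exactly
``rho`` in expectation, giving closed-form control of the planted PCC.

All randomness flows from one top-level seed via ``numpy`` SeedSequence
spawning, with a fixed stream index per stage (cohort, biology, arrays,
artifacts), so identical specs give byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cohort as _cohort

__all__ = [
    "SyntheticCohortSpec",
    "PlantedSignal",
    "SyntheticExperiment",
    "gene_ids",
    "generate_cohort",
    "generate_expression",
    "generate_interactome",
    "generate_annotation",
    "write_experiment",
    "truth_edges",
]

SATURATION_VALUE = 64000.0  # written into planted saturated spots (>= 63000 ceiling)


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic child generator: one stream index per pipeline stage."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


def gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Design of a synthetic autopsy cohort and its array layout.

    Defaults mirror the emulated study: a 4,608-probe custom platform and a
    dye-swap replicate pair for every subject (arrays = 2 x subjects).
    """

    n_cpad: int
    n_pad: int
    n_control: int
    n_genes: int = 4608
    dye_swap: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cpad", "n_pad", "n_control"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")

    @property
    def n_subjects(self) -> int:
        return self.n_cpad + self.n_pad + self.n_control

    @property
    def n_arrays(self) -> int:
        return self.n_subjects * (2 if self.dye_swap else 1)


@dataclass(frozen=True)
class PlantedSignal:
    """Ground-truth structure planted into a synthetic experiment.

    Fields
    ------
    de_genes
        ``(gene_id, log2_effect, direction)`` triples; ``direction`` is
        ``"up"``/``"down"`` in the pathology group relative to controls.
    diffcorr_hubs
        ``(hub_gene_id, n_interactors, pcc_pathology, pcc_control)`` —
        hub–interactor Pearson correlation planted per group.
    triplet_signature
        Three gene ids separated between CP-AD and P-AD by
        ``triplet_offset`` (log2 units, added to CP-AD subjects).
    noise_sd
        Subject-level biological noise s.d. of M values (log2 units).
    """

    de_genes: tuple[tuple[str, float, str], ...] = ()
    diffcorr_hubs: tuple[tuple[str, int, float, float], ...] = ()
    triplet_signature: tuple[str, str, str] | None = None
    triplet_offset: float = 1.5
    noise_sd: float = 0.5

    def __post_init__(self):
        for gid, eff, direction in self.de_genes:
            if not math.isfinite(eff):
                raise ValueError(f"non-finite effect size for {gid}")
            if direction not in ("up", "down"):
                raise ValueError(f"direction must be 'up'/'down', got {direction!r}")
        for hub, k, rho_a, rho_b in self.diffcorr_hubs:
            if abs(rho_a) > 1 or abs(rho_b) > 1:
                raise ValueError(f"planted |PCC| > 1 for hub {hub}")
            if k < 1:
                raise ValueError(f"hub {hub} needs >= 1 interactor")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        planted = [g for g, _, _ in self.de_genes]
        planted += [h for h, *_ in self.diffcorr_hubs]
        if self.triplet_signature is not None:
            if len(self.triplet_signature) != 3:
                raise ValueError("triplet_signature must name exactly 3 genes")
            planted += list(self.triplet_signature)
        if len(planted) != len(set(planted)):
            raise ValueError("planted gene ids must be distinct")


@dataclass
class SyntheticExperiment:
    """In-memory synthetic experiment: spot tables + metadata + ground truth."""

    subjects: pd.DataFrame
    manifest: pd.DataFrame
    arrays: dict[str, pd.DataFrame]
    truth: dict


def generate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Sample a subject table whose derived group labels match the spec.

    Braak/CERAD/CDR are drawn from the value sets each group admits under
    the assignment rules; ages and post-mortem intervals come from the
    plausible autopsy ranges of the emulated cohort (55–100 y, 6–19 h).
    """
    if spec.n_subjects == 0:
        raise ValueError("empty cohort")
    rng = _rng(spec.seed, 0)
    rows = []

    def _draw(group: str, i: int):
        sid = f"{group.replace('-', '')}{i + 1}"
        sex = rng.choice(["F", "M"], p=[0.65, 0.35])
        age = int(np.clip(round(rng.normal(80, 10)), 55, 100))
        pmi = round(float(rng.uniform(6.0, 19.0)), 1)
        if group in ("CP-AD", "P-AD"):
            braak = rng.choice(["IV", "V", "VI"])
            cerad = rng.choice(["A", "B", "C"], p=[0.2, 0.4, 0.4])
            cdr = float(rng.choice([1, 2, 3])) if group == "CP-AD" else 0.0
        else:
            braak = rng.choice(["0", "I", "II"])
            cerad = rng.choice(["0", "A"], p=[0.7, 0.3])
            cdr = 0.0
        rows.append((sid, sex, age, braak, cerad, cdr, pmi))

    for i in range(spec.n_cpad):
        _draw("CP-AD", i)
    for i in range(spec.n_pad):
        _draw("P-AD", i)
    for i in range(spec.n_control):
        _draw("N", i)
    df = pd.DataFrame(rows, columns=["subject_id", "sex", "age", "braak", "cerad", "cdr", "pmi"])
    return _cohort.assign_groups(df)


def _plant_biology(
    spec: SyntheticCohortSpec,
    signal: PlantedSignal,
    subjects: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str], dict]:
    """Subject-level biological M matrix (genes x subjects) plus truth record."""
    ids = gene_ids(spec.n_genes)
    index = {g: i for i, g in enumerate(ids)}
    n_sub = len(subjects)
    groups = subjects["group"].to_numpy()
    pathology = np.isin(groups, ("CP-AD", "P-AD"))
    control = groups == "N"

    M = rng.normal(0.0, signal.noise_sd, size=(spec.n_genes, n_sub))

    truth: dict = {
        "de_genes": [],
        "diffcorr_hubs": [],
        "triplet": None,
        "noise_sd": signal.noise_sd,
    }

    # group-specific co-expression: shared latent factor per hub and group
    taken = {g for g, _, _ in signal.de_genes}
    taken |= {h for h, *_ in signal.diffcorr_hubs}
    if signal.triplet_signature:
        taken |= set(signal.triplet_signature)
    free = [g for g in ids if g not in taken]
    free_pos = 0
    for hub, k, rho_a, rho_b in signal.diffcorr_hubs:
        if hub not in index:
            raise ValueError(f"planted hub {hub} not on platform")
        if free_pos + k > len(free):
            raise ValueError("not enough free genes for planted interactors")
        interactors = free[free_pos:free_pos + k]
        free_pos += k
        members = [hub] + interactors
        mrows = np.array([index[g] for g in members])
        for mask, rho in ((pathology, rho_a), (control, rho_b)):
            m = int(mask.sum())
            if m == 0:
                continue
            a = math.sqrt(abs(rho))
            sign = 1.0 if rho >= 0 else -1.0
            z = rng.normal(size=m)
            resid = rng.normal(size=(len(members), m))
            loadings = np.full(len(members), sign * a)
            loadings[0] = a  # hub carries the positive loading
            vals = loadings[:, None] * z[None, :] + np.sqrt(1 - a * a) * resid
            M[np.ix_(mrows, np.flatnonzero(mask))] = signal.noise_sd * vals
        truth["diffcorr_hubs"].append(
            {"hub": hub, "interactors": interactors, "pcc_pathology": rho_a, "pcc_control": rho_b}
        )

    for gid, eff, direction in signal.de_genes:
        if gid not in index:
            raise ValueError(f"planted DE gene {gid} not on platform")
        delta = eff if direction == "up" else -eff
        M[index[gid], pathology] += delta
        truth["de_genes"].append({"gene": gid, "log2_effect": eff, "direction": direction})

    if signal.triplet_signature is not None:
        cpad = groups == "CP-AD"
        for gid in signal.triplet_signature:
            if gid not in index:
                raise ValueError(f"planted triplet gene {gid} not on platform")
            M[index[gid], cpad] += signal.triplet_offset
        truth["triplet"] = {
            "genes": list(signal.triplet_signature),
            "log2_offset": signal.triplet_offset,
        }
    return M, ids, truth


def generate_expression(
    spec: SyntheticCohortSpec,
    signal: PlantedSignal,
    *,
    subjects: pd.DataFrame | None = None,
    tech_sd: float = 0.1,
    dye_bias: float = 0.3,
    saturation_fraction: float = 0.0,
    nonpositive_fraction: float = 0.0,
) -> SyntheticExperiment:
    """Generate spot-level two-channel arrays with planted signal.

    Parameters
    ----------
    subjects
        Optional pre-generated subject table; by default drawn from ``spec``.
    tech_sd
        Array-level technical noise s.d. added to each spot's M (log2).
    dye_bias
        Amplitude of the smooth intensity-dependent dye bias curve that the
        lowess step must remove.
    saturation_fraction, nonpositive_fraction
        Fractions of spots per array overwritten with a saturated foreground
        (>= 63,000) or a background-dominated foreground, to exercise the
        spot filters.  The two sets are disjoint.
    """
    if subjects is None:
        subjects = generate_cohort(spec)
    manifest = _cohort.build_design(subjects, dye_swap=spec.dye_swap)
    rng_bio = _rng(spec.seed, 1)
    rng_arr = _rng(spec.seed, 2)
    rng_art = _rng(spec.seed, 3)

    M_bio, ids, truth = _plant_biology(spec, signal, subjects, rng_bio)
    sub_index = {s: i for i, s in enumerate(subjects["subject_id"])}
    n_genes = spec.n_genes

    arrays: dict[str, pd.DataFrame] = {}
    for _, arow in manifest.iterrows():
        s = sub_index[arow["subject_id"]]
        orient = int(arow["orientation"])
        m = M_bio[:, s] + (rng_arr.normal(0.0, tech_sd, n_genes) if tech_sd > 0 else 0.0)
        A = rng_arr.normal(11.0, 0.7, n_genes)
        m_raw = orient * m + dye_bias * np.tanh(11.0 - A)
        bg1 = np.power(2.0, rng_arr.normal(6.0, 0.5, n_genes))
        bg2 = np.power(2.0, rng_arr.normal(6.0, 0.5, n_genes))
        ch1 = bg1 + np.power(2.0, A - m_raw / 2.0)
        ch2 = bg2 + np.power(2.0, A + m_raw / 2.0)

        n_sat = int(round(saturation_fraction * n_genes))
        n_bad = int(round(nonpositive_fraction * n_genes))
        if n_sat + n_bad > 0:
            idx = rng_art.choice(n_genes, size=n_sat + n_bad, replace=False)
            sat_idx, bad_idx = idx[:n_sat], idx[n_sat:]
            ch2[sat_idx] = SATURATION_VALUE
            ch1[bad_idx] = bg1[bad_idx] * 0.5  # background-dominated channel
        arrays[arow["array_id"]] = pd.DataFrame(
            {
                "probe_id": ids,
                "ch1_fg": ch1,
                "ch1_bg": bg1,
                "ch2_fg": ch2,
                "ch2_bg": bg2,
            }
        )
    return SyntheticExperiment(subjects=subjects, manifest=manifest, arrays=arrays, truth=truth)


def generate_interactome(
    n_genes: int,
    mean_degree: float,
    seed: int,
    *,
    ids: Sequence[str] | None = None,
    extra_edges: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Random undirected simple interaction graph as a 2-column edge list.

    Erdős–Rényi G(n, p) with p = mean_degree / (n - 1), relabelled to
    platform gene ids; ``extra_edges`` (e.g. planted hub spokes from
    :func:`truth_edges`) are unioned in with duplicate removal.
    """
    if mean_degree < 0:
        raise ValueError("mean_degree must be >= 0")
    if ids is None:
        ids = gene_ids(n_genes)
    rng = _rng(seed, 4)
    p = mean_degree / max(n_genes - 1, 1)
    edges: set[tuple[str, str]] = set()
    # row-wise Bernoulli draw over the upper triangle (memory-light for 4.6k nodes)
    if p > 0:
        for i in range(n_genes - 1):
            hits = np.flatnonzero(rng.random(n_genes - 1 - i) < p)
            for j in hits:
                edges.add((ids[i], ids[i + 1 + j]))
    for a, b in extra_edges:
        if a == b:
            continue
        edges.add((a, b) if a <= b else (b, a))
    ordered = sorted(edges)
    return pd.DataFrame(ordered, columns=["gene_a", "gene_b"])


def truth_edges(truth: Mapping) -> list[tuple[str, str]]:
    """Hub–interactor edges implied by a truth record's planted structure."""
    out = []
    for rec in truth.get("diffcorr_hubs", []):
        out.extend((rec["hub"], j) for j in rec["interactors"])
    return out


def generate_annotation(
    n_genes: int,
    n_categories: int,
    seed: int,
    *,
    ids: Sequence[str] | None = None,
    mean_memberships: float = 2.0,
    planted: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Random gene -> category annotation table.

    Every category is seeded with at least one gene; each gene then joins a
    Poisson-distributed number of additional categories, so multi-membership
    occurs.  ``planted`` adds fixed category memberships (e.g. a category
    enriched for planted DE genes) on top.
    """
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    if ids is None:
        ids = gene_ids(n_genes)
    rng = _rng(seed, 5)
    cats = [f"C{c:03d}" for c in range(n_categories)]
    pairs: set[tuple[str, str]] = set()
    for c in cats:  # non-empty guarantee
        pairs.add((str(rng.choice(ids)), c))
    counts = rng.poisson(mean_memberships, size=len(ids))
    for g, k in zip(ids, counts):
        for c in rng.choice(cats, size=min(int(k), n_categories), replace=False):
            pairs.add((g, str(c)))
    if planted:
        for c, members in planted.items():
            pairs.update((g, c) for g in members)
    out = pd.DataFrame(sorted(pairs), columns=["gene_id", "category_id"])
    return out


def write_experiment(exp: SyntheticExperiment, out_dir) -> Path:
    """Write spot tables, manifest, subject table and truth record to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exp.subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
    exp.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    spot_dir = out / "arrays"
    spot_dir.mkdir(exist_ok=True)
    for array_id, table in exp.arrays.items():
        table.to_csv(spot_dir / f"{array_id}.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(exp.truth, fh, indent=2)
    return out
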