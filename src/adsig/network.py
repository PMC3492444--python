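"""Interactome overlay and differential co-expression signature.

Seed genes (e.g. the DEGs of a contrast) are mapped onto a protein–protein
interaction network together with their first neighbors, the result is
restricted to genes present on the array platform, and each gene ``g`` with
interactors ``j`` is scored by the change in co-expression between two
phenotype groups::

    avg_abs_diff(g) = mean_j | PCC_A(g, j) - PCC_B(g, j) |

where the Pearson correlations are computed across each group's sample
columns.  Significance comes from a permutation null: sample labels are
reassigned to the two groups (sizes preserved) ``n_perm`` times and the
statistic recomputed; a gene's p-value is the frequency of null statistics
at or above the observed one (clamped below at 1/n_perm).  When the number
of distinct relabelings is small the null is enumerated exhaustively.
Genes significant at P <= 0.05 constitute the network signature; exports go
to GraphML/SIF with per-edge group correlations and a degree-ranked hub
report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Subnetwork",
    "NetworkScores",
    "build_subnetwork",
    "diffcorr_signature",
    "export_network",
]

logger = logging.getLogger(__name__)


@dataclass
class Subnetwork:
    """Platform-restricted first-neighbor expansion of a seed gene set."""

    graph: nx.Graph  # node attribute "seed": bool

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b in self.graph.edges]

    def degree(self, gene: str) -> int:
        return int(self.graph.degree[gene])

    def seeds(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("seed")]


@dataclass
class NetworkScores:
    """Per-gene differential-correlation scores plus per-edge observed PCCs."""

    genes: pd.DataFrame  # gene_id, degree, n_scored, avg_abs_diff, times_greater, p_perm, significant
    edges: pd.DataFrame  # gene_a, gene_b, pcc_a, pcc_b


def _as_graph(interactome) -> nx.Graph:
    if isinstance(interactome, nx.Graph):
        G = nx.Graph(interactome)
    elif isinstance(interactome, pd.DataFrame):
        a, b = interactome.columns[:2]
        G = nx.from_pandas_edgelist(interactome, source=a, target=b)
    else:
        G = nx.Graph(list(interactome))
    G.remove_edges_from(nx.selfloop_edges(G))
    return G


def build_subnetwork(seeds, interactome, platform_genes) -> Subnetwork:
    """Expand seeds to first neighbors and restrict to the platform.

    Nodes are ``(seeds ∪ neighbors(seeds)) ∩ platform`` with the induced
    edge set; seeds with no interactome entry are retained as isolated
    nodes (degree 0) and logged.
    """
    seeds = list(dict.fromkeys(seeds))
    if not seeds:
        raise ValueError("seed gene set is empty")
    platform = set(platform_genes)
    G = _as_graph(interactome)
    missing = [s for s in seeds if s not in G]
    if missing:
        logger.info("%d seed gene(s) absent from the interactome: %s",
                    len(missing), ",".join(missing[:5]))
    nodes = set(s for s in seeds if s in platform)
    for s in seeds:
        if s in G:
            nodes.update(j for j in G.neighbors(s) if j in platform)
    if not nodes:
        raise ValueError("subnetwork is empty after platform restriction")
    H = nx.Graph()
    H.add_nodes_from(nodes)
    H.add_edges_from((a, b) for a, b in G.subgraph(nodes).edges)
    seed_set = set(seeds)
    nx.set_node_attributes(H, {n: n in seed_set for n in H.nodes}, "seed")
    return Subnetwork(graph=H)


def _edge_pcc_per_perm(xg: np.ndarray, xj: np.ndarray, masks: np.ndarray):
    """PCC of one gene pair within mask=True and mask=False columns, per perm.

    ``masks`` is perms x m boolean over the pair's complete columns.
    Degenerate groups (fewer than 3 points or zero variance) yield NaN.
    """
    out = []
    for mk in (masks, ~masks):
        n = mk.sum(axis=1).astype(float)
        sg = mk @ xg
        sj = mk @ xj
        sgg = mk @ (xg * xg)
        sjj = mk @ (xj * xj)
        sgj = mk @ (xg * xj)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sgj - sg * sj / n
            vg = sgg - sg * sg / n
            vj = sjj - sj * sj / n
            pcc = cov / np.sqrt(vg * vj)
            pcc = np.where((n >= 3) & (vg > 0) & (vj > 0), pcc, np.nan)
        out.append(pcc)
    return out[0], out[1]


def _relabelings(is_a: np.ndarray, n_perm: int, seed) -> np.ndarray:
    """Perms x n boolean label matrix, exhaustive when C(n, n_A) <= n_perm."""
    n, na = is_a.size, int(is_a.sum())
    if comb(n, na) <= n_perm:
        masks = np.zeros((comb(n, na), n), dtype=bool)
        for i, pos in enumerate(combinations(range(n), na)):
            masks[i, list(pos)] = True
        return masks
    rng = np.random.default_rng(seed)
    return np.stack([rng.permutation(is_a) for _ in range(n_perm)])


def diffcorr_signature(
    subnetwork: Subnetwork,
    values: pd.DataFrame,
    groups: pd.Series | dict,
    a: str,
    b: str,
    *,
    n_perm: int = 1000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> NetworkScores:
    """Permutation test of per-gene co-expression change between groups.

    Parameters
    ----------
    values
        Genes x samples expression matrix; only subnetwork genes with a row
        here can be scored.  Pairwise-complete columns are used per edge.
    groups, a, b
        Column labels and the two group names to contrast.
    alpha
        Significance operating point for the ``significant`` flag.
    """
    groups = pd.Series(groups)
    cols = [c for c in values.columns if groups.get(c) in (a, b)]
    is_a = np.array([groups[c] == a for c in cols])
    if is_a.sum() < 3 or (~is_a).sum() < 3:
        raise ValueError("need at least 3 samples per group for correlation")
    X = values[cols].to_numpy(float)
    row_of = {g: i for i, g in enumerate(values.index)}

    # scoreable edges: both endpoints measured and non-constant
    edges = []
    for g, j in subnetwork.graph.edges:
        if g not in row_of or j not in row_of:
            logger.info("edge %s-%s skipped: no expression row", g, j)
            continue
        edges.append((g, j))

    masks = _relabelings(is_a, n_perm, seed)
    n_lab = masks.shape[0]
    genes = sorted(subnetwork.graph.nodes)
    gidx = {g: i for i, g in enumerate(genes)}
    sum_diff = np.zeros((len(genes), n_lab))
    cnt_diff = np.zeros((len(genes), n_lab))
    obs_edges = []
    identity = is_a[None, :]

    for g, j in edges:
        xg_full, xj_full = X[row_of[g]], X[row_of[j]]
        ok = np.isfinite(xg_full) & np.isfinite(xj_full)
        if ok.sum() < 6:
            logger.info("edge %s-%s skipped: <6 complete samples", g, j)
            continue
        xg, xj = xg_full[ok], xj_full[ok]
        if np.ptp(xg) == 0 or np.ptp(xj) == 0:
            logger.info("edge %s-%s skipped: constant expression", g, j)
            continue
        mk = masks[:, ok]
        pa, pb = _edge_pcc_per_perm(xg, xj, mk)
        diff = np.abs(pa - pb)
        good = np.isfinite(diff)
        for node in (g, j):
            i = gidx[node]
            sum_diff[i, good] += diff[good]
            cnt_diff[i, good] += 1
        oa, ob = _edge_pcc_per_perm(xg, xj, identity[:, ok])
        obs_edges.append((g, j, float(oa[0]), float(ob[0])))

    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(cnt_diff > 0, sum_diff / np.maximum(cnt_diff, 1), np.nan)

    # observed statistic per gene from the per-edge observed PCCs
    obs_sum = np.zeros(len(genes))
    obs_cnt = np.zeros(len(genes))
    for g, j, oa, ob in obs_edges:
        d = abs(oa - ob)
        if np.isfinite(d):
            for node in (g, j):
                obs_sum[gidx[node]] += d
                obs_cnt[gidx[node]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_avg = np.where(obs_cnt > 0, obs_sum / np.maximum(obs_cnt, 1), np.nan)

    rows = []
    for g in genes:
        i = gidx[g]
        if obs_cnt[i] == 0:
            continue  # unscored: no usable interactor
        null = avg[i]
        # ties at floating precision count as hits (complement relabelings
        # give mathematically equal statistics)
        thresh = obs_avg[i] * (1 - 1e-10) - 1e-12
        times = int(np.nansum(null >= thresh))
        p = max(times, 1) / n_lab
        rows.append(
            {
                "gene_id": g,
                "degree": subnetwork.degree(g),
                "n_scored": int(obs_cnt[i]),
                "avg_abs_diff": obs_avg[i],
                "times_greater": times,
                "p_perm": p,
                "significant": p <= alpha,
            }
        )
    genes_df = pd.DataFrame(
        rows,
        columns=["gene_id", "degree", "n_scored", "avg_abs_diff",
                 "times_greater", "p_perm", "significant"],
    ).sort_values(["p_perm", "gene_id"], kind="stable").reset_index(drop=True)
    edges_df = pd.DataFrame(obs_edges, columns=["gene_a", "gene_b", "pcc_a", "pcc_b"])
    return NetworkScores(genes=genes_df, edges=edges_df)


def export_network(
    scores: NetworkScores,
    subnetwork: Subnetwork,
    out_dir,
    *,
    deg_genes=(),
    basename: str = "network",
) -> dict[str, Path]:
    """Write GraphML + SIF + degree-ranked hub report.

    Node attributes: ``seed``/``deg`` flags, degree, and (where scored)
    ``avg_abs_diff``, ``p_perm``, ``significant``.  Edge attributes carry
    the per-group observed correlations.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    G = nx.Graph()
    deg_set = set(deg_genes)
    by_gene = scores.genes.set_index("gene_id")
    for n, d in subnetwork.graph.nodes(data=True):
        attrs = {
            "seed": bool(d.get("seed", False)),
            "deg": n in deg_set,
            "degree": subnetwork.degree(n),
        }
        if n in by_gene.index:
            rec = by_gene.loc[n]
            attrs.update(
                avg_abs_diff=float(rec["avg_abs_diff"]),
                p_perm=float(rec["p_perm"]),
                significant=bool(rec["significant"]),
            )
        G.add_node(n, **attrs)
    pcc = {(r.gene_a, r.gene_b): (r.pcc_a, r.pcc_b) for r in scores.edges.itertuples()}
    for u, v in subnetwork.graph.edges:
        key = (u, v) if (u, v) in pcc else (v, u)
        if key in pcc:
            G.add_edge(u, v, pcc_a=float(pcc[key][0]), pcc_b=float(pcc[key][1]))
        else:
            G.add_edge(u, v)
    paths = {
        "graphml": out / f"{basename}.graphml",
        "sif": out / f"{basename}.sif",
        "hubs": out / f"{basename}_hubs.tsv",
    }
    nx.write_graphml(G, paths["graphml"])
    with open(paths["sif"], "w") as fh:
        for u, v in G.edges:
            fh.write(f"{u}\tpp\t{v}\n")
        for n in G.nodes:
            if G.degree[n] == 0:
                fh.write(f"{n}\n")
    hubs = pd.DataFrame(
        sorted(((n, G.nodes[n]["degree"]) for n in G.nodes), key=lambda t: (-t[1], t[0])),
        columns=["gene_id", "degree"],
    )
    hubs.to_csv(paths["hubs"], sep="\t", index=False)
    return paths
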