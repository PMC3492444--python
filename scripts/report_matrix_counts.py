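#!/usr/bin/env python
"""Report headline analysis counts for a user-supplied normalized matrix.

Intended for a pre-normalized log-ratio gene x array matrix (e.g. a series
matrix export of the deposited hybridizations) plus the subject table.  The
script recomputes, without asserting any expected values:

* DEG counts for the pathology contrast at P <= 0.01 (with up/down split)
  and P <= 0.005, and for the manifestation contrast at P <= 0.01;
* the 2-cluster split of samples clustered on the stricter DEG set;
* with ``--interactome``, the number of significant differential-correlation
  genes at P <= 0.05.

Counts from real data depend on normalization choices and interactome
snapshots, so they are reported for comparison only.

Usage:
    python scripts/report_matrix_counts.py --matrix M.tsv --subjects S.tsv \
        [--manifest MAN.tsv] [--interactome EDGES.tsv] [--seed 0] [--n-perm 1000]
"""

import argparse
import json
import sys
from collections import Counter

import pandas as pd

from adsig import clustering, cohort, diffexpr, network
from adsig.pipeline import read_interactome


def build_labels(matrix: pd.DataFrame, subjects: pd.DataFrame, manifest) -> pd.Series:
    subjects = cohort.assign_groups(subjects) if "group" not in subjects.columns else subjects
    by_subject = subjects.set_index("subject_id")["group"]
    if manifest is not None:
        man = manifest.set_index("array_id")
        return pd.Series({c: by_subject[man.loc[c, "subject_id"]] for c in matrix.columns})
    if set(matrix.columns) <= set(by_subject.index):
        return pd.Series({c: by_subject[c] for c in matrix.columns})
    raise SystemExit("matrix columns are not subject ids; provide --manifest")


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--matrix", required=True)
    ap.add_argument("--subjects", required=True)
    ap.add_argument("--manifest", default=None)
    ap.add_argument("--interactome", default=None)
    ap.add_argument("--n-perm", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default=None, help="optional JSON output path")
    args = ap.parse_args(argv)

    matrix = pd.read_csv(args.matrix, sep="\t", index_col=0)
    subjects = cohort.read_subject_table(args.subjects)
    manifest = pd.read_csv(args.manifest, sep="\t") if args.manifest else None
    groups = build_labels(matrix, subjects, manifest)

    report = {"n_genes": int(matrix.shape[0]), "n_columns": int(matrix.shape[1]),
              "group_sizes": dict(Counter(groups))}

    lab_path = groups.map(lambda g: "A" if g in ("CP-AD", "P-AD") else ("B" if g == "N" else ""))
    res = diffexpr.permutation_ttest(matrix, lab_path, "A", "B",
                                     n_perm=args.n_perm, seed=args.seed)
    for alpha, key in ((0.01, "pathology_degs_p01"), (0.005, "pathology_degs_p005")):
        sel, counts = diffexpr.select_degs(res, alpha)
        report[key] = counts
    strict, _ = diffexpr.select_degs(res, 0.005)

    lab_man = groups.map(lambda g: "A" if g == "CP-AD" else ("B" if g == "P-AD" else ""))
    res_man = diffexpr.permutation_ttest(matrix, lab_man, "A", "B",
                                         n_perm=args.n_perm, seed=args.seed)
    _, counts_man = diffexpr.select_degs(res_man, 0.01)
    report["manifestation_degs_p01"] = counts_man

    if len(strict) >= 2:
        dend = clustering.average_linkage(matrix, strict.index)
        cut = clustering.cut_to_k(dend, 2)
        split = {}
        for col, cl in cut.items():
            split.setdefault(cl, Counter())[groups[col]] += 1
        report["two_cluster_split"] = {str(k): dict(v) for k, v in split.items()}

    if args.interactome and len(strict):
        edges = read_interactome(args.interactome)
        subnet = network.build_subnetwork(list(strict.index), edges, matrix.index)
        scores = network.diffcorr_signature(subnet, matrix, lab_path, "A", "B",
                                            n_perm=args.n_perm, seed=args.seed)
        report["network_nodes"] = len(subnet.nodes)
        report["network_significant_p05"] = int(scores.genes["significant"].sum())

    text = json.dumps(report, indent=2)
    print(text)
    if args.out:
        with open(args.out, "w") as fh:
            fh.write(text + "\n")
    return 0


if __name__ == "__main__":
    sys.exit(main())
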