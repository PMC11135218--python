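#!/usr/bin/env python
"""Profile the shared genes across the simulated disease datasets.

Intersects gene IDs across the 3 disease matrices from
01_simulate_datasets.py, summarizes each shared gene per dataset by
mean/median/SD/variance (datasets have unequal sample counts, so the
4-statistic summary is the common representation), and builds a
per-gene disease tree with the maximum-average combination.  Reports,
per gene, which two diseases cluster together and whether that matches
the planted means.  Writes per-gene profiles and Newick trees under
results/pleiotropy/.
"""

import numpy as np
import pandas as pd

from analysis_util import DATA, RESULTS, ensure_data
from clustgrid import (
    find_common_genes,
    pleiotropy_tree,
    read_expression_matrix,
    summarize_gene,
    write_newick,
)
from clustgrid.pleiotropy import SUMMARY_COLUMNS


def main() -> None:
    ensure_data()
    datasets = [read_expression_matrix(DATA / f"disease_{i}.tsv") for i in range(3)]
    planted = pd.read_csv(RESULTS / "data" / "shared_genes.tsv", sep="\t", index_col=0)
    common = find_common_genes(datasets)
    print(f"{len(common)} genes shared by all {len(datasets)} disease datasets: {common}")
    outdir = RESULTS / "pleiotropy"
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for gid in common:
        profile = summarize_gene(gid, datasets)
        pd.DataFrame(
            profile.stats, index=profile.dataset_names, columns=SUMMARY_COLUMNS
        ).to_csv(outdir / f"{gid}.profile.tsv", sep="\t")
        tree = pleiotropy_tree(profile, metric="maximum", linkage="average")
        (outdir / f"{gid}.nwk").write_text(
            write_newick(tree, profile.dataset_names) + "\n"
        )
        sisters = sorted(
            profile.dataset_names[i] for i in (int(tree.left[0]), int(tree.right[0]))
        )
        means = planted.loc[gid].to_numpy()
        gaps = np.abs(means[:, None] - means[None, :]).astype(float)
        np.fill_diagonal(gaps, np.inf)
        i, j = np.unravel_index(np.argmin(gaps), gaps.shape)
        expected = sorted((planted.columns[i], planted.columns[j]))
        rows.append(
            {
                "gene": gid,
                "sister_diseases": "+".join(sisters),
                "closest_planted_means": "+".join(expected),
                "match": sisters == expected,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "sister_summary.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(
        f"\n{int(df['match'].sum())}/{len(df)} per-gene trees pair the two diseases "
        "with the closest planted means"
    )


if __name__ == "__main__":
    main()
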