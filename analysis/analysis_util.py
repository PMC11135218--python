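"""Shared helpers for the analysis drivers.

Bulky regenerable artifacts (expression matrices, full gene trees) live
under scratch/; small result tables live under results/.  Every driver
calls :func:`ensure_data` so the inputs exist whatever order the
scripts run in.
"""

from pathlib import Path

import numpy as np
from scipy.special import comb

from clustgrid import (
    PlantedSpec,
    generate_disease_collection,
    generate_planted_matrix,
    write_expression_matrix,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
DATA = SCRATCH / "data"
SEED = 2026


def ari(a, b) -> float:
    """Adjusted Rand index between two label vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    ct = np.zeros((a.max() + 1, b.max() + 1))
    for x, y in zip(a, b):
        ct[x, y] += 1
    sum_ij = comb(ct, 2).sum()
    sa = comb(ct.sum(axis=1), 2).sum()
    sb = comb(ct.sum(axis=0), 2).sum()
    total = comb(a.size, 2)
    exp = sa * sb / total
    denom = (sa + sb) / 2 - exp
    return 1.0 if denom == 0 else float((sum_ij - exp) / denom)


def ensure_data(force: bool = False, verbose: bool = False) -> None:
    """Generate the study datasets (idempotent unless ``force``).

    Planted matrices: medium regime scaled down 10x (200 genes x 60
    samples, k=4, separation 10), one uniform and one heteroscedastic.
    Disease collection: 3 datasets of 200 genes with 60/72/60 samples
    and 9 planted shared genes.
    """
    marker = DATA / "planted_uniform.tsv"
    if marker.exists() and not force:
        return
    DATA.mkdir(parents=True, exist_ok=True)
    (RESULTS / "data").mkdir(parents=True, exist_ok=True)

    for profile in ("uniform", "heteroscedastic"):
        spec = PlantedSpec(
            n_genes=200,
            n_samples=60,
            k=4,
            separation=10,
            column_variance_profile=profile,
            seed=SEED,
        )
        m, truth = generate_planted_matrix(spec)
        path = DATA / f"planted_{profile}.tsv"
        write_expression_matrix(m, path)
        with open(RESULTS / "data" / f"planted_{profile}.truth.tsv", "w") as fh:
            fh.write("gene_id\tcluster\n")
            for g, lab in zip(m.gene_ids, truth.labels):
                fh.write(f"{g}\t{int(lab)}\n")
        if verbose:
            print(f"wrote {path} ({m.n_genes} genes x {m.n_samples} samples, k={spec.k})")

    specs = [
        PlantedSpec(n_genes=200, n_samples=p, k=2, separation=5, seed=SEED + 1 + i)
        for i, p in enumerate((60, 72, 60))
    ]
    coll = generate_disease_collection(3, 9, specs, seed=SEED + 10)
    for m in coll.matrices:
        path = DATA / f"{m.name}.tsv"
        write_expression_matrix(m, path)
        if verbose:
            print(f"wrote {path} ({m.n_genes} genes x {m.n_samples} samples)")
    with open(RESULTS / "data" / "shared_genes.tsv", "w") as fh:
        fh.write("gene_id\t" + "\t".join(m.name for m in coll.matrices) + "\n")
        for gid, row in zip(coll.shared_gene_ids, coll.shared_means):
            fh.write(gid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
    if verbose:
        print(f"planted {len(coll.shared_gene_ids)} shared genes across 3 disease datasets")
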