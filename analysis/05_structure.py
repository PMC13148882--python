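#!/usr/bin/env python
"""Project the genetic landscape: classical MDS and UPGMA clustering.

Restricts the average-D matrix to a readable set of reference populations
(Southern European, West African, Amerindian, East Asian and regional admixed
groups plus the study cohort), embeds it in two dimensions by classical MDS,
and builds the UPGMA dendrogram.  Writes coordinates, Newick tree, and — if
matplotlib is importable — a two-panel figure under results/.
"""

from pathlib import Path

import pandas as pd

from nullmark.genetic_distance import DistanceMatrix
from nullmark.structure_viz import classical_mds, upgma

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

POPULATIONS = [
    "current study",
    "Urban/admixed (Venezuela)",
    "Wayuu (ethnic group, Venezuela)",
    "Pemon (ethnic group, Venezuela)",
    "Colombia",
    "Mexico (central)",
    "Portuguese",
    "Spanish (Madrid)",
    "Italian (Rome)",
    "Ibo (Abuja)",
    "Yoruba (Abuja)",
    "Chinese (Beijing)",
    "Japanese (Tokyo)",
]


def main() -> None:
    frame = pd.read_csv(RESULTS / "distance_matrix_subset.tsv", sep="\t", index_col=0)
    full = DistanceMatrix(list(frame.index), frame.to_numpy())
    matrix = full.subset(POPULATIONS)

    mds = classical_mds(matrix, k=2)
    mds.write_tsv(RESULTS / "mds_coordinates.tsv")
    print("classical MDS (k=2):")
    print(mds.to_frame().round(4).to_string())
    print(f"eigenvalues: {mds.eigenvalues[:4].round(5)} ... "
          f"negative inertia {mds.negative_inertia:.5f}, "
          f"reconstruction error {mds.reconstruction_error:.5f}")

    tree = upgma(matrix)
    tree.write_newick(RESULTS / "upgma_tree.nwk")
    print("\nUPGMA Newick:")
    print(tree.to_newick())

    coords = mds.to_frame()
    nearest = (
        ((coords - coords.loc["current study"]) ** 2).sum(axis=1).drop("current study").idxmin()
    )
    print(f"\nnearest neighbour of the study cohort in the MDS plane: {nearest}")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram
    except ImportError:
        print("matplotlib not available; skipping figure")
        return

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(13, 5))
    ax1.scatter(coords["dim1"], coords["dim2"], s=18, color="steelblue")
    for label, row in coords.iterrows():
        ax1.annotate(label, (row["dim1"], row["dim2"]), fontsize=7)
    ax1.set_xlabel("dim 1")
    ax1.set_ylabel("dim 2")
    ax1.set_title("Classical MDS of average Nei D")

    # scipy-style linkage rows (height doubled back to cluster distance).
    import numpy as np

    link = np.array([[l, r, 2 * h, s] for l, r, h, s in tree.merges], dtype=float)
    dendrogram(link, labels=matrix.labels, ax=ax2, leaf_rotation=90, leaf_font_size=7)
    ax2.set_title("UPGMA on average Nei D")
    fig.tight_layout()
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    fig.savefig(scratch / "structure.png", dpi=120)
    print("-> results/mds_coordinates.tsv, upgma_tree.nwk, scratch/structure.png")


if __name__ == "__main__":
    main()
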