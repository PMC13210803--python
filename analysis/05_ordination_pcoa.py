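#!/usr/bin/env python
"""Principal coordinates of the Sokal-Michener dissimilarity matrix.

Embeds the 110 focal individuals, reports the variance explained by the two
leading axes, and writes per-sample coordinates plus population centroids to
results/; a scatter plot goes to scratch/figures/.
"""

from pathlib import Path

import pandas as pd

from popband import (centroids, pcoa, read_band_matrix, sokal_michener_matrix,
                     subset_samples)
from popband.ordination import plot_pcoa

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "synthetic_dataset"
FOCAL = {"CG", "DN", "PQ", "CD"}


def main() -> None:
    m = subset_samples(read_band_matrix(DATA / "band_matrix.csv", "long_csv"),
                       FOCAL)
    r = pcoa(sokal_michener_matrix(m), n_axes=2)
    coords = pd.DataFrame(r.coordinates, columns=["axis_1", "axis_2"])
    coords.insert(0, "population", list(m.population_labels))
    coords.insert(0, "sample_id", list(m.sample_ids))
    coords.to_csv(ROOT / "results" / "pcoa_coordinates.csv", index=False)

    cents = centroids(r, m.population_labels)
    pd.DataFrame([{"population": p, "axis_1": c[0], "axis_2": c[1]}
                  for p, c in cents.items()]).to_csv(
        ROOT / "results" / "pcoa_centroids.csv", index=False)

    print(f"axis 1 explains {r.pct_variance[0]:.1f}% of the variance, "
          f"axis 2 explains {r.pct_variance[1]:.1f}%")
    for p, c in cents.items():
        print(f"centroid {p}: ({c[0]:+.3f}, {c[1]:+.3f})")

    fig_dir = ROOT / "scratch" / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    plot_pcoa(r, m.population_labels, fig_dir / "pcoa.png",
              title="PCoA of Sokal-Michener dissimilarities")
    print(f"figure: {fig_dir / 'pcoa.png'}")


if __name__ == "__main__":
    main()
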