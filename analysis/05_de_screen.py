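#!/usr/bin/env python
"""Differential-expression filtering, TF ranking, coordinate normalization
and the normality-gated test selector on synthetic tables.

Builds a synthetic DESeq2-style results table with a planted set of
upregulated transcription factors, applies the padj <= 0.05 / |log2FC| >=
0.59 filter, ranks the top-20 TFs, normalizes a synthetic cell-coordinate
table to the central canal, and demonstrates the test selector on Gaussian
and heavy-tailed groups.  Writes results/de_top20_tf.csv and
results/section_coords_normalized.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from spinalrhythm.screens import (SectionCoordinates, compare_groups,
                                  filter_de_table, normalize_section_coords,
                                  rank_top_tf)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 100


def synthetic_de_table(rng: np.random.Generator, n_genes: int = 2000,
                       n_tfs: int = 60) -> tuple:
    """Null genes plus a planted block of differentially expressed TFs."""
    genes = [f"gene{i}" for i in range(n_genes)]
    log2fc = rng.normal(0.0, 0.3, n_genes)
    padj = rng.uniform(0.0, 1.0, n_genes)
    padj[rng.random(n_genes) < 0.05] = np.nan   # not expressed per the caller
    tf_names = [f"tf{i}" for i in range(n_tfs)]
    tf_fc = rng.normal(0.0, 1.5, n_tfs)
    tf_fc[:30] += np.sign(tf_fc[:30]) * 0.8     # planted strong responders
    tf_padj = rng.uniform(0.0, 0.08, n_tfs)
    table = pd.DataFrame({
        "gene": genes + tf_names,
        "log2fc": np.concatenate([log2fc, tf_fc]),
        "padj": np.concatenate([padj, tf_padj]),
    })
    return table, set(tf_names)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)

    table, tf_members = synthetic_de_table(rng)
    up, down = filter_de_table(table)
    top = rank_top_tf(pd.concat([up, down], ignore_index=True), tf_members, k=20)
    top.to_csv(RESULTS / "de_top20_tf.csv", index=False)
    print(f"expressed {table['padj'].notna().sum()}, up {len(up)}, down {len(down)}, "
          f"top-20 TFs written ({len(top)} rows)")

    cells = rng.uniform([30.0, 50.0], [290.0, 250.0], size=(200, 2))
    coords = SectionCoordinates(positions=cells, canal=(140.0, 160.0),
                                bbox=(20.0, 300.0, 40.0, 260.0))
    norm = normalize_section_coords(coords)
    pd.DataFrame(norm.positions, columns=["x_norm", "y_norm"]).to_csv(
        RESULTS / "section_coords_normalized.csv", index=False)
    print(f"normalized {len(cells)} cell positions to the central canal; "
          f"extent x [{norm.positions[:,0].min():.2f}, {norm.positions[:,0].max():.2f}]")

    gauss = compare_groups([rng.normal(0, 1, 10), rng.normal(0.8, 1, 10)])
    heavy = compare_groups([np.append(rng.normal(0, 1, 9), 40.0),
                            rng.normal(0, 1, 10)])
    print(f"Gaussian groups -> {gauss.test} (p = {gauss.p:.3f}); "
          f"outlier group -> {heavy.test} (p = {heavy.p:.3f})")


if __name__ == "__main__":
    main()
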