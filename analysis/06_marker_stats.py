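#!/usr/bin/env python
"""Rank the TR/SSR markers and ordinate the populations.

Sum-normalizes and log-transforms the marker matrix, runs the per-marker
Kruskal-Wallis test and PLS-DA (reporting VIP scores), selects the top
five markers, and runs PCA on them with per-population mean scores.
Writes marker_stats.tsv, pca_scores.tsv and pca_group_scores.tsv under
results/study/.
"""

import sys
from pathlib import Path

from mitomarkers import (kruskal_wallis, normalize, pca, plsda_vip,
                         top_markers)
from mitomarkers.io_formats import read_marker_table
from mitomarkers.pipeline import NormalizedView

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main(seed: int = 1) -> None:
    table = read_marker_table(OUT / "marker_matrix.tsv")
    norm = normalize(table)
    kw = kruskal_wallis(norm)
    vip = plsda_vip(norm)
    ranked = top_markers(kw, vip, 5)
    stats = kw.table.copy()
    stats["VIP"] = vip.vip
    stats["rank"] = [ranked.index(m) + 1 if m in ranked else "" for m in stats.index]
    stats.to_csv(OUT / "marker_stats.tsv", sep="\t")
    res = pca(NormalizedView(norm.values[ranked], norm.groups),
              collapse_groups=True)
    res.scores.to_csv(OUT / "pca_scores.tsv", sep="\t")
    res.group_scores.to_csv(OUT / "pca_group_scores.tsv", sep="\t")
    significant = [m for m in stats.index if stats.loc[m, "p"] <= 0.05]
    print("Kruskal-Wallis (H, p) per marker:")
    for m in stats.index:
        print(f"  {m}: H={stats.loc[m, 'H']:.2f}, p={stats.loc[m, 'p']:.3g}, "
              f"VIP={stats.loc[m, 'VIP']:.2f}")
    print(f"markers significant at p<=0.05: {significant}")
    print(f"top-5 combined ranking: {ranked}")
    print(f"PC1/PC2 variance explained: {res.variance_pct[0]:.1f}% / "
          f"{res.variance_pct[1]:.1f}%")
    print(f"wrote marker_stats.tsv, pca_scores.tsv, pca_group_scores.tsv -> {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
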