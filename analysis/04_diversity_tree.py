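#!/usr/bin/env python
"""Nei-Li nucleotide diversity, similarity matrix and the bootstrap UPGMA
tree.

Computes within-population, between-population and regional (north /
south / north-east) diversity, the pairwise similarity matrix and network
edge list, and the TN93 + UPGMA tree of the nine consensuses with 1000
bootstrap replicates. Writes diversity.tsv, similarity_matrix.tsv,
similarity_edges.tsv and tree.nwk under results/study/.
"""

import sys
from pathlib import Path

from mitomarkers import STUDY_REGIONS, diversity_report, read_fasta
from mitomarkers.phylo import bootstrap_tree

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main(seed: int = 1) -> None:
    pop_set = read_fasta(OUT / "sequences.fasta")
    rep = diversity_report(pop_set, STUDY_REGIONS)
    with open(OUT / "diversity.tsv", "w") as fh:
        fh.write("grouping\tname\tpi_percent\n")
        fh.write(f"inter\toverall\t{rep.inter.percent}\n")
        for region, est in rep.regional.items():
            fh.write(f"regional\t{region}\t{est.percent}\n")
        for pop, est in rep.intra.items():
            fh.write(f"intra\t{pop}\t{est.percent}\n")
    rep.similarity.to_tsv(OUT / "similarity_matrix.tsv")
    rep.similarity.edge_list().to_csv(OUT / "similarity_edges.tsv",
                                      sep="\t", index=False)
    tree = bootstrap_tree(rep.consensus_msa, reps=1000, seed=seed)
    (OUT / "tree.nwk").write_text(tree.to_newick() + "\n")
    best, worst = rep.similarity.extremes()
    print(f"overall inter-population pi = {rep.inter.percent}%")
    print("regional pi: " + ", ".join(
        f"{r} {e.percent}%" for r, e in rep.regional.items()))
    intra = {p: e.percent for p, e in rep.intra.items()}
    print(f"intra-population pi ranges {min(intra.values())}-"
          f"{max(intra.values())}%")
    print(f"most similar pair: {best[0]}-{best[1]} ({best[2]:.4f}); "
          f"most divergent: {worst[0]}-{worst[1]} ({worst[2]:.4f})")
    print(f"tree: {tree.to_newick()}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
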