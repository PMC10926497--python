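#!/usr/bin/env python
"""Align each population, call consensuses, and tabulate cross-consensus
SNPs.

Each population's individuals are progressively aligned, a majority/IUPAC
consensus is called per population, the nine consensuses are aligned
against each other, and every variant column (including private SNPs such
as the engineered restriction-site toggles) is tabulated. Writes aligned
FASTAs, consensus.fasta and snp_table.tsv under results/study/.
"""

import sys
from pathlib import Path

from mitomarkers import (call_consensus, progressive_msa, read_fasta,
                         snp_table)
from mitomarkers.alignment import Msa
from mitomarkers.io_formats import LabeledSequence

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main(seed: int = 1) -> None:
    pop_set = read_fasta(OUT / "sequences.fasta")
    consensuses = []
    for population, seqs in pop_set.items():
        msa = progressive_msa(list(seqs))
        with open(OUT / f"msa_{population}.fasta", "w") as fh:
            for row in msa.rows:
                fh.write(f">{row.id}|{row.population}\n{row.residues}\n")
        consensuses.append(call_consensus(msa, population=population))
    with open(OUT / "consensus.fasta", "w") as fh:
        for cons in consensuses:
            fh.write(f">{cons.population}\n{cons.residues}\n")
    cons_msa = progressive_msa(
        [LabeledSequence(c.population, c.population, c.residues)
         for c in consensuses])
    table = snp_table(cons_msa)
    table.to_tsv(OUT / "snp_table.tsv")
    private = table.private_rows()
    substitutions = [r for r in private if "-" not in r.states.values()]
    print(f"aligned {len(pop_set.populations)} populations; "
          f"cross-consensus alignment has {cons_msa.n_columns} columns")
    print(f"SNP table: {len(table)} variant rows, {len(private)} private, "
          f"{len(substitutions)} private substitutions")
    print(f"wrote msa_*.fasta, consensus.fasta, snp_table.tsv -> {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
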