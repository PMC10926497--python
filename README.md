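# mitomarkers

Combinatorial marker analysis of the mitochondrial Control Region for
insect population differentiation.

The brown planthopper (*Nilaparvata lugens*), a migratory rice pest, is
hard to trace with conventional markers. The AT-rich Control Region (CR)
of its mitogenome is extremely length-polymorphic: a 21-bp motif
(`GGAAAAAATGTCACGTTTTTC`, "TR10") is tandemly repeated anywhere from ~4 to
~75 times per individual, and populations additionally carry private SNPs
and private indels (including a 333-bp insertion in one population and a
20-bp deletion in another). This package turns that polymorphism into a
reproducible marker pipeline for population geneticists and pest-surveillance
labs:

- **Tandem-repeat markers** — a periodicity scanner quantifies per-individual
  copy numbers (fractional, to one decimal) for any motif; SSR loci are
  genotyped by in silico PCR amplicon length.
- **Consensus + SNP layer** — per-population progressive multiple alignment,
  majority/IUPAC consensus calling, and a cross-consensus SNP table with
  private-variant flags.
- **Nucleotide diversity** — Nei & Li's estimator
  `pi = n/(n-1) * sum_{a!=b} X_a X_b pi_ab`, where `X_a` is the estimated
  frequency of entity *a* (distinct sequence within a population, or a
  population consensus between populations) and `pi_ab` the proportion of
  differing comparable sites; reported within populations, between all nine
  populations, and per geographic region, plus the pairwise similarity
  matrix `1 - pi_ab`.
- **Phylogeny** — Tamura–Nei (TN93) distances, UPGMA tree, bootstrap support
  from column resampling.
- **dRFLP screen** — in silico digestion of the consensuses with a
  REBASE-derived library of ~200 type II enzymes (via biopython), gel-band
  modelling, and a combinatorial search for the smallest enzyme set whose
  band patterns uniquely identify every population (in the emulated study:
  the HpyCH4IV + Tsp45I double digest).
- **Marker statistics** — sum-normalization + ln transform + autoscaling,
  Kruskal–Wallis per marker, PLS-DA with VIP scores, PCA with per-population
  mean scores.
- **Synthetic data** — a simulator that emulates the study design (nine
  populations, 53 individuals, the TR/SSR loci and private variants above)
  and emits an exact truth record, so every stage is testable without any
  download.

## Worked example

Run the numbered analysis scripts (each reads the previous step's output
from `results/study/`):

```bash
python analysis/01_simulate.py 1
python analysis/02_scan_markers.py 1
python analysis/03_align_consensus.py 1
python analysis/04_diversity_tree.py 1
python analysis/05_drflp_screen.py 1
python analysis/06_marker_stats.py 1
```

With seed 1 this prints (abridged):

```
simulated 53 individuals in 9 populations (seed 1)
control region lengths 1307-3003 bp
TR10 iterations 4.9-70.5
...
overall inter-population pi = 3.6%
regional pi: north 3.2%, south 3.7%, northeast 3.6%
intra-population pi ranges 0.7-1.1%
most similar pair: NewDelhi-Ludhiana (0.9681); most divergent: Cuttack-NewDelhi (0.9601)
...
screened 197 enzymes singly and in pairs: 2381 sets separate all 36 population pairs
HpyCH4IV+Tsp45I double digest: 36/36 pairs distinguished, full discrimination = True
...
markers significant at p<=0.05: ['TR10', 'gSSR3']
top-5 combined ranking: ['TR10', 'gSSR3', 'gSSR1', 'gSSR2', 'TR2']
PC1/PC2 variance explained: 32.8% / 28.5%
```

Reading this: the simulated study set spans 1.3–3.0 kb of CR length driven by
TR10 copy number (4.9–70.5 iterations); between-population diversity sits
at a few percent while within-population diversity (substitution noise
only — the gap-excluding `pi` cannot see copy-number differences) stays
around 1%; the engineered HpyCH4IV + Tsp45I double digest yields nine
distinct gel patterns, one per population; and TR10 dominates the marker
ranking, as expected for the most polymorphic locus.

The same pipeline runs from a shell on any labelled FASTA via the
`mitomarkers` CLI (`simulate`, `scan`, `genotype`, `align`, `consensus`,
`diversity`, `tree`, `digest`, `screen`, `stats`, `run`); population labels
come from the header token after the last `|` or from a two-column
id→population TSV.

## Layout

- `src/mitomarkers/` — the library (io, simulator, markers, alignment,
  diversity, phylogeny, restriction screen, statistics, pipeline, CLI)
- `analysis/` — the numbered study drivers shown above
- `tests/` — pytest suite (oracle-based unit tests, property tests,
  acceptance checks)
- `docs/methods.md` — models, conventions and design choices
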