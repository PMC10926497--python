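# Methods

This note records the models, conventions and design choices behind the
package, in the order the pipeline runs them. It states no empirical result
that the tests or `scripts/acceptance.py` do not themselves compute.

## Coordinates and alphabets

All internal positions are 0-based, half-open; positions in written reports
(SNP tables, digest reports) are 1-based. Sequences are stored uppercase
over the IUPAC alphabet; `-` is legal only inside alignments. IUPAC
ambiguity letters are treated as base *sets* (`W = {A,T}`, `S = {G,C}`,
...), which drives both consensus calling and degenerate enzyme-site
matching.

## Synthetic Control Region populations

The simulator emulates a clone-sequencing survey of nine populations
(N = 53; 5 + 6×8 individuals — only the total is fixed by the emulated
design, so the near-even split is a documented convention). Each individual is built from
a shared random template (default 1028 bp, GC 0.20 — AT-rich, as insect
control regions are) by applying, in template order:

1. the population's **private SNPs** (~25 per population at positions
   disjoint across populations, plus the engineered restriction-site
   toggles below), so between-population consensus divergence lands on the
   few-percent scale typical of such surveys;
2. the population's **private indels** — a 333-bp AT-rich insertion private
   to Bishnupur and a 20-bp deletion private to NewDelhi;
3. **tandem-repeat arrays**: the 21-bp TR10 motif at per-population uniform
   copy ranges spanning 4–75 (lowest in Nalgonda, highest in Bishnupur),
   and a second 12-mer locus (TR2) at 2–8 copies. Fractional copies are
   expanded as full copies plus the first `round(frac·|motif|)` bases;
4. **SSR loci**: three dinucleotide arrays genotyped downstream by in
   silico PCR (integer copies, 40-bp clear primer flanks);
5. i.i.d. **substitution noise** (default 5×10⁻³/site). Noise is
   substitution-only and never lands on a manifest SNP position: large
   indels are population features in this design, not noise, and this
   keeps every truth coordinate exact at any noise rate.

Two RNG streams derive from the seed — one for structure (template, copy
numbers), one for noise — so the structural draw is identical across noise
settings of the same seed. Every edit is recorded in a `TruthRecord`
(realized copy numbers, emitted-coordinate spans, SNP manifest with mapped
positions), checkable by direct string inspection.

**Boundary guards.** Tandem arrays are inserted between template bases
forced to letters that cannot extend the array by chance (e.g. `C` next to
a C-free motif); TR10's sampled fractional parts are restricted to the
subset whose partial-copy boundary base differs from the guard. Without
this, a single chance match at the array edge would shift short-motif copy
numbers by 0.1 and break exact truth recovery.

**Engineered discriminability.** Seven populations carry one private SNP
each that converts a template cassette (`AAGTA`) into an HpyCH4IV site
(`ACGT`) at a distinct position; Aizawl instead carries three toggles that
create Tsp45I sites (`GTSAC`) at spread positions (three, so that at least
one extra cut splits a fragment gel-visibly wherever the flanking cut
landscape falls); NewDelhi carries none (its 20-bp deletion and private
SNPs are its signature). Both enzymes also cut inside the TR10 motif
itself, so the repeat array collapses to invisible 21-bp fragments and the
discrimination is carried by the single-copy regions — the property that
makes this double digest a clean population fingerprint.

**What the simulator does not emulate**: PCR stutter, chimeric clones,
sequencing error profiles, recombination, within-population haplotype
genealogies (no coalescent), heteroplasmy within an individual, and any
nuclear-vs-mitochondrial copy-number difference (SSR loci ride on the same
molecule for convenience). Passing tests therefore show the pipeline's
operations are correct on data with this structure, not that a wet-lab
dataset would be free of those artefacts.

## Tandem-repeat scanner

For each candidate period p (default 2–50) the scanner marks positions
`seq[i] == seq[i-p]` and extracts maximal positive-scoring segments under
match = +1, mismatch = −(1/ε − 1) with ε = 0.2: a segment's overall
mismatch fraction can never exceed ε, segments begin and end on matches,
and a locally hopeless stretch (score < 0) terminates the run. A hit's
copy number is `span/period` rounded to one decimal; its consensus motif
is the per-phase majority; purity is the in-phase match fraction.

Hits whose consensus motif is itself approximately periodic at a smaller
period q ≤ |motif|/2 are discarded: homopolymers seen at period 2 are not
tandem repeats, and composite hits at period multiples (2×21 = 42) would
otherwise systematically outspan the base-period hit (a span includes one
extra period by construction). Overlaps across the surviving periods are
resolved longest-span-first, ties to the smaller period.

This is a deliberate simplification of alignment-based repeat finders: no
wraparound alignment and no probabilistic score model. On arrays of the
purity this pipeline deals with it quantifies copy number exactly
(noise 0) or to within a fraction of a copy (edge erosion under noise).

Locus quantification matches a query motif up to cyclic rotation and one
mismatch; two disjoint matching arrays sum, with a warning. In silico PCR
matches primers by Hamming distance (the simulator introduces
substitutions only), requires the reverse site downstream of the forward
site, scans both strands, and reports amplicon length from forward-site
start to reverse-site end; the SSR genotype is the largest product
(smaller products would be stutter candidates on a real gel).

## Alignment, consensus, SNP tables

The pairwise primitive is global Needleman–Wunsch with linear gap costs
(match +1, mismatch −1, gap −2), oracle-tested against an independent
full-matrix DP and against biopython's pairwise aligner.

The progressive aligner builds a UPGMA guide tree from pairwise
p-distances and merges profiles leaf-to-root, scoring a column pair by the
mean pairwise residue score (computed as a counts-matrix product) with a
numba DP kernel. Profile merges use **affine** gap costs (open −4, extend
−0.5) rather than the linear primitive. The reason is structural: under
linear gaps the optimum is a maximum-weight monotone matching in which
pairing two otherwise-gapped residues always pays, so whenever two
sequences each have an unmatched excess (different loci expanded in
different individuals), the optimizer scatters one locus's excess repeat
bases against the other's, manufacturing mismatch columns in insertion-only
pairs. No linear-gap parameterization avoids this while still preferring a
substitution over a double gap. The affine open cost suppresses
block-splitting, and locus-scale insertions stay contiguous — restoring
the property that noise-free same-population individuals align with zero
mismatch columns.

Consensus calling is column-wise: strict-majority base wins; a tie among
bases becomes the IUPAC code of the tied set (a "first-row base" policy is
available; either is defensible for consensus software, so both exist); a majority-gap column is excluded from the consensus residues but
kept in the position map. Rows under 80% identity to the consensus are
flagged, never dropped — the 80% figure is an alignment QC
threshold here, not an exclusion rule.

The SNP table reports every cross-consensus alignment column with ≥ 2
states (gaps count as states), 1-based in alignment coordinates,
which are self-consistent within a run (any external coordinate system
would depend on a different alignment). A
row is private when exactly one population differs from all others.

## Nei–Li diversity

`pi = n/(n−1) · Σ_{a≠b} X_a X_b pi_ab` over **ordered** pairs — the
convention is fixed by requiring that n = 2 with X = (½, ½) recovers
`pi_ab` itself. Within a population, entities are the distinct sequences
(identical sequences pool into one frequency class, X = count/n — the
documented default pooling rule); n is the number of samples. Between populations, entities are
the consensuses with equal weights 1/k. `pi_ab` excludes columns with `-`
or `N` in either sequence; two IUPAC letters count as a difference only
when their base sets are disjoint (configurable to strict letter
inequality). Similarity is `1 − pi_ab`; regional diversity restricts the
consensus set to each region's populations (consensus mode is the default;
an individuals mode would pool all of a region's samples). Percentages are
`pi × 100` to one decimal.

Because gap columns are excluded, copy-number variation is invisible to
`pi`: at noise 0 the within-population diversity is exactly 0, and under
the default noise it reflects the substitution rate only. This is a
property of the estimator, not a bug — the repeat polymorphism is carried
by the marker layer and the dRFLP patterns instead.

## Distances, tree, bootstrap

TN93 separates the two transition classes (A↔G, C↔T) from transversions,
with base frequencies estimated from the two sequences pooled and pairwise
deletion of gap/N columns; no gamma correction (plain "Tamura–Nei"). A
non-positive logarithm argument raises a saturation error. The
implementation agrees with an external reference implementation to 12
digits (frozen oracle value in the tests) and reduces to JC69 on an
equal-frequency, uniform-spectrum pair.

UPGMA is size-weighted average-linkage agglomeration; node height is half
the joined distance, so trees are rooted and ultrametric by construction;
ties break on the lexicographic order of the merged leaf-name sets.
Bootstrap support of an internal node is the percentage of
column-resampling replicates whose UPGMA tree contains the same leaf set
(default 1000 replicates); replicates with saturated distances are skipped
and the denominator adjusted. An invariant alignment yields zero distances
everywhere and the tie-broken topology at support 100 — degenerate but
deterministic.

## Restriction digestion and the dRFLP screen

Recognition sites match under IUPAC degeneracy on the enzyme side. For
ambiguity letters in a *consensus* sequence the default is strict: a site
matches only if every concrete resolution of the sequence letter does
(avoiding phantom bands from ambiguous calls); a permissive mode accepts
any shared resolution. Cut positions are single top-strand coordinates,
`match_start + cut_offset`; non-palindromic sites are also matched on the
reverse complement with the mirrored offset. Molecules are linear (the
cloned CR fragment is linear even though the mitogenome is circular). A
multi-enzyme digest cuts at the union of the single-digest cut sets.

One consequence of the single top-strand cut convention: for palindromic
enzymes with asymmetric cuts (EcoRI `G^AATTC`), reverse-complementing the
input shifts fragment boundaries by up to the overhang length — the
sticky-end ambiguity of real digests. Fragment multisets are therefore
exactly strand-invariant for non-palindromic and blunt cutters and
invariant within the overhang otherwise; the tests encode exactly that.

The default library is built from biopython's REBASE tables: commercial
type II enzymes with a single elucidated cut inside the recognition site,
deduplicated across isoschizomers by (site, offset) — 197 distinct
digestion specificities representing 500+ commercial enzymes, including
HpyCH4IV (`A^CGT`) and Tsp45I (`^GTSAC`). User tables load from TSV.

The gel model drops fragments below 50 bp and merges fragments whose
sorted-neighbour relative differences chain within r = 0.05 (transitive
closure) into one band at their mean — both parameters are documented
conventions standing in for a visual call on a 1.5% agarose gel. Two
patterns are distinguishable iff their band counts differ or any sorted
band pair differs by more than r. The screen digests every consensus with
every single enzyme and every pair, scores each set by the number of
population pairs distinguished, sorts by (score desc, set size asc, total
sites asc, name) and flags sets that separate all pairs. The gel renderer
places bands by an affine function of log10(length), ladder lane first.

## Marker statistics

Missing cells are imputed as half the marker's smallest observed positive
value (a common metabolomics-tool default), then rows are divided by their sum, ln-transformed with a
`1e-9·max` pseudo-value guarding zeros, and columns autoscaled (constant
columns stay at zero). Kruskal–Wallis uses mid-ranks with tie correction
and a chi-squared p on groups−1 df (delegated to scipy; the all-identical
case is reported as H = 0, p = 1 since the tie-correction denominator
vanishes). p-values are descriptive, matching a threshold-line
presentation; a Benjamini–Hochberg option exists but is off by default.

PLS-DA fits PLS2 (NIPALS, via scikit-learn) on the one-hot group matrix
with `min(5, n−1, p)` components by default;
`VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)` with
`SSY_a = (t_a·t_a)(q_a·q_a)`, so `Σ_j VIP_j² = p` identically. PCA is an
SVD of the autoscaled matrix, variance per component `σ_k²/Σσ²·100`, with
optional per-population mean scores. The top-marker ranking orders by
(−log10 p, then VIP) descending. VIP *ordering*, not its absolute values,
is the stable surface across component-count choices.

## Problem sizes

The default study set (53 individuals, 1.3–3.0 kb) is the scale every
result in the README and acceptance script is computed at: per-population
alignments and the cross-consensus alignment take ~20 s total (numba
kernels), the full 197-enzyme pair screen ~10 s, and 1000 bootstrap
replicates a few seconds. Property tests run at the draw counts stated in
their docstrings.

## Known limitations

- The progressive aligner has no iterative refinement; pathological guide
  trees could propagate early gap placements.
- The scanner's purity model is per-array, not per-window; long arrays
  with clustered noise can split into two summed hits.
- Digest patterns ignore methylation sensitivity, star activity and
  partial digestion; >2-enzyme combinations are configurable but not
  screened by default.
- Consensus-mode regional diversity weights populations, not samples; the
  individuals mode would differ when sample sizes are uneven.
- The simulator's emitted length range (~1.3–3.0 kb) is slightly wider
  than the 1112–2612 bp the emulated design targets: a length maximum
  that tight is not jointly consistent with a 74+-copy array plus a
  333-bp insertion on a single template, and the generator honours the
  copy range and private indels.
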