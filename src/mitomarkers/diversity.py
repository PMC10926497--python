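"""Nei & Li nucleotide diversity and the population similarity matrix.

The statistic is the classic heterozygosity-style estimator

    pi = (n / (n - 1)) * sum_{a != b} X_a X_b pi_ab

summed over ordered entity pairs (equivalently twice the sum over a < b),
where X_a is the estimated frequency of entity a and pi_ab the proportion
of differing comparable sites between entities a and b. The ordered-pair
convention is fixed by the two-sequence case: with n = 2 and X = (1/2,
1/2) the estimator must recover pi_ab itself.

Entities depend on the grouping. Within a population they are the
distinct sequences, each weighted by its sample count over n samples
(identical sequences pool into one frequency class). Between populations
they are the per-population consensus sequences with equal weights
1/(number of populations); the similarity matrix is 1 - pairwise pi.

Comparable columns exclude gaps and N on either sequence. When consensus
sequences carry IUPAC ambiguity calls, two letters count as a difference
only if their base sets are disjoint (W vs A overlap on A, so they match);
set ``ambiguity_overlap_matches=False`` to count any letter difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import Msa, PopulationConsensus, Scoring, call_consensus, progressive_msa
from .io_formats import PopulationSet
from .iupac import IUPAC_SETS

__all__ = [
    "DiversityInput",
    "NeiLiEstimate",
    "SimilarityMatrix",
    "proportion_diff",
    "nei_li_pi",
    "intra_population_pi",
    "inter_population_pi",
    "regional_pi",
    "diversity_report",
    "DiversityReport",
]


@dataclass(frozen=True)
class NeiLiEstimate:
    """Nucleotide diversity as a unitless proportion; percent view rounds
    to one decimal for reporting."""

    pi: float
    n: int

    @property
    def percent(self) -> float:
        return round(self.pi * 100.0, 1)


@dataclass
class DiversityInput:
    """n entities with frequencies X (summing to 1) and a symmetric
    zero-diagonal matrix of pairwise difference proportions."""

    n: int
    X: np.ndarray
    Pi: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Pi = np.asarray(self.Pi, dtype=float)
        k = self.X.shape[0]
        if self.Pi.shape != (k, k):
            raise ValueError("Pi must be square over the entities")
        if not np.isclose(self.X.sum(), 1.0):
            raise ValueError("entity frequencies must sum to 1")
        if not np.allclose(self.Pi, self.Pi.T) or np.any(np.diag(self.Pi) != 0):
            raise ValueError("Pi must be symmetric with zero diagonal")
        if self.n < 2:
            raise ValueError("need n >= 2 samples")


@dataclass
class SimilarityMatrix:
    """Pairwise population similarity, 1 - pi_ab, symmetric, unit diagonal."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix must be symmetric with unit diagonal")

    @property
    def populations(self) -> list[str]:
        return list(self.values.index)

    def extremes(self) -> tuple[tuple[str, str, float], tuple[str, str, float]]:
        """((pop, pop, max similarity), (pop, pop, min similarity)) over
        off-diagonal pairs."""
        best = worst = None
        for a, b in combinations(self.populations, 2):
            s = float(self.values.loc[a, b])
            if best is None or s > best[2]:
                best = (a, b, s)
            if worst is None or s < worst[2]:
                worst = (a, b, s)
        return best, worst

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")

    def edge_list(self) -> pd.DataFrame:
        """Long-form pairwise network edges (for the relationship plot)."""
        records = [
            {"a": a, "b": b, "similarity": float(self.values.loc[a, b])}
            for a, b in combinations(self.populations, 2)
        ]
        return pd.DataFrame.from_records(records)


def proportion_diff(a: str, b: str, *, ambiguity_overlap_matches: bool = True) -> float:
    """Proportion of differing comparable columns between two aligned
    sequences; columns with '-' or 'N' in either are excluded entirely."""
    a = a if isinstance(a, str) else a.residues
    b = b if isinstance(b, str) else b.residues
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal length)")
    comparable = 0
    diffs = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-N" or y in "-N":
            continue
        comparable += 1
        if x == y:
            continue
        if ambiguity_overlap_matches and (IUPAC_SETS[x] & IUPAC_SETS[y]):
            continue
        diffs += 1
    if comparable == 0:
        raise ValueError("no comparable columns")
    return diffs / comparable


def nei_li_pi(div_input: DiversityInput) -> NeiLiEstimate:
    """Evaluate pi = (n/(n-1)) * sum over ordered pairs of X_a X_b pi_ab."""
    X, Pi, n = div_input.X, div_input.Pi, div_input.n
    total = float(X @ Pi @ X)   # ordered-pair sum; diagonal is zero
    return NeiLiEstimate(pi=n / (n - 1) * total, n=n)


# ---------------------------------------------------------------------------
# Groupings

def intra_population_pi(seqs: Sequence, scoring: Scoring = Scoring(),
                        msa: Msa | None = None) -> NeiLiEstimate:
    """Within-population diversity over one population's individuals.

    Identical sequences pool into one entity with frequency count/n. A
    population whose individuals are all identical has pi = 0.
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if msa is None:
        msa = progressive_msa(list(seqs), scoring)
    classes: dict[str, list[str]] = {}
    for row in msa.rows:
        classes.setdefault(row.residues, []).append(row.id)
    reps = list(classes)
    if len(reps) == 1:
        return NeiLiEstimate(0.0, n)
    X = np.array([len(classes[r]) / n for r in reps])
    k = len(reps)
    Pi = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            Pi[i, j] = Pi[j, i] = proportion_diff(reps[i], reps[j])
    return nei_li_pi(DiversityInput(n, X, Pi))


def inter_population_pi(consensus_msa: Msa,
                        populations: Sequence[str] | None = None,
                        ) -> tuple[NeiLiEstimate, SimilarityMatrix]:
    """Between-population diversity over aligned consensus sequences,
    equally weighted, plus the pairwise similarity matrix."""
    rows = [r for r in consensus_msa.rows
            if populations is None or r.id in populations]
    names = [r.id for r in rows]
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 populations")
    Pi = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            Pi[i, j] = Pi[j, i] = proportion_diff(rows[i].residues, rows[j].residues)
    X = np.full(k, 1.0 / k)
    estimate = nei_li_pi(DiversityInput(k, X, Pi))
    sim = SimilarityMatrix(pd.DataFrame(1.0 - Pi, index=names, columns=names))
    return estimate, sim


def regional_pi(consensus_msa: Msa, region_map: Mapping[str, str],
                ) -> dict[str, NeiLiEstimate]:
    """Inter-population diversity restricted to each region's populations.

    Regions with fewer than 2 populations are rejected.
    """
    regions: dict[str, list[str]] = {}
    for pop, region in region_map.items():
        regions.setdefault(region, []).append(pop)
    out = {}
    for region, pops in regions.items():
        if len(pops) < 2:
            raise ValueError(f"region {region!r} has fewer than 2 populations")
        estimate, _ = inter_population_pi(consensus_msa, pops)
        out[region] = estimate
    return out


@dataclass
class DiversityReport:
    intra: dict[str, NeiLiEstimate]
    inter: NeiLiEstimate
    similarity: SimilarityMatrix
    regional: dict[str, NeiLiEstimate]
    consensus_msa: Msa = field(repr=False, default=None)
    population_msas: dict = field(repr=False, default_factory=dict)
    consensuses: dict = field(repr=False, default_factory=dict)


def diversity_report(pop_set: PopulationSet,
                     region_map: Mapping[str, str] | None = None,
                     scoring: Scoring = Scoring(),
                     tie_policy: str = "iupac") -> DiversityReport:
    """End-to-end diversity summary for a labelled sequence set.

    Aligns each population, calls consensuses, aligns the consensuses,
    and computes intra-, inter- and (optionally) regional diversity plus
    the similarity matrix.
    """
    population_msas: dict[str, Msa] = {}
    consensuses: dict[str, PopulationConsensus] = {}
    intra: dict[str, NeiLiEstimate] = {}
    for population, seqs in pop_set.items():
        if len(seqs) == 1:
            msa = progressive_msa(list(seqs), scoring)
            intra[population] = NeiLiEstimate(0.0, 1)
        else:
            msa = progressive_msa(list(seqs), scoring)
            intra[population] = intra_population_pi(seqs, scoring, msa=msa)
        population_msas[population] = msa
        consensuses[population] = call_consensus(msa, tie_policy, population)

    from .io_formats import LabeledSequence

    cons_seqs = [LabeledSequence(c.population, c.population, c.residues)
                 for c in consensuses.values()]
    consensus_msa = progressive_msa(cons_seqs, scoring)
    inter, similarity = inter_population_pi(consensus_msa)
    regional = (regional_pi(consensus_msa, region_map) if region_map else {})
    return DiversityReport(intra, inter, similarity, regional,
                           consensus_msa, population_msas, consensuses)
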