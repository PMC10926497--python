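"""Progressive multiple alignment, per-population consensus and SNP tables.

The aligner is a classic progressive scheme: global Needleman-Wunsch with
linear gap costs as the primitive, a UPGMA guide tree built from pairwise
p-distances, and profile-profile merges leaf-to-root where a column pair is
scored by the mean pairwise residue score. Defaults are match=+1,
mismatch=-1, gap=-2. Rows whose identity to the final consensus falls
below 80% are flagged (never dropped) — a QC signal, mirroring the
end-to-end-alignment identity floor used when assembling clone sequences.

Consensus calling is column-wise: a strict-majority base wins; a tie among
bases becomes the IUPAC ambiguity code of the tied set (configurable to
first-row base instead); a column that is majority gap is excluded from
the consensus residues but kept in the consensus-to-column map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .io_formats import LabeledSequence
from .iupac import ambiguity_code

__all__ = [
    "Scoring",
    "Msa",
    "PopulationConsensus",
    "SnpRow",
    "SnpTable",
    "pairwise_align",
    "progressive_msa",
    "call_consensus",
    "snp_table",
]

_SYMBOLS = "ACGTN-"
_INDEX = {c: i for i, c in enumerate(_SYMBOLS)}
_GAP = _INDEX["-"]
_N = _INDEX["N"]


@dataclass(frozen=True)
class Scoring:
    """Alignment scores. ``gap`` is the linear per-column cost used by the
    pairwise primitive; the progressive profile merges use the affine pair
    (``gap_open`` block surcharge + ``gap_extend`` per column), which keeps
    locus-scale insertions as contiguous blocks instead of letting the
    optimizer scatter one locus's excess repeat bases against another's."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -0.5

    def matrix(self) -> np.ndarray:
        S = np.full((6, 6), self.mismatch)
        for i in range(4):
            S[i, i] = self.match
        S[_N, :] = 0.0
        S[:, _N] = 0.0
        S[_GAP, :] = self.gap
        S[:, _GAP] = self.gap
        S[_GAP, _GAP] = 0.0
        S[_N, _GAP] = S[_GAP, _N] = self.gap
        return S


@dataclass
class Msa:
    """A multiple alignment: equal-length gapped rows in a fixed order.

    ``low_identity`` lists row ids whose identity to the consensus is
    below the QC floor (flagged, not removed).
    """

    rows: list[LabeledSequence]
    low_identity: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(r.residues) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].residues) if self.rows else 0

    def ungapped(self, row_id: str) -> str:
        for r in self.rows:
            if r.id == row_id:
                return r.residues.replace("-", "")
        raise KeyError(row_id)

    def column(self, j: int) -> list[str]:
        return [r.residues[j] for r in self.rows]


@dataclass
class PopulationConsensus:
    population: str
    residues: str
    support: list[float]          # per consensus position, in (0, 1]
    column_map: list[int]         # consensus position -> MSA column

    @property
    def id(self) -> str:  # lets consensuses act as plain sequences downstream
        return self.population

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SnpRow:
    column: int                   # 1-based MSA column
    states: dict
    private: bool
    private_population: str | None


@dataclass
class SnpTable:
    populations: list[str]
    rows: list[SnpRow]

    def __len__(self) -> int:
        return len(self.rows)

    def private_rows(self) -> list[SnpRow]:
        return [r for r in self.rows if r.private]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("column\t" + "\t".join(self.populations)
                     + "\tprivate\tprivate_population\n")
            for row in self.rows:
                states = "\t".join(row.states[p] for p in self.populations)
                fh.write(f"{row.column}\t{states}\t{int(row.private)}\t"
                         f"{row.private_population or ''}\n")


# ---------------------------------------------------------------------------
# Needleman-Wunsch over profiles

@njit(cache=True)
def _nw_pointers(S: np.ndarray, gap_a: np.ndarray,
                 gap_b: np.ndarray) -> np.ndarray:  # pragma: no cover - numba
    la, lb = S.shape
    H = np.empty((la + 1, lb + 1))
    P = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    H[0, 0] = 0.0
    for i in range(1, la + 1):
        H[i, 0] = H[i - 1, 0] + gap_a[i - 1]
        P[i, 0] = 1
    for j in range(1, lb + 1):
        H[0, j] = H[0, j - 1] + gap_b[j - 1]
        P[0, j] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            up = H[i - 1, j] + gap_a[i - 1]
            left = H[i, j - 1] + gap_b[j - 1]
            best = diag
            ptr = 0
            if up > best:
                best = up
                ptr = 1
            if left > best:
                best = left
                ptr = 2
            H[i, j] = best
            P[i, j] = ptr
    return P


@njit(cache=True)
def _gotoh_pointers(S: np.ndarray, ext_a: np.ndarray, ext_b: np.ndarray,
                    open_cost: float):  # pragma: no cover - numba
    """Affine-gap DP (three-state Gotoh). Returns the three pointer
    matrices and the best final state."""
    la, lb = S.shape
    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)   # gap in B, consuming A
    Y = np.full((la + 1, lb + 1), NEG)   # gap in A, consuming B
    pM = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    pX = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    pY = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    if la > 0:
        X[1, 0] = open_cost + ext_a[0]
        pX[1, 0] = 0
        for i in range(2, la + 1):
            X[i, 0] = X[i - 1, 0] + ext_a[i - 1]
            pX[i, 0] = 1
    if lb > 0:
        Y[0, 1] = open_cost + ext_b[0]
        pY[0, 1] = 0
        for j in range(2, lb + 1):
            Y[0, j] = Y[0, j - 1] + ext_b[j - 1]
            pY[0, j] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            # M: consume one column of each
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + S[i - 1, j - 1]
            pM[i, j] = ptr
            # X: A column against gap
            stay = X[i - 1, j] + ext_a[i - 1]
            fresh = max(M[i - 1, j], Y[i - 1, j]) + open_cost + ext_a[i - 1]
            if stay >= fresh:
                X[i, j] = stay
                pX[i, j] = 1
            else:
                X[i, j] = fresh
                pX[i, j] = 0 if M[i - 1, j] >= Y[i - 1, j] else 2
            # Y: B column against gap
            stay = Y[i, j - 1] + ext_b[j - 1]
            fresh = max(M[i, j - 1], X[i, j - 1]) + open_cost + ext_b[j - 1]
            if stay >= fresh:
                Y[i, j] = stay
                pY[i, j] = 2
            else:
                Y[i, j] = fresh
                pY[i, j] = 0 if M[i, j - 1] >= X[i, j - 1] else 1
    end_state = 0
    best = M[la, lb]
    if X[la, lb] > best:
        best = X[la, lb]
        end_state = 1
    if Y[la, lb] > best:
        best = Y[la, lb]
        end_state = 2
    return pM, pX, pY, end_state, best


def _encode(profile_rows: list[str]) -> np.ndarray:
    """Per-column symbol counts (n_cols x 6) of a gapped profile."""
    n_cols = len(profile_rows[0])
    counts = np.zeros((n_cols, 6), dtype=np.float64)
    for row in profile_rows:
        arr = np.frombuffer(row.encode(), dtype=np.uint8)
        for sym, idx in _INDEX.items():
            counts[arr == ord(sym), idx] += 1
        known = np.isin(arr, np.frombuffer(_SYMBOLS.encode(), dtype=np.uint8))
        counts[~known, _N] += 1   # any other ambiguity letter scores like N
    return counts


def _align_profiles(rows_a: list[str], rows_b: list[str],
                    scoring: Scoring) -> tuple[list[str], list[str], float]:
    """Globally align two profiles; returns gap-extended row sets and the
    alignment score."""
    ca, cb = _encode(rows_a), _encode(rows_b)
    ra, rb = len(rows_a), len(rows_b)
    S = scoring.matrix()
    pair = (ca @ S @ cb.T) / (ra * rb)
    gap_col = S[:, _GAP]
    gap_a = (ca @ gap_col) / ra
    gap_b = (cb @ gap_col) / rb
    P = _nw_pointers(pair, gap_a, gap_b)

    i, j = len(rows_a[0]), len(rows_b[0])
    ops: list[int] = []
    while i > 0 or j > 0:
        ptr = P[i, j]
        ops.append(ptr)
        if ptr == 0:
            i, j = i - 1, j - 1
        elif ptr == 1:
            i -= 1
        else:
            j -= 1
    ops.reverse()

    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    score = 0.0
    for ptr in ops:
        if ptr == 0:
            for k, row in enumerate(rows_a):
                out_a[k].append(row[ia])
            for k, row in enumerate(rows_b):
                out_b[k].append(row[ib])
            score += pair[ia, ib]
            ia += 1
            ib += 1
        elif ptr == 1:
            for k, row in enumerate(rows_a):
                out_a[k].append(row[ia])
            for k in range(len(rows_b)):
                out_b[k].append("-")
            score += gap_a[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append("-")
            for k, row in enumerate(rows_b):
                out_b[k].append(row[ib])
            score += gap_b[ib]
            ib += 1
    return (["".join(r) for r in out_a], ["".join(r) for r in out_b], score)


def _apply_ops(ops: list[int], rows_a: list[str], rows_b: list[str]
               ) -> tuple[list[str], list[str]]:
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for ptr in ops:
        if ptr == 0:
            for k, row in enumerate(rows_a):
                out_a[k].append(row[ia])
            for k, row in enumerate(rows_b):
                out_b[k].append(row[ib])
            ia += 1
            ib += 1
        elif ptr == 1:
            for k, row in enumerate(rows_a):
                out_a[k].append(row[ia])
            for k in range(len(rows_b)):
                out_b[k].append("-")
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append("-")
            for k, row in enumerate(rows_b):
                out_b[k].append(row[ib])
            ib += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _align_profiles_affine(rows_a: list[str], rows_b: list[str],
                           scoring: Scoring
                           ) -> tuple[list[str], list[str], float]:
    """Affine-gap (Gotoh) global profile-profile alignment."""
    ca, cb = _encode(rows_a), _encode(rows_b)
    ra, rb = len(rows_a), len(rows_b)
    S = scoring.matrix()
    pair = (ca @ S @ cb.T) / (ra * rb)
    nongap_a = 1.0 - ca[:, _GAP] / ra
    nongap_b = 1.0 - cb[:, _GAP] / rb
    ext_a = scoring.gap_extend * nongap_a
    ext_b = scoring.gap_extend * nongap_b
    pM, pX, pY, state, score = _gotoh_pointers(pair, ext_a, ext_b,
                                               scoring.gap_open)
    i, j = len(rows_a[0]), len(rows_b[0])
    ops: list[int] = []
    while i > 0 or j > 0:
        if state == 0:
            ops.append(0)
            state = pM[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append(1)
            state = pX[i, j]
            i -= 1
        else:
            ops.append(2)
            state = pY[i, j]
            j -= 1
    ops.reverse()
    out_a, out_b = _apply_ops(ops, rows_a, rows_b)
    return out_a, out_b, float(score)


def pairwise_align(a: LabeledSequence | str, b: LabeledSequence | str,
                   scoring: Scoring = Scoring()) -> tuple[Msa, float]:
    """Optimal global pairwise alignment under linear gap costs.

    Returns the two-row alignment and the identity fraction
    (identical non-gap column pairs / alignment columns).
    """
    sa = a if isinstance(a, str) else a.residues
    sb = b if isinstance(b, str) else b.residues
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    rows_a, rows_b, _ = _align_profiles([sa], [sb], scoring)
    ga, gb = rows_a[0], rows_b[0]
    matches = sum(x == y and x != "-" for x, y in zip(ga, gb))
    identity = matches / len(ga)
    id_a = getattr(a, "id", "a")
    id_b = getattr(b, "id", "b")
    pop_a = getattr(a, "population", "-")
    pop_b = getattr(b, "population", "-")
    msa = Msa([LabeledSequence(id_a, pop_a, ga, aligned=True),
               LabeledSequence(id_b, pop_b, gb, aligned=True)])
    return msa, identity


def alignment_score(a: str, b: str, scoring: Scoring = Scoring()) -> float:
    """Optimal global alignment score of two plain sequences."""
    _, _, score = _align_profiles([a], [b], scoring)
    return round(score, 9)


def progressive_msa(seqs: list[LabeledSequence],
                    scoring: Scoring = Scoring(),
                    identity_floor: float = 0.8) -> Msa:
    """Progressive multiple alignment guided by a UPGMA tree on pairwise
    p-distances; rows below ``identity_floor`` identity to the consensus
    are flagged in ``low_identity``."""
    from .phylo import upgma

    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        s = seqs[0]
        return Msa([LabeledSequence(s.id, s.population, s.residues, aligned=True)])

    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rows_a, rows_b, _ = _align_profiles_affine(
                [seqs[i].residues], [seqs[j].residues], scoring)
            ga, gb = rows_a[0], rows_b[0]
            identity = sum(x == y and x != "-" for x, y in zip(ga, gb)) / len(ga)
            D[i, j] = D[j, i] = 1.0 - identity
    tree = upgma(D, labels=[str(i) for i in range(n)])

    def merge(node) -> dict[str, str]:
        if node.is_leaf:
            k = int(node.name)
            return {seqs[k].id: seqs[k].residues}
        profiles = [merge(child) for child in node.children]
        acc = profiles[0]
        for other in profiles[1:]:
            ids_a, ids_b = list(acc), list(other)
            rows_a, rows_b, _ = _align_profiles_affine(
                [acc[i] for i in ids_a], [other[i] for i in ids_b], scoring)
            acc = dict(zip(ids_a, rows_a)) | dict(zip(ids_b, rows_b))
        return acc

    aligned = merge(tree.root)
    rows = [LabeledSequence(s.id, s.population, aligned[s.id], aligned=True)
            for s in seqs]
    msa = Msa(rows)
    consensus = call_consensus(msa, population="_tmp")
    flagged = []
    for row in rows:
        matches = sum(
            row.residues[col] == consensus.residues[k]
            for k, col in enumerate(consensus.column_map))
        if matches / msa.n_columns < identity_floor:
            flagged.append(row.id)
    msa.low_identity = flagged
    return msa


def call_consensus(msa: Msa, tie_policy: str = "iupac",
                   population: str | None = None) -> PopulationConsensus:
    """Column-wise consensus of an alignment (see module docstring for the
    majority / tie / gap rules)."""
    if not msa.rows:
        raise ValueError("empty alignment")
    n_rows = len(msa.rows)
    name = population or msa.rows[0].population
    residues: list[str] = []
    support: list[float] = []
    column_map: list[int] = []
    for j in range(msa.n_columns):
        col = msa.column(j)
        gaps = col.count("-")
        if gaps * 2 > n_rows:
            continue   # majority-gap column: excluded from the consensus
        counts: dict[str, int] = {}
        for c in col:
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        top = max(counts.values())
        winners = sorted(c for c, k in counts.items() if k == top)
        if len(winners) == 1:
            base = winners[0]
            support.append(top / n_rows)
        elif tie_policy == "first":
            base = next(c for c in col if c in winners)
            support.append(top / n_rows)
        else:
            concrete: set[str] = set()
            for w in winners:
                concrete |= {w} if w in "ACGT" else {"A", "C", "G", "T"}
            base = ambiguity_code(frozenset(concrete & {"A", "C", "G", "T"}))
            support.append(top * len(winners) / n_rows)
        residues.append(base)
        column_map.append(j)
    return PopulationConsensus(name, "".join(residues), support, column_map)


def snp_table(consensus_msa: Msa) -> SnpTable:
    """Variant table across aligned population consensuses: one row per
    column with >= 2 distinct states (gaps count as states); a row is
    private when exactly one population differs from all the others."""
    populations = [r.id for r in consensus_msa.rows]
    rows: list[SnpRow] = []
    for j in range(consensus_msa.n_columns):
        col = consensus_msa.column(j)
        if len(set(col)) < 2:
            continue
        states = dict(zip(populations, col))
        private = False
        private_pop = None
        for k, pop in enumerate(populations):
            others = col[:k] + col[k + 1:]
            if len(set(others)) == 1 and others[0] != col[k]:
                private = True
                private_pop = pop
                break
        rows.append(SnpRow(j + 1, states, private, private_pop))
    return SnpTable(populations, rows)
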