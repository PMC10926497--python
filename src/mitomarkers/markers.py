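"""Tandem-repeat detection, copy-number quantification and in silico PCR.

The scanner is a run-length periodicity test: for each candidate period p
it marks positions i where seq[i] == seq[i-p] and extracts maximal
positive-scoring segments under the weighting (match = +1, mismatch =
-(1/eps - 1)), which is exactly the set of maximal runs whose overall
mismatch fraction stays at or below eps while never extending through a
locally hopeless stretch. Overlapping hits across periods are resolved by
span (longer wins; ties go to the smaller period). This is deliberately
simpler than alignment-based repeat finders: no wraparound alignment and
no probabilistic score model, which is sufficient for faithful copy-number
quantification on arrays of the purity this pipeline deals with.

Copy numbers are reported to one decimal, matching the convention of
reporting fractional iterations such as 74.4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .io_formats import LabeledSequence, MarkerTable, PopulationSet
from .iupac import reverse_complement

__all__ = [
    "TandemRepeatHit",
    "ScanParams",
    "PrimerPair",
    "scan_tandem_repeats",
    "quantify_locus",
    "in_silico_pcr",
    "build_marker_matrix",
]


@dataclass(frozen=True)
class TandemRepeatHit:
    """One tandem array: [start, end) span, period, fractional copy number,
    majority consensus motif and purity (fraction of in-phase matches)."""

    sequence_id: str
    start: int
    end: int
    period: int
    copy_number: float
    consensus_motif: str
    purity: float

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ScanParams:
    min_period: int = 2
    max_period: int = 50
    min_copies: float = 2.0
    max_mismatch_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 2 <= self.min_period <= self.max_period:
            raise ValueError("need 2 <= min_period <= max_period")
        if not 0 <= self.max_mismatch_fraction < 0.5:
            raise ValueError("max_mismatch_fraction must be in [0, 0.5)")


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, each written 5'->3' on its own strand."""

    forward: str
    reverse: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())
        if len(self.forward) < 10 or len(self.reverse) < 10:
            raise ValueError("primers must be at least 10 bases")


@njit(cache=True)
def _max_segments(match: np.ndarray, penalty: float,
                  out: np.ndarray) -> int:  # pragma: no cover - numba
    """Maximal positive-scoring segments of a 0/1 array (match=+1,
    mismatch=-penalty). Writes (start, end) pairs into ``out``; returns
    the count. Segments end at their running-maximum position, so they
    always begin and end on matches."""
    n = match.shape[0]
    count = 0
    i = 0
    while i < n:
        if match[i] == 0:
            i += 1
            continue
        score = 0.0
        best = 0.0
        best_end = i
        start = i
        j = i
        while j < n:
            if match[j] == 1:
                score += 1.0
            else:
                score -= penalty
            if score > best:
                best = score
                best_end = j
            if score < 0.0:
                break
            j += 1
        out[count, 0] = start
        out[count, 1] = best_end + 1
        count += 1
        i = best_end + 1
        if j >= n:
            break
        if j > best_end:
            i = j + 1
    return count


def _smallest_period(motif: str, eps: float = 0.0) -> int:
    """Smallest q such that the motif is q-periodic up to a mismatch
    fraction of eps (eps 0 = exact). Only q <= len/2 can demonstrate
    repetition; anything larger is the motif's own length."""
    m = len(motif)
    for q in range(1, m // 2 + 1):
        mism = sum(motif[i] != motif[i - q] for i in range(q, m))
        if mism <= eps * (m - q):
            return q
    return m


def _majority_motif(region: np.ndarray, period: int) -> str:
    """Column-majority consensus over the p phases of an array region."""
    motif = []
    for phase in range(period):
        col = region[phase::period]
        values, counts = np.unique(col, return_counts=True)
        motif.append(chr(values[np.argmax(counts)]))
    return "".join(motif)


def scan_tandem_repeats(seq: LabeledSequence | str,
                        params: ScanParams = ScanParams()) -> list[TandemRepeatHit]:
    """All tandem arrays in an unaligned sequence, longest-span first."""
    residues = seq if isinstance(seq, str) else seq.residues
    seq_id = getattr(seq, "id", "seq")
    arr = np.frombuffer(residues.encode(), dtype=np.uint8)
    n = arr.shape[0]
    eps = params.max_mismatch_fraction
    penalty = (1.0 / eps - 1.0) if eps > 0 else float(n + 1)

    raw: list[TandemRepeatHit] = []
    out = np.empty((max(n, 1), 2), dtype=np.int64)
    for period in range(params.min_period, min(params.max_period, n - 1) + 1):
        match = (arr[period:] == arr[:-period]).astype(np.uint8)
        count = _max_segments(match, penalty, out)
        for k in range(count):
            s, e = int(out[k, 0]), int(out[k, 1])
            # match index i refers to seq position i+period
            start, end = s, e + period
            span = end - start
            if span < period * params.min_copies:
                continue
            copy_number = round(span / period, 1)
            if copy_number < params.min_copies:
                continue
            region = arr[start:end]
            matches = int(match[s:e].sum())
            purity = matches / (span - period) if span > period else 1.0
            motif = _majority_motif(region, period)
            # a run whose motif is itself (approximately) periodic belongs
            # to the smaller period: homopolymers seen at period 2 are not
            # tandem repeats at all, and composite hits at period multiples
            # (e.g. 2x21) would otherwise outspan the base-period hit
            if _smallest_period(motif, eps) < period:
                continue
            raw.append(TandemRepeatHit(seq_id, start, end, period, copy_number,
                                       motif, purity))

    raw.sort(key=lambda h: (-h.span, h.period, h.start))
    kept: list[TandemRepeatHit] = []
    for hit in raw:
        if all(hit.end <= other.start or hit.start >= other.end for other in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.start)
    return kept


def _rotations(motif: str) -> list[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def _motif_matches(consensus: str, query: str, max_mismatch: int = 1) -> bool:
    """Equality up to cyclic rotation and <= max_mismatch substitutions."""
    if len(consensus) != len(query):
        return False
    for rot in _rotations(query):
        if sum(a != b for a, b in zip(consensus, rot)) <= max_mismatch:
            return True
    return False


def quantify_locus(hits: list[TandemRepeatHit], motif: str) -> float:
    """Copy number of the array whose consensus motif matches ``motif``
    (cyclic rotation, <=1 mismatch); 0.0 if absent. Two matching arrays in
    one sequence sum, with a warning."""
    if not motif:
        raise ValueError("empty query motif")
    matching = [h for h in hits if _motif_matches(h.consensus_motif, motif.upper())]
    if not matching:
        return 0.0
    if len(matching) > 1:
        warnings.warn(
            f"{matching[0].sequence_id}: {len(matching)} arrays match motif "
            f"{motif!r}; reporting their summed copy number", stacklevel=2)
    return round(sum(h.copy_number for h in matching), 1)


def _primer_sites(template: str, primer: str, max_mismatches: int) -> list[int]:
    """Start positions where ``primer`` matches with <= max_mismatches
    (Hamming; primer sites are short and indel-free here)."""
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    n, m = t.shape[0], p.shape[0]
    if n < m:
        return []
    if max_mismatches == 0:
        # exact search via string find
        sites, at = [], template.find(primer)
        while at != -1:
            sites.append(at)
            at = template.find(primer, at + 1)
        return sites
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mism = (windows != p).sum(axis=1)
    return list(np.nonzero(mism <= max_mismatches)[0])


def in_silico_pcr(seq: LabeledSequence | str, primers: PrimerPair) -> list[int]:
    """Predicted amplicon lengths for a primer pair on a linear template.

    The forward primer anneals on one strand, the reverse-complement of the
    reverse primer downstream of it; length runs from the start of the
    forward site to the end of the reverse site. Both template strands are
    scanned; no inverted (reverse-before-forward) products.
    """
    template = (seq if isinstance(seq, str) else seq.residues).upper()
    products: set[int] = set()
    for strand in (template, reverse_complement(template)):
        fwd_sites = _primer_sites(strand, primers.forward, primers.max_mismatches)
        rev_rc = reverse_complement(primers.reverse)
        rev_sites = _primer_sites(strand, rev_rc, primers.max_mismatches)
        for f in fwd_sites:
            for r in rev_sites:
                if r >= f + len(primers.forward):
                    products.add(r + len(rev_rc) - f)
    return sorted(products)


def build_marker_matrix(pop_set: PopulationSet,
                        tr_motifs: dict[str, str],
                        primer_pairs: dict[str, PrimerPair] | None = None,
                        params: ScanParams = ScanParams()) -> MarkerTable:
    """Sample x marker table: TR columns hold copy numbers (0.0 when the
    array is absent), SSR columns the largest amplicon length in bp
    (missing when no product; shorter extra products are discarded as
    stutter)."""
    if len(pop_set) == 0 or (not tr_motifs and not primer_pairs):
        raise ValueError("need at least one sequence and one marker")
    primer_pairs = primer_pairs or {}
    columns = list(tr_motifs) + list(primer_pairs)
    rows, groups, ids = [], [], []
    for seq in pop_set:
        hits = scan_tandem_repeats(seq, params)
        row = [quantify_locus(hits, motif) for motif in tr_motifs.values()]
        for pair in primer_pairs.values():
            amplicons = in_silico_pcr(seq, pair)
            row.append(float(amplicons[-1]) if amplicons else np.nan)
        rows.append(row)
        groups.append(seq.population)
        ids.append(seq.id)
    values = pd.DataFrame(rows, index=pd.Index(ids, name="sample"), columns=columns)
    return MarkerTable(values, pd.Series(groups, index=values.index, name="group"))
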