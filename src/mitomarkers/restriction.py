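"""In silico restriction digestion and the dRFLP discrimination screen.

A digital RFLP (dRFLP) replaces the wet-lab digest: recognition sites are
located computationally, the linear molecule is fragmented at the union of
all cut positions, and the fragment multiset is reduced to the bands a
1.5% agarose gel would resolve. Screening every single enzyme and every
enzyme pair against a set of population consensus sequences then finds the
smallest enzyme set whose band patterns uniquely identify each population.

Sequences are treated as linear molecules (the cloned Control Region
fragment is linear even though the mitogenome is circular). Cut positions
are reported on the top strand; for non-palindromic sites the reverse
strand is scanned too, with the mirrored offset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .iupac import IUPAC_SETS, reverse_complement

__all__ = [
    "EnzymeDefinition",
    "DigestPattern",
    "GelModel",
    "find_sites",
    "digest",
    "visible_bands",
    "distinguishable",
    "screen_enzymes",
    "render_gel",
    "ScreenEntry",
]


@dataclass(frozen=True)
class EnzymeDefinition:
    """A type II restriction enzyme: name, IUPAC recognition site, and the
    cut offset in bases from the site start on the top strand."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.site.upper()
        object.__setattr__(self, "site", site)
        bad = set(site) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC letters {sorted(bad)} in site")
        if len(site) < 4:
            raise ValueError(f"{self.name}: recognition site shorter than 4 bp")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(
                f"{self.name}: cut offset {self.cut_offset} outside site of "
                f"length {len(site)}")

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.site) == self.site


@dataclass(frozen=True)
class GelModel:
    """Resolution model for a simulated agarose gel.

    Fragments below ``min_detectable_bp`` run off or stain too faintly to
    score; fragments within relative length tolerance ``resolution`` of one
    another co-migrate and merge into a single band.
    """

    min_detectable_bp: int = 50
    resolution: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.resolution < 0.5:
            raise ValueError("gel resolution must be in (0, 0.5)")
        if self.min_detectable_bp < 1:
            raise ValueError("min_detectable_bp must be >= 1")


@dataclass(frozen=True)
class DigestPattern:
    """Fragment lengths (bp, multiset stored sorted) of one linear digest."""

    source_id: str
    enzymes: tuple[str, ...]
    fragments: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragments", tuple(sorted(self.fragments)))
        if any(f < 1 for f in self.fragments):
            raise ValueError("zero-length fragment in digest pattern")

    @property
    def total_length(self) -> int:
        return sum(self.fragments)


def _residues(seq) -> str:
    return seq if isinstance(seq, str) else seq.residues


def _site_regex(site: str, ambiguous_sequence: str) -> re.Pattern:
    """Regex matching the IUPAC site against a sequence that may itself
    contain ambiguity letters.

    strict mode: a sequence letter matches only if every one of its
    resolutions does (its base set is a subset of the site letter's).
    permissive mode: any shared resolution suffices (sets intersect).
    """
    parts = []
    for s in site:
        sset = IUPAC_SETS[s]
        if ambiguous_sequence == "strict":
            allowed = [c for c, cset in IUPAC_SETS.items() if cset <= sset]
        else:
            allowed = [c for c, cset in IUPAC_SETS.items() if cset & sset]
        parts.append("[" + "".join(sorted(allowed)) + "]")
    # lookahead so overlapping occurrences are all found
    return re.compile("(?=" + "".join(parts) + ")")


def find_sites(seq, enzyme: EnzymeDefinition, *,
               ambiguity: str = "strict") -> list[int]:
    """Sorted top-strand cut positions of ``enzyme`` in ``seq``.

    The given strand contributes ``match_start + cut_offset`` per site
    occurrence; for non-palindromic sites the reverse complement of the
    site is also matched, contributing the mirrored offset
    ``match_start + len(site) - cut_offset``.

    ``ambiguity`` governs IUPAC letters in the *sequence* (consensus
    calls): ``"strict"`` requires every resolution to match, ``"permissive"``
    any resolution.
    """
    residues = _residues(seq).upper()
    site = enzyme.site
    cuts: set[int] = set()
    for m in _site_regex(site, ambiguity).finditer(residues):
        cuts.add(m.start() + enzyme.cut_offset)
    if not enzyme.is_palindromic:
        rc_site = reverse_complement(site)
        mirrored = len(site) - enzyme.cut_offset
        for m in _site_regex(rc_site, ambiguity).finditer(residues):
            cuts.add(m.start() + mirrored)
    return sorted(c for c in cuts if 0 <= c <= len(residues))


def digest(seq, enzymes: Iterable[EnzymeDefinition], *,
           ambiguity: str = "strict",
           cut_cache: dict | None = None) -> DigestPattern:
    """Digest a linear sequence with one or more enzymes simultaneously.

    The cut set of a multi-enzyme (double) digest is the union of the
    single digests; duplicate positions collapse. No sites at all yields a
    single full-length fragment.
    """
    enzymes = list(enzymes)
    if not enzymes:
        raise ValueError("digest needs at least one enzyme")
    residues = _residues(seq).upper()
    seq_id = getattr(seq, "id", None) or getattr(seq, "population", None) or "seq"
    cuts: set[int] = set()
    for enz in enzymes:
        if cut_cache is not None:
            key = (id(seq), enz.name)
            if key not in cut_cache:
                cut_cache[key] = find_sites(residues, enz, ambiguity=ambiguity)
            cuts.update(cut_cache[key])
        else:
            cuts.update(find_sites(residues, enz, ambiguity=ambiguity))
    bounds = sorted({0, len(residues)} | cuts)
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]) if b > a)
    return DigestPattern(seq_id, tuple(sorted(e.name for e in enzymes)), fragments)


def visible_bands(pattern: DigestPattern, gel: GelModel = GelModel()) -> list[float]:
    """Bands a gel of the given resolution would show, sorted ascending.

    Fragments below the detection floor are dropped; fragments whose
    pairwise relative difference chains within ``gel.resolution``
    (transitive closure) merge into one band at their mean length.
    """
    frags = sorted(f for f in pattern.fragments if f >= gel.min_detectable_bp)
    bands: list[float] = []
    i = 0
    while i < len(frags):
        j = i + 1
        while j < len(frags) and (frags[j] - frags[j - 1]) / frags[j] <= gel.resolution:
            j += 1
        bands.append(float(np.mean(frags[i:j])))
        i = j
    return bands


def distinguishable(pattern_a: DigestPattern, pattern_b: DigestPattern,
                    gel: GelModel = GelModel()) -> bool:
    """Whether two digests would look different on the modelled gel."""
    a = visible_bands(pattern_a, gel)
    b = visible_bands(pattern_b, gel)
    if len(a) != len(b):
        return True
    for x, y in zip(a, b):
        if abs(x - y) / max(x, y) > gel.resolution:
            return True
    return False


@dataclass(frozen=True)
class ScreenEntry:
    """One candidate enzyme set from the discrimination screen."""

    enzymes: tuple[str, ...]
    score: int                # population pairs distinguished
    n_pairs: int              # total population pairs
    total_sites: int
    full_discrimination: bool
    patterns: tuple[DigestPattern, ...] = field(repr=False, default=())


def screen_enzymes(consensuses: Sequence, library: Sequence[EnzymeDefinition],
                   gel: GelModel = GelModel(), max_set_size: int = 2, *,
                   ambiguity: str = "strict") -> list[ScreenEntry]:
    """Screen single enzymes and enzyme pairs for population discrimination.

    Each candidate set digests every consensus; its score is the number of
    population pairs whose gel patterns differ. Results are sorted by
    (score desc, set size asc, total cut sites asc, name); sets that
    separate every pair are flagged ``full_discrimination``.
    """
    if not library:
        raise ValueError("empty enzyme library")
    if not 1 <= max_set_size <= 2:
        raise ValueError("max_set_size must be 1 or 2")
    if len(consensuses) < 2:
        raise ValueError("need at least two consensus sequences to screen")

    names = []
    residues = []
    for cons in consensuses:
        names.append(getattr(cons, "population", None) or getattr(cons, "id", "seq"))
        residues.append(_residues(cons).upper())

    # single-digest cut sets, computed once
    cut_sets = {
        enz.name: [np.asarray(find_sites(r, enz, ambiguity=ambiguity), dtype=np.int64)
                   for r in residues]
        for enz in library
    }

    def patterns_for(enz_names: tuple[str, ...]) -> list[DigestPattern]:
        pats = []
        for k, (pop, r) in enumerate(zip(names, residues)):
            cuts = cut_sets[enz_names[0]][k]
            for extra in enz_names[1:]:
                cuts = np.union1d(cuts, cut_sets[extra][k])
            bounds = np.concatenate(([0], cuts[(cuts > 0) & (cuts < len(r))], [len(r)]))
            bounds = np.unique(bounds)
            frags = tuple(int(f) for f in np.diff(bounds))
            pats.append(DigestPattern(pop, enz_names, frags))
        return pats

    n_pairs = len(names) * (len(names) - 1) // 2
    candidates: list[tuple[str, ...]] = [(e.name,) for e in library]
    if max_set_size >= 2:
        candidates += [tuple(sorted((a.name, b.name)))
                       for a, b in combinations(library, 2)]

    entries: list[ScreenEntry] = []
    for cand in candidates:
        pats = patterns_for(cand)
        bands = [visible_bands(p, gel) for p in pats]
        score = 0
        for i, j in combinations(range(len(pats)), 2):
            bi, bj = bands[i], bands[j]
            if len(bi) != len(bj) or any(
                    abs(x - y) / max(x, y) > gel.resolution for x, y in zip(bi, bj)):
                score += 1
        total_sites = sum(len(cut_sets[n][k]) for n in cand for k in range(len(names)))
        entries.append(ScreenEntry(cand, score, n_pairs, total_sites,
                                   score == n_pairs, tuple(pats)))
    entries.sort(key=lambda e: (-e.score, len(e.enzymes), e.total_sites, e.enzymes))
    return entries


def render_gel(patterns: Sequence[DigestPattern], gel: GelModel = GelModel(),
               *, width: int = 60, rows: int = 24,
               ladder: Sequence[int] = (100, 250, 500, 1000, 1500, 2000, 3000),
               path: str | None = None) -> str:
    """Plain-text rendering of a simulated agarose gel.

    Lanes appear in the order given, after a ladder lane; band height is an
    affine function of log10(length), large fragments at the top. If
    ``path`` is given, a PNG is also written with matplotlib.
    """
    if not patterns:
        raise ValueError("render_gel needs at least one pattern")
    lanes = [("ladder", [float(x) for x in ladder])]
    lanes += [(p.source_id, visible_bands(p, gel)) for p in patterns]
    all_bands = [b for _, bands in lanes for b in bands]
    lo = np.log10(min(all_bands + [gel.min_detectable_bp]))
    hi = np.log10(max(all_bands + [1]) * 1.05)

    def row_of(length: float) -> int:
        # top of the gel = largest fragment
        frac = (np.log10(length) - lo) / (hi - lo) if hi > lo else 0.5
        return int(round((1 - frac) * (rows - 1)))

    lane_w = max(8, width // max(1, len(lanes)))
    grid = [[" " * lane_w for _ in lanes] for _ in range(rows)]
    for k, (_, bands) in enumerate(lanes):
        for b in bands:
            r = min(rows - 1, max(0, row_of(b)))
            grid[r][k] = "=" * lane_w
    header = "".join(name[:lane_w].center(lane_w) for name, _ in lanes)
    text = header + "\n" + "\n".join("".join(row) for row in grid) + "\n"

    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1 + len(lanes), 4))
        for k, (name, bands) in enumerate(lanes):
            for b in bands:
                ax.plot([k - 0.3, k + 0.3], [b, b], lw=3, color="k")
        ax.set_yscale("log")
        ax.set_xticks(range(len(lanes)))
        ax.set_xticklabels([n for n, _ in lanes], rotation=45, ha="right")
        ax.set_ylabel("fragment length (bp)")
        ax.invert_yaxis()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return text
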