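"""Synthetic mitochondrial Control Region populations with ground truth.

The generator emulates the data structure of a clone-sequencing survey of
the AT-rich insect Control Region: nine populations of a few individuals
each, a shared template, population-private SNPs and indels (including one
population carrying a large private insertion and another a 20-bp private
deletion), tandem-repeat (TR) loci whose copy number varies per individual,
and dinucleotide SSR loci genotyped by in silico PCR. Every edit is
recorded in a :class:`TruthRecord` so downstream stages (repeat scanning,
consensus/SNP calling, diversity, the dRFLP screen) can be validated by
direct string inspection rather than against themselves.

Noise is substitution-only: large indels are population features here, not
noise, which keeps every truth coordinate exact. Noise never lands on a
manifest SNP position, so the manifest stays recoverable from the emitted
sequences at any noise rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .io_formats import LabeledSequence, PopulationSet

__all__ = [
    "Indel",
    "PopulationSpec",
    "TandemLocusSpec",
    "SsrLocusSpec",
    "SimulationConfig",
    "TruthRecord",
    "expand_tandem_array",
    "simulate_populations",
    "study_config",
    "STUDY_POPULATIONS",
    "STUDY_REGIONS",
    "TR10_MOTIF",
]

#: the 21-bp repeat motif of the most polymorphic Control Region TR locus
TR10_MOTIF = "GGAAAAAATGTCACGTTTTTC"

#: the nine sampled populations (collection sites across rice-growing India)
STUDY_POPULATIONS = [
    "Cuttack", "NewDelhi", "Hyderabad", "Bishnupur", "Aizawl",
    "Nalgonda", "Ludhiana", "Rajnagar", "Warangal",
]

#: geographic grouping used for regional diversity
STUDY_REGIONS = {
    "NewDelhi": "north", "Ludhiana": "north",
    "Cuttack": "south", "Hyderabad": "south", "Nalgonda": "south",
    "Warangal": "south",
    "Aizawl": "northeast", "Bishnupur": "northeast", "Rajnagar": "northeast",
}


@dataclass(frozen=True)
class Indel:
    """A private structural edit: insertion of ``sequence`` at ``position``
    or deletion of ``length`` bases starting there (template coordinates)."""

    position: int
    sequence: str | None = None   # insertion
    length: int = 0               # deletion

    def __post_init__(self) -> None:
        if (self.sequence is None) == (self.length == 0):
            raise ValueError("indel must be either an insertion or a deletion")

    @property
    def is_insertion(self) -> bool:
        return self.sequence is not None

    @property
    def span(self) -> tuple[int, int]:
        if self.is_insertion:
            return (self.position, self.position)
        return (self.position, self.position + self.length)


@dataclass
class PopulationSpec:
    name: str
    n_individuals: int
    private_snps: list[tuple[int, str]] = field(default_factory=list)
    private_indels: list[Indel] = field(default_factory=list)


@dataclass
class TandemLocusSpec:
    """A tandem-repeat locus: ``motif`` inserted head-to-tail at ``position``
    with per-population uniform copy-number ranges (fractional copies to
    one decimal; '*' keys the default range)."""

    name: str
    motif: str
    position: int
    copy_ranges: dict[str, tuple[float, float]]
    #: fractional parts allowed when sampling copies (None = full 0.1 grid)
    allowed_fractions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.motif) < 2:
            raise ValueError(f"locus {self.name}: motif shorter than 2 bp")
        for pop, (lo, hi) in self.copy_ranges.items():
            if lo > hi or lo < 0:
                raise ValueError(f"locus {self.name}: bad copy range for {pop}")

    def range_for(self, population: str) -> tuple[float, float]:
        return self.copy_ranges.get(population, self.copy_ranges.get("*", (0.0, 0.0)))


@dataclass
class SsrLocusSpec:
    """A dinucleotide-repeat locus genotyped by amplicon length; integer
    copies, uniform per population."""

    name: str
    motif: str
    position: int
    copy_ranges: dict[str, tuple[int, int]]
    flank: int = 40   # clear template flank reserved for primer sites

    def range_for(self, population: str) -> tuple[int, int]:
        return self.copy_ranges.get(population, self.copy_ranges.get("*", (0, 0)))


@dataclass
class SimulationConfig:
    seed: int
    template_length: int = 1028
    gc_fraction: float = 0.20
    populations: list[PopulationSpec] = field(default_factory=list)
    tr_loci: list[TandemLocusSpec] = field(default_factory=list)
    ssr_loci: list[SsrLocusSpec] = field(default_factory=list)
    substitution_noise_rate: float = 0.0
    #: deterministic template patches (position, subsequence), applied after
    #: the random draw; used for locus boundary guards and site cassettes
    template_overrides: list[tuple[int, str]] = field(default_factory=list)
    template: str | None = None   # fixed template overrides the random draw

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if not 0.0 <= self.substitution_noise_rate <= 1.0:
            raise ValueError("substitution_noise_rate must be in [0, 1]")
        self.validate_layout()

    def validate_layout(self) -> None:
        """Reject overlapping locus/indel coordinates up front."""
        spans: list[tuple[int, int, str]] = []
        for locus in self.tr_loci:
            spans.append((locus.position, locus.position, f"TR locus {locus.name}"))
        for locus in self.ssr_loci:
            spans.append((locus.position - locus.flank, locus.position + locus.flank,
                          f"SSR locus {locus.name}"))
        for pop in self.populations:
            for indel in pop.private_indels:
                a, b = indel.span
                spans.append((a, b, f"{pop.name} indel @{indel.position}"))
        spans.sort()
        for (a1, b1, n1), (a2, b2, n2) in zip(spans, spans[1:]):
            # two point events at the same position still collide
            if a2 < b1 or (a1 == a2):
                raise ValueError(f"overlapping features: {n1} and {n2}")
        L = self.template_length
        for a, b, n in spans:
            if not (0 <= a and b <= L):
                raise ValueError(f"{n} outside template of length {L}")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")


@dataclass
class TruthRecord:
    """Exact description of every edit behind an emitted PopulationSet."""

    template: str
    copy_numbers: dict[str, dict[str, float]]          # individual -> locus -> copies
    locus_coords: dict[str, dict[str, tuple[int, int]]]  # emitted half-open spans
    snp_manifest: dict[str, list[tuple[int, str, str]]]  # pop -> (pos, anc, derived)
    indel_manifest: dict[str, list[dict]]
    snp_coords: dict[str, dict[int, int]]              # individual -> template pos -> emitted pos
    populations: dict[str, list[str]]                  # pop -> individual ids

    def to_json(self, path) -> None:
        payload = {
            "template": self.template,
            "copy_numbers": self.copy_numbers,
            "locus_coords": self.locus_coords,
            "snp_manifest": self.snp_manifest,
            "indel_manifest": self.indel_manifest,
            "snp_coords": {k: {str(p): e for p, e in v.items()}
                           for k, v in self.snp_coords.items()},
            "populations": self.populations,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            template=d["template"],
            copy_numbers=d["copy_numbers"],
            locus_coords={k: {n: tuple(v) for n, v in loci.items()}
                          for k, loci in d["locus_coords"].items()},
            snp_manifest={k: [tuple(x) for x in v]
                          for k, v in d["snp_manifest"].items()},
            indel_manifest=d["indel_manifest"],
            snp_coords={k: {int(p): e for p, e in v.items()}
                        for k, v in d["snp_coords"].items()},
            populations=d["populations"],
        )


def expand_tandem_array(motif: str, copies: float) -> str:
    """Head-to-tail expansion of ``motif`` to a (possibly fractional) copy
    number: full copies plus the first ``round(frac * |motif|)`` bases."""
    if copies < 0:
        raise ValueError("copy number must be non-negative")
    full = int(math.floor(copies))
    extra = int(round((copies - full) * len(motif)))
    return motif * full + motif[:extra]


def _draw_template(config: SimulationConfig, rng: np.random.Generator) -> str:
    if config.template is not None:
        template = config.template.upper()
        if len(template) != config.template_length:
            raise ValueError("fixed template length disagrees with template_length")
    else:
        gc = config.gc_fraction
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        template = "".join(rng.choice(list("ACGT"), size=config.template_length,
                                      p=probs))
    chars = list(template)
    for pos, sub in config.template_overrides:
        if pos < 0 or pos + len(sub) > len(chars):
            raise ValueError(f"template override at {pos} outside template")
        chars[pos:pos + len(sub)] = list(sub.upper())
    return "".join(chars)


def _sample_copies(locus: TandemLocusSpec, population: str,
                   rng: np.random.Generator) -> float:
    lo, hi = locus.range_for(population)
    raw = rng.uniform(lo, hi)
    whole = math.floor(raw)
    if locus.allowed_fractions:
        frac = locus.allowed_fractions[rng.integers(len(locus.allowed_fractions))]
    else:
        frac = round(raw - whole, 1)
    copies = min(max(whole + frac, lo), hi)
    return round(copies, 1)


def simulate_populations(config: SimulationConfig,
                         ) -> tuple[PopulationSet, TruthRecord]:
    """Emit one sequence per individual plus the exact truth record.

    Each individual is the template with its population's private SNPs and
    indels applied, tandem/SSR arrays inserted at their loci with sampled
    copy numbers, and i.i.d. substitution noise added everywhere except at
    manifest SNP positions. Deterministic for a fixed config.
    """
    # separate streams so the structural draw (template, copy numbers) is
    # identical across noise settings of the same seed
    rng = np.random.default_rng([config.seed, 1])
    noise_rng = np.random.default_rng([config.seed, 2])
    template = _draw_template(config, rng)
    L = len(template)

    snp_manifest: dict[str, list[tuple[int, str, str]]] = {}
    indel_manifest: dict[str, list[dict]] = {}
    for pop in config.populations:
        entries = []
        for pos, derived in pop.private_snps:
            ancestral = template[pos]
            if derived.upper() == ancestral:
                raise ValueError(
                    f"{pop.name}: SNP at {pos} derived base equals template base")
            entries.append((pos, ancestral, derived.upper()))
        snp_manifest[pop.name] = entries
        indel_manifest[pop.name] = [
            {"position": ind.position,
             "kind": "insertion" if ind.is_insertion else "deletion",
             "length": len(ind.sequence) if ind.is_insertion else ind.length,
             "sequence": ind.sequence}
            for ind in pop.private_indels
        ]

    copy_numbers: dict[str, dict[str, float]] = {}
    locus_coords: dict[str, dict[str, tuple[int, int]]] = {}
    snp_coords: dict[str, dict[int, int]] = {}
    populations: dict[str, list[str]] = {}

    sequences: list[LabeledSequence] = []
    counter = 0
    for pop in config.populations:
        populations[pop.name] = []
        for _ in range(pop.n_individuals):
            counter += 1
            ind_id = f"ind{counter:03d}"
            populations[pop.name].append(ind_id)

            base = list(template)
            snp_positions = set()
            for pos, _, derived in snp_manifest[pop.name]:
                base[pos] = derived
                snp_positions.add(pos)

            # events in template order: (position, kind, payload)
            events: list[tuple[int, str, object]] = []
            for locus in config.tr_loci:
                copies = _sample_copies(locus, pop.name, rng)
                segment = expand_tandem_array(locus.motif, copies)
                events.append((locus.position, "insert", (locus.name, segment,
                                                          len(locus.motif))))
            for locus in config.ssr_loci:
                lo, hi = locus.range_for(pop.name)
                k = int(rng.integers(lo, hi + 1))
                segment = locus.motif * k
                events.append((locus.position, "insert", (locus.name, segment,
                                                          len(locus.motif))))
            for indel in pop.private_indels:
                if indel.is_insertion:
                    events.append((indel.position, "insert",
                                   (None, indel.sequence.upper(), None)))
                else:
                    events.append((indel.position, "delete", indel.length))
            events.sort(key=lambda e: e[0])

            parts: list[str] = []
            coords: dict[str, tuple[int, int]] = {}
            pos_map: dict[int, int] = {}
            cursor = 0
            emitted = 0
            ind_copies: dict[str, float] = {}

            def flush(upto: int) -> None:
                nonlocal cursor, emitted
                chunk = base[cursor:upto]
                for off, tpos in enumerate(range(cursor, upto)):
                    if tpos in snp_positions:
                        pos_map[tpos] = emitted + off
                parts.append("".join(chunk))
                emitted += upto - cursor
                cursor = upto

            for position, kind, payload in events:
                flush(position)
                if kind == "insert":
                    name, segment, period = payload
                    parts.append(segment)
                    if name is not None:
                        coords[name] = (emitted, emitted + len(segment))
                        ind_copies[name] = round(len(segment) / period, 1)
                    emitted += len(segment)
                else:
                    cursor += payload   # deletion: skip template bases
            flush(L)
            residues = "".join(parts)

            if config.substitution_noise_rate > 0:
                arr = np.frombuffer(residues.encode(), dtype="S1").copy()
                hits = np.nonzero(
                    noise_rng.random(len(arr)) < config.substitution_noise_rate)[0]
                protected = set(pos_map.values())
                alphabet = np.array([b"A", b"C", b"G", b"T"])
                for i in hits:
                    if int(i) in protected:
                        continue
                    current = arr[i]
                    choices = [b for b in alphabet if b != current]
                    arr[i] = choices[noise_rng.integers(3)]
                residues = b"".join(arr).decode()

            sequences.append(LabeledSequence(ind_id, pop.name, residues))
            copy_numbers[ind_id] = ind_copies
            locus_coords[ind_id] = coords
            snp_coords[ind_id] = pos_map

    truth = TruthRecord(template, copy_numbers, locus_coords, snp_manifest,
                        indel_manifest, snp_coords, populations)
    return PopulationSet(sequences), truth


# ---------------------------------------------------------------------------
# The default study configuration

# template patches: locus boundary guards (so tandem arrays never extend by
# chance into flanking template) and near-site cassettes a single private
# SNP toggles into a restriction site
_CASSETTE_HPY = "AAGTA"   # SNP at +1 (A->C) creates ACGT (HpyCH4IV)
_CASSETTE_TSP = "GTTAC"   # SNP at +2 (T->G) creates GTGAC (Tsp45I, GTSAC)

_TR2_MOTIF = "TATGATTGAAGT"   # 12-mer, C-free so 'C' guards pin its borders

_HPY_CASSETTE_POS = {
    "Cuttack": [100], "Hyderabad": [180], "Nalgonda": [260], "Ludhiana": [340],
    "Rajnagar": [480], "Warangal": [560], "Bishnupur": [744],
}
# three spread toggles: wherever the flanking cut landscape puts the other
# Tsp45I sites, at least one extra cut splits a fragment gel-visibly
_TSP_CASSETTE_POS = {"Aizawl": [60, 585, 640]}


def _tr10_allowed_fractions() -> tuple[float, ...]:
    # fractions whose partial-copy boundary base is not the 'C' guard
    out = []
    for tenth in range(10):
        f = tenth / 10
        if TR10_MOTIF[int(round(f * len(TR10_MOTIF))) % len(TR10_MOTIF)] != "C":
            out.append(f)
    return tuple(out)


def study_config(seed: int, *, noise_rate: float = 0.005,
                 n_private_snps: int = 25) -> SimulationConfig:
    """The default nine-population configuration.

    53 individuals (5 + 6x8) across the nine collection sites; a 1028-bp
    AT-rich template (GC 0.20); the 21-bp TR10 motif with per-population
    copy ranges spanning ~4-75 so total lengths span roughly 1.1-2.9 kb; a
    333-bp insertion private to Bishnupur and a 20-bp deletion private to
    NewDelhi; ~25 private SNPs per population (pairwise consensus
    divergence on the few-percent scale); and engineered single-SNP
    restriction-site toggles so that the HpyCH4IV + Tsp45I double digest
    discriminates all populations while neither enzyme alone separates the
    NewDelhi/Aizawl pair.
    """
    rng = np.random.default_rng([seed, 9157])
    overrides: list[tuple[int, str]] = []
    cassette_snps: dict[str, list[tuple[int, str]]] = {}
    for pop, positions in _HPY_CASSETTE_POS.items():
        for pos in positions:
            overrides.append((pos, _CASSETTE_HPY))
            cassette_snps.setdefault(pop, []).append((pos + 1, "C"))
    for pop, positions in _TSP_CASSETTE_POS.items():
        for pos in positions:
            overrides.append((pos, _CASSETTE_TSP))
            cassette_snps.setdefault(pop, []).append((pos + 2, "G"))
    # tandem locus boundary guards
    overrides.append((299, "CC"))    # TR2 at 300, C-free motif
    overrides.append((619, "AC"))    # TR10 at 620: left 'A' (motif ends C),
                                     # right 'C' with fractions filtered below

    tr_loci = [
        TandemLocusSpec("TR2", _TR2_MOTIF, 300, {"*": (2.0, 8.0)},
                        allowed_fractions=(0.0,)),
        TandemLocusSpec("TR10", TR10_MOTIF, 620, {
            "Cuttack": (10.0, 20.0), "NewDelhi": (20.0, 30.0),
            "Hyderabad": (8.0, 16.0), "Bishnupur": (40.0, 75.0),
            "Aizawl": (18.0, 28.0), "Nalgonda": (4.0, 12.0),
            "Ludhiana": (25.0, 35.0), "Rajnagar": (8.0, 15.0),
            "Warangal": (14.0, 24.0),
        }, allowed_fractions=_tr10_allowed_fractions()),
    ]
    ssr_loci = [
        SsrLocusSpec("gSSR1", "AT", 420, {"*": (8, 25)}),
        SsrLocusSpec("gSSR2", "AG", 695, {"*": (10, 30)}),
        SsrLocusSpec("gSSR3", "AT", 900, {"*": (6, 20)}),
    ]

    # template positions private SNPs may occupy: away from every
    # engineered feature so truth stays exactly recoverable
    blocked = set()
    for pos, sub in overrides:
        blocked.update(range(pos - 2, pos + len(sub) + 2))
    for locus in tr_loci:
        blocked.update(range(locus.position - 25, locus.position + 25))
    for locus in ssr_loci:
        blocked.update(range(locus.position - locus.flank - 5,
                             locus.position + locus.flank + 5))
    blocked.update(range(150 - 25, 150 + 25))        # Bishnupur insertion point
    blocked.update(range(820 - 25, 840 + 25))        # NewDelhi deletion span
    candidates = [p for p in range(5, 1023) if p not in blocked]
    rng.shuffle(candidates)

    # the 333-bp AT-rich private insertion
    ins333 = "".join(rng.choice(list("ACGT"), size=333, p=[0.4, 0.1, 0.1, 0.4]))

    populations = []
    counts = {pop: 6 for pop in STUDY_POPULATIONS}
    counts["Cuttack"] = 5   # 5 + 6*8 = 53 individuals
    cursor = 0
    for pop in STUDY_POPULATIONS:
        snps: list[tuple[int, str]] = list(cassette_snps.get(pop, []))
        take = candidates[cursor:cursor + n_private_snps]
        cursor += n_private_snps
        for pos in sorted(take):
            snps.append((pos, None))   # derived base filled in by simulate?
        indels = []
        if pop == "Bishnupur":
            indels.append(Indel(150, sequence=ins333))
        if pop == "NewDelhi":
            indels.append(Indel(820, length=20))
        populations.append(PopulationSpec(pop, counts[pop], snps, indels))

    config = SimulationConfig(
        seed=int(seed) % (2**31),
        template_length=1028,
        gc_fraction=0.20,
        populations=populations,
        tr_loci=tr_loci,
        ssr_loci=ssr_loci,
        substitution_noise_rate=noise_rate,
        template_overrides=overrides,
    )
    _fill_derived_bases(config, rng)
    return config


def _fill_derived_bases(config: SimulationConfig, rng: np.random.Generator) -> None:
    """Resolve placeholder private-SNP derived bases against the realized
    template (derived base drawn uniformly among the three non-template
    bases)."""
    template = _draw_template(config, np.random.default_rng([config.seed, 1]))
    for pop in config.populations:
        resolved = []
        for pos, derived in pop.private_snps:
            if derived is None:
                options = [b for b in "ACGT" if b != template[pos]]
                derived = options[rng.integers(3)]
            resolved.append((pos, derived))
        pop.private_snps = resolved
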