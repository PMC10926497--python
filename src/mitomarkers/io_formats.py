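"""Sequence containers and readers/writers for the pipeline's external formats.

Formats handled here: FASTA (population-labelled sequences), TSV
(restriction-enzyme table, sample x marker table, id -> population map).
Population labels ride along in FASTA headers as the token after the last
``|`` (``>clone1|Cuttack``); a two-column sidecar TSV mapping id to
population overrides the header convention when supplied.

All coordinates inside the package are 0-based half-open; positions in
written reports are 1-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import DNA_LETTERS, IUPAC_SETS

__all__ = [
    "LabeledSequence",
    "PopulationSet",
    "MarkerTable",
    "read_fasta",
    "write_fasta",
    "read_population_map",
    "read_enzyme_table",
    "write_enzyme_table",
    "default_enzyme_library",
    "read_marker_table",
    "write_marker_table",
]

MISSING = "NA"


@dataclass(frozen=True)
class LabeledSequence:
    """A population-tagged DNA sequence.

    ``residues`` is stored uppercase over the IUPAC alphabet; ``-`` is only
    legal inside alignments (``aligned=True``).
    """

    id: str
    population: str
    residues: str
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residues")
        canon = self.residues.upper()
        object.__setattr__(self, "residues", canon)
        bad = set(canon) - DNA_LETTERS
        if bad:
            raise ValueError(f"sequence {self.id!r}: non-IUPAC letters {sorted(bad)}")
        if not self.aligned and "-" in canon:
            raise ValueError(f"sequence {self.id!r}: gap character in unaligned sequence")

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "LabeledSequence":
        return LabeledSequence(self.id, self.population, self.residues.replace("-", ""))


class PopulationSet:
    """Ordered mapping population name -> list of LabeledSequence."""

    def __init__(self, sequences: Iterable[LabeledSequence] = ()) -> None:
        self._groups: dict[str, list[LabeledSequence]] = {}
        self._ids: set[str] = set()
        for seq in sequences:
            self.add(seq)

    def add(self, seq: LabeledSequence) -> None:
        if seq.id in self._ids:
            raise ValueError(f"duplicate sequence id {seq.id!r}")
        self._ids.add(seq.id)
        self._groups.setdefault(seq.population, []).append(seq)

    @property
    def populations(self) -> list[str]:
        return list(self._groups)

    def __getitem__(self, population: str) -> list[LabeledSequence]:
        return self._groups[population]

    def __contains__(self, population: str) -> bool:
        return population in self._groups

    def __iter__(self) -> Iterator[LabeledSequence]:
        for seqs in self._groups.values():
            yield from seqs

    def __len__(self) -> int:
        return sum(len(s) for s in self._groups.values())

    def items(self) -> Iterator[tuple[str, list[LabeledSequence]]]:
        return iter(self._groups.items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PopulationSet):
            return NotImplemented
        return list(self._groups) == list(other._groups) and all(
            self._groups[p] == other._groups[p] for p in self._groups
        )


@dataclass
class MarkerTable:
    """Rectangular sample x marker table of non-negative values.

    ``values`` is a float DataFrame indexed by sample id, NaN marking
    missing cells; ``groups`` maps each sample to its population label.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            raise ValueError("marker table: sample ids and group labels disagree")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=np.inf) < 0:
            raise ValueError("marker table: negative marker value")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def markers(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# FASTA

def _population_from_header(description: str) -> str | None:
    if "|" not in description:
        return None
    token = description.rsplit("|", 1)[1].split()[0].strip()
    return token or None


def read_fasta(path: str | os.PathLike,
               population_map: Mapping[str, str] | str | os.PathLike | None = None,
               ) -> PopulationSet:
    """Read population-labelled sequences from FASTA.

    Population comes from the token after the last ``|`` of each header
    unless ``population_map`` (an id -> population mapping, or a path to a
    two-column TSV) is given, in which case the map wins.
    """
    if population_map is not None and not isinstance(population_map, Mapping):
        population_map = read_population_map(population_map)
    pop_set = PopulationSet()
    for record in SeqIO.parse(str(path), "fasta"):
        if population_map is not None:
            try:
                population = population_map[record.id.split("|", 1)[0]]
            except KeyError:
                raise ValueError(
                    f"record {record.id!r}: no population in sidecar map") from None
        else:
            population = _population_from_header(record.description)
            if population is None:
                raise ValueError(
                    f"record {record.id!r}: header carries no '|population' token "
                    "and no sidecar map was given")
        seq_id = record.id.split("|", 1)[0]
        pop_set.add(LabeledSequence(seq_id, population, str(record.seq)))
    return pop_set


def write_fasta(pop_set: PopulationSet, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=f"{s.id}|{s.population}", description="")
        for s in pop_set
    ]
    SeqIO.write(records, str(path), "fasta")


def read_population_map(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["id"], df["population"]))


def write_population_map(pop_set: PopulationSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for seq in pop_set:
            fh.write(f"{seq.id}\t{seq.population}\n")


# ---------------------------------------------------------------------------
# Enzyme tables

def read_enzyme_table(path: str | os.PathLike) -> list:
    """Parse a TSV of restriction enzymes: name, IUPAC site, cut offset."""
    from .restriction import EnzymeDefinition

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"name": str, "site": str})
    required = {"name", "site", "cut_offset"}
    if not required <= set(df.columns):
        raise ValueError(f"enzyme table must have columns {sorted(required)}")
    enzymes = []
    for row in df.itertuples(index=False):
        enzymes.append(EnzymeDefinition(row.name, row.site, int(row.cut_offset)))
    return enzymes


def write_enzyme_table(enzymes: Iterable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("name\tsite\tcut_offset\n")
        for enz in enzymes:
            fh.write(f"{enz.name}\t{enz.site}\t{enz.cut_offset}\n")


def default_enzyme_library(min_site_len: int = 4) -> list:
    """Restriction-enzyme library drawn from biopython's REBASE tables.

    Commercially available type II enzymes with a single elucidated cut
    inside the recognition site, deduplicated across isoschizomers by
    (site, offset): one representative name per distinct digestion
    specificity (~200, standing in for the 500+ commercial enzymes they
    cover). HpyCH4IV (A^CGT) and Tsp45I (^GTSAC), the enzymes this
    analysis leans on, are preferred over their isoschizomers; otherwise
    the alphabetically first name wins.
    """
    from Bio.Restriction import CommOnly

    from .restriction import EnzymeDefinition

    preferred = {"HpyCH4IV", "Tsp45I"}
    seen: dict[tuple[str, int], str] = {}
    for enz in CommOnly:
        site = str(enz.site)
        fst5 = enz.charac[0]
        if fst5 is None or not enz.cut_once():
            continue
        if len(site) < min_site_len or not (0 <= fst5 <= len(site)):
            continue
        if set(site) - set(IUPAC_SETS):
            continue
        key = (site, fst5)
        name = str(enz)
        held = seen.get(key)
        if (held is None or (name in preferred and held not in preferred)
                or (held not in preferred and name < held)):
            seen[key] = name
    library = [EnzymeDefinition(name, site, offset)
               for (site, offset), name in seen.items()]
    library.sort(key=lambda e: e.name)
    return library


# ---------------------------------------------------------------------------
# Marker tables

def read_marker_table(path: str | os.PathLike) -> MarkerTable:
    """Read a sample x marker TSV: columns sample, group, then markers.

    Cells are non-negative numbers or the sentinel ``NA`` for missing.
    A malformed cell raises with its row and column named.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError("marker table needs sample, group and >=1 marker column")
    sample_col, group_col = df.columns[:2]
    marker_cols = list(df.columns[2:])
    values = pd.DataFrame(index=pd.Index(df[sample_col], name="sample"),
                          columns=marker_cols, dtype=float)
    for col in marker_cols:
        for sample, cell in zip(df[sample_col], df[col]):
            if isinstance(cell, str):
                cell = cell.strip()
            if cell is None or cell == MISSING or (isinstance(cell, float) and np.isnan(cell)):
                values.loc[sample, col] = np.nan
                continue
            try:
                values.loc[sample, col] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"marker table cell {cell!r} (sample {sample!r}, "
                    f"marker {col!r}) is not numeric or {MISSING!r}") from None
    groups = pd.Series(df[group_col].to_numpy(), index=values.index, name="group")
    return MarkerTable(values, groups)


def write_marker_table(table: MarkerTable, path: str | os.PathLike) -> None:
    out = table.values.copy()
    out.insert(0, "group", table.groups)
    out.to_csv(path, sep="\t", na_rep=MISSING, index_label="sample")
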