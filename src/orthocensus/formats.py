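"""Readers, writers, and core containers for the pipeline's external formats.

This module owns every representation the pipeline touches on disk:

* orthogroup membership tables in the OrthoFinder ``Orthogroups.tsv`` dialect
  (one row per orthogroup, one tab-separated column per proteome, protein IDs
  joined by ``", "`` within a cell);
* protein / transcript FASTA, where the first whitespace token of a header is
  the record ID and the remainder is free-text description used downstream for
  annotation transfer;
* GFF3 genomic-interval files (1-based, inclusive coordinates; attribute order
  and percent-encoded reserved characters survive a read/write cycle exactly);
* the protein -> (assembly, gene cluster) map as a 3-column TSV;
* the species-group configuration that assigns proteomes to the nested
  focal / conspecific / ingroup sets the census criteria quantify over.

All coordinate handling in the package is 1-based with inclusive ends; a
feature of length one has ``start == end``.
"""

from __future__ import annotations

import csv
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .errors import ConfigError, ConsistencyError, FormatError

__all__ = [
    "OrthogroupTable",
    "FastaRecord",
    "ProteinRecord",
    "IntervalFeature",
    "GeneClusterMap",
    "SpeciesGroupConfig",
    "read_orthogroup_table",
    "write_orthogroup_table",
    "read_fasta",
    "read_protein_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_cluster_map",
    "write_cluster_map",
    "load_group_config",
    "write_group_config",
]

# IUPAC amino-acid letters (incl. ambiguity codes and rare residues), stop, X.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBJOUZX*")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")


# ---------------------------------------------------------------------------
# Orthogroup tables
# ---------------------------------------------------------------------------

@dataclass
class OrthogroupTable:
    """Orthogroup ID -> per-proteome ordered lists of member protein IDs.

    Within-cell order is preserved exactly as read: the annotation-transfer
    rule ("first protein listed for a species") depends on it.
    """

    proteomes: list[str]
    orthogroups: dict[str, dict[str, list[str]]]
    id_column: str = "Orthogroup"

    def __post_init__(self) -> None:
        seen = set()
        for p in self.proteomes:
            if p in seen:
                raise FormatError(f"duplicate proteome column {p!r}")
            seen.add(p)
        for og, membership in self.orthogroups.items():
            unknown = set(membership) - seen
            if unknown:
                raise FormatError(
                    f"orthogroup {og!r} has members for proteomes not in the "
                    f"header: {sorted(unknown)}"
                )
            for p in self.proteomes:
                cell = membership.setdefault(p, [])
                if len(cell) != len(set(cell)):
                    dups = sorted({x for x in cell if cell.count(x) > 1})
                    raise FormatError(
                        f"orthogroup {og!r}, proteome {p!r}: duplicate protein "
                        f"IDs {dups}"
                    )

    def members(self, orthogroup_id: str, proteome_id: str) -> list[str]:
        return self.orthogroups[orthogroup_id][proteome_id]

    @property
    def n_orthogroups(self) -> int:
        return len(self.orthogroups)

    def proteins_for(self, proteome_id: str) -> list[str]:
        """All member IDs of one proteome across orthogroups, in row order."""
        out: list[str] = []
        for membership in self.orthogroups.values():
            out.extend(membership[proteome_id])
        return out


def _split_cell(cell: str) -> list[str]:
    # OrthoFinder joins with ", "; tolerate bare commas and stray whitespace.
    return [tok for tok in (t.strip() for t in cell.split(",")) if tok]


def read_orthogroup_table(path: str | Path) -> OrthogroupTable:
    """Read an OrthoFinder-style ``Orthogroups.tsv`` file.

    Row order, column order and within-cell protein order are all preserved;
    empty cells become empty lists.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header line")
        if not header or not header[0]:
            raise FormatError(f"{path}: header must start with an ID column")
        proteomes = header[1:]
        orthogroups: dict[str, dict[str, list[str]]] = {}
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(row)}"
                )
            og_id = row[0]
            if og_id in orthogroups:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate orthogroup ID {og_id!r}"
                )
            orthogroups[og_id] = {
                p: _split_cell(cell) for p, cell in zip(proteomes, row[1:])
            }
    return OrthogroupTable(
        proteomes=list(proteomes), orthogroups=orthogroups, id_column=header[0]
    )


def write_orthogroup_table(table: OrthogroupTable, path: str | Path) -> None:
    """Write the dialect :func:`read_orthogroup_table` consumes (", " joins)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join([table.id_column, *table.proteomes]) + "\n")
        for og_id, membership in table.orthogroups.items():
            cells = [", ".join(membership[p]) for p in table.proteomes]
            fh.write("\t".join([og_id, *cells]) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FastaRecord:
    """One FASTA record; ``id`` is the first whitespace token of the header."""

    id: str
    description: str
    sequence: str


@dataclass(frozen=True)
class ProteinRecord:
    """A protein FASTA record with an alphabet-validated sequence."""

    protein_id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise FormatError("protein record with empty ID")
        bad = set(self.sequence.upper()) - PROTEIN_ALPHABET
        if bad:
            raise FormatError(
                f"protein {self.protein_id!r}: invalid residues {sorted(bad)}"
            )


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read FASTA records, preserving header descriptions.

    Raises :class:`FormatError` if sequence text precedes the first header or
    a header carries no ID.
    """
    path = Path(path)
    with path.open() as fh:
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: sequence line before any '>' header"
                    )
                break
    records: list[FastaRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: header with empty record ID")
        desc = rec.description[len(rec.id):].strip()
        records.append(FastaRecord(rec.id, desc, str(rec.seq)))
    return records


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(r.id, r.description, r.sequence) for r in read_fasta(path)
    ]


def write_fasta(
    records: Iterable[FastaRecord | ProteinRecord], path: str | Path, width: int = 60
) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            rid = rec.id if isinstance(rec, FastaRecord) else rec.protein_id
            header = f">{rid} {rec.description}".rstrip()
            fh.write(header + "\n")
            seq = rec.sequence
            if seq:
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
            else:
                fh.write("\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

# GFF3 reserves these inside attribute values; they are percent-encoded on
# write and decoded on read ('%' must be encoded first).
_GFF3_RESERVED = "%;=&,\t\n"


def _gff3_escape(value: str) -> str:
    for ch in _GFF3_RESERVED:
        value = value.replace(ch, f"%{ord(ch):02X}")
    return value


def _gff3_unescape(value: str) -> str:
    return urllib.parse.unquote(value)


@dataclass
class IntervalFeature:
    """One GFF3 feature line (1-based, inclusive coordinates)."""

    seqid: str
    source: str
    feature_type: str
    start: int
    end: int
    score: str | None
    strand: str
    phase: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise FormatError(f"feature start {self.start} < 1")
        if self.end < self.start:
            raise FormatError(
                f"feature end {self.end} < start {self.start}"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"invalid strand {self.strand!r}")
        if self.phase not in {"0", "1", "2", "."}:
            raise FormatError(f"invalid phase {self.phase!r}")

    def copy(self) -> "IntervalFeature":
        return IntervalFeature(
            self.seqid,
            self.source,
            self.feature_type,
            self.start,
            self.end,
            self.score,
            self.strand,
            self.phase,
            dict(self.attributes),
        )


def read_gff3(path: str | Path) -> list[IntervalFeature]:
    path = Path(path)
    features: list[IntervalFeature] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{cols[3]!r}/{cols[4]!r}"
                )
            attributes: dict[str, str] = {}
            if cols[8] not in {".", ""}:
                for pair in cols[8].split(";"):
                    if not pair:
                        continue
                    if "=" not in pair:
                        raise FormatError(
                            f"{path}: line {lineno}: malformed attribute "
                            f"{pair!r}"
                        )
                    key, _, value = pair.partition("=")
                    attributes[_gff3_unescape(key)] = _gff3_unescape(value)
            try:
                features.append(
                    IntervalFeature(
                        seqid=cols[0],
                        source=cols[1],
                        feature_type=cols[2],
                        start=start,
                        end=end,
                        score=None if cols[5] == "." else cols[5],
                        strand=cols[6],
                        phase=cols[7],
                        attributes=attributes,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return features


def write_gff3(features: Iterable[IntervalFeature], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(
                f"{_gff3_escape(k)}={_gff3_escape(v)}"
                for k, v in f.attributes.items()
            )
            fh.write(
                "\t".join(
                    [
                        f.seqid,
                        f.source,
                        f.feature_type,
                        str(f.start),
                        str(f.end),
                        "." if f.score is None else f.score,
                        f.strand,
                        f.phase,
                        attrs or ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene-cluster map
# ---------------------------------------------------------------------------

_CLUSTER_MAP_HEADER = ["protein_id", "assembly_id", "cluster_id"]


@dataclass
class GeneClusterMap:
    """Total mapping protein ID -> (assembly ID, gene-cluster ID).

    Lookup of an unmapped protein raises :class:`ConsistencyError` rather
    than silently missing: the collapse step must never drop a protein.
    """

    entries: dict[str, tuple[str, str]]

    def lookup(self, protein_id: str) -> tuple[str, str]:
        try:
            return self.entries[protein_id]
        except KeyError:
            raise ConsistencyError(
                f"protein {protein_id!r} has no gene-cluster mapping"
            ) from None

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def read_cluster_map(path: str | Path) -> GeneClusterMap:
    path = Path(path)
    entries: dict[str, tuple[str, str]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1 and row == _CLUSTER_MAP_HEADER:
                continue
            if len(row) != 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(row)}"
                )
            pid, asm, cluster = row
            if pid in entries and entries[pid] != (asm, cluster):
                raise FormatError(
                    f"{path}: line {lineno}: protein {pid!r} mapped to two "
                    f"different clusters"
                )
            entries[pid] = (asm, cluster)
    return GeneClusterMap(entries)


def write_cluster_map(cmap: GeneClusterMap, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CLUSTER_MAP_HEADER)
        for pid, (asm, cluster) in cmap.entries.items():
            writer.writerow([pid, asm, cluster])


# ---------------------------------------------------------------------------
# Species-group configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesGroupConfig:
    """Nested proteome groups the census criteria quantify over.

    ``focal_assemblies`` are the annotations being censused; ``conspecific``
    adds the same-species reference proteome(s); ``ingroup`` adds close
    relatives; everything else is outgroup. ``required_species`` is the
    outgroup proteome the novel-gene filter insists on (the study used
    *Drosophila melanogaster*). Group membership is always declared, never
    inferred from taxonomy.
    """

    proteomes: tuple[str, ...]
    focal_assemblies: frozenset[str]
    conspecific: frozenset[str]
    ingroup: frozenset[str]
    required_species: str
    counting_unit: str = "species"

    def __post_init__(self) -> None:
        universe = set(self.proteomes)
        if len(self.proteomes) != len(universe):
            raise ConfigError("duplicate proteome IDs in config")
        for name, sub, sup in [
            ("focal_assemblies", self.focal_assemblies, self.conspecific),
            ("conspecific", self.conspecific, self.ingroup),
            ("ingroup", self.ingroup, universe),
        ]:
            extra = set(sub) - set(sup)
            if extra:
                raise ConfigError(
                    f"group nesting violated: {name} members {sorted(extra)} "
                    f"not contained in the enclosing group"
                )
        if self.required_species not in universe:
            raise ConfigError(
                f"required_species {self.required_species!r} not a proteome"
            )
        if self.required_species in self.ingroup:
            raise ConfigError(
                f"required_species {self.required_species!r} must lie outside "
                f"the ingroup"
            )
        if self.counting_unit not in {"species", "proteins"}:
            raise ConfigError(
                f"counting_unit must be 'species' or 'proteins', got "
                f"{self.counting_unit!r}"
            )

    @property
    def reference_proteomes(self) -> frozenset[str]:
        """Conspecific proteomes that are not focal assemblies (e.g. RefSeq)."""
        return self.conspecific - self.focal_assemblies

    @property
    def outgroup(self) -> frozenset[str]:
        return frozenset(self.proteomes) - self.ingroup


_LIST_KEYS = ("proteomes", "focal_assemblies", "conspecific", "ingroup")


def load_group_config(path: str | Path) -> SpeciesGroupConfig:
    """Load a flat ``key = comma, separated, values`` group-config file."""
    path = Path(path)
    raw: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(
                    f"{path}: line {lineno}: expected 'key = value'"
                )
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
    missing = [k for k in (*_LIST_KEYS, "required_species") if k not in raw]
    if missing:
        raise ConfigError(f"{path}: missing keys {missing}")
    lists = {k: _split_cell(raw[k]) for k in _LIST_KEYS}
    return SpeciesGroupConfig(
        proteomes=tuple(lists["proteomes"]),
        focal_assemblies=frozenset(lists["focal_assemblies"]),
        conspecific=frozenset(lists["conspecific"]),
        ingroup=frozenset(lists["ingroup"]),
        required_species=raw["required_species"],
        counting_unit=raw.get("counting_unit", "species"),
    )


def write_group_config(config: SpeciesGroupConfig, path: str | Path) -> None:
    order = {p: i for i, p in enumerate(config.proteomes)}
    with Path(path).open("w") as fh:
        fh.write("proteomes = " + ", ".join(config.proteomes) + "\n")
        for key in ("focal_assemblies", "conspecific", "ingroup"):
            members = sorted(getattr(config, key), key=order.__getitem__)
            fh.write(f"{key} = " + ", ".join(members) + "\n")
        fh.write(f"required_species = {config.required_species}\n")
        fh.write(f"counting_unit = {config.counting_unit}\n")
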