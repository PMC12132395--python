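"""Synthetic multi-assembly gene-family scenarios with planted ground truth.

The generator emulates the data shape of a multi-assembly re-annotation
study: several focal genome assemblies of one species, a pre-existing
same-species reference annotation, a handful of ingroup relatives, and a
panel of outgroup species, all summarized in an orthogroup table (one
orthogroup per gene family). Four event types are planted per family:

* focal-lineage duplication (two gene clusters per assembly instead of one);
* a gene missing from the reference annotation (empty reference cell);
* paralog collapse in the reference (duplicated focal clusters but a single
  reference entry — the short-read mis-assembly signature);
* pseudogenization, modeled as premature stop codons at assembly-specific
  positions, so the longest intact ORF differs between assemblies and copies
  below the 100-aa coding threshold drop out of the orthogroup table.

Every downstream expectation (census counts, novel-gene set, per-assembly
longest-ORF lengths) is derivable exactly from the planted events, which is
what makes end-to-end parameter recovery an integer-equality test.

Transcript sequences are built over a restricted alphabet — UTRs and coding
codons use only C/G/T, with A confined to the planted ATG and to stop codons,
and the codon following any stop never begins "TG" — so the planted ORF is
provably the unique longest ORF on the sense strand. The sequence model is
deliberately minimal: membership and ORF structure, not similarity, drive
every downstream stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import coding
from .census import DEFAULT_CRITERIA, CensusResult, Criterion
from .errors import ParameterError
from .formats import (
    FastaRecord,
    GeneClusterMap,
    IntervalFeature,
    OrthogroupTable,
    ProteinRecord,
    SpeciesGroupConfig,
    write_cluster_map,
    write_fasta,
    write_gff3,
    write_group_config,
    write_orthogroup_table,
)

__all__ = [
    "MIN_CODING_AA",
    "ScenarioParams",
    "CopyTruth",
    "FamilyTruth",
    "SyntheticTruth",
    "ScenarioPaths",
    "generate_scenario",
    "expected_census",
    "perturb_clustering",
]

#: Coding threshold (aa) deciding orthogroup membership of planted proteins;
#: matches the default long-ORF scan cutoff.
MIN_CODING_AA = 100

REFERENCE_ID = "refseq"
REQUIRED_SPECIES_ID = "dmel"

_STOPS = ("TAA", "TAG", "TGA")
_NO_A = np.array(list("CGT"))
# All 27 C/G/T codons: no stops (stops need A) and no ATG anywhere.
_CODING_CODONS = np.array([a + b + c for a in "CGT" for b in "CGT" for c in "CGT"])
_CODING_CODONS_NO_TG = np.array(
    [c for c in _CODING_CODONS if not c.startswith("TG")]
)
_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# Pseudogene fragment lengths straddle the coding threshold so some copies
# drop out of the proteome and some survive.
_PSEUDO_FRAGMENT_RANGE = (40, 160)


@dataclass(frozen=True)
class ScenarioParams:
    """Study conditions of a synthetic scenario.

    Defaults mirror the scale used throughout the analyses: 500 families over
    three focal assemblies, one reference annotation, five ingroup relatives
    and fifteen outgroup species (so the >=10-outgroup criteria are
    satisfiable), with duplication in 20% of families, half of the duplicated
    families collapsed in the reference, and 5% rates for reference-missing
    and pseudogene events.
    """

    n_families: int = 500
    n_outgroup_species: int = 15
    n_ingroup_species: int = 5
    n_focal_assemblies: int = 3
    p_focal_duplication: float = 0.2
    p_missing_in_reference: float = 0.05
    p_collapse_in_reference: float = 0.5
    p_pseudogene: float = 0.05
    orf_length_aa: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_focal_duplication",
            "p_missing_in_reference",
            "p_collapse_in_reference",
            "p_pseudogene",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        for name in (
            "n_families",
            "n_outgroup_species",
            "n_ingroup_species",
            "n_focal_assemblies",
        ):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.p_collapse_in_reference > 0 and self.p_focal_duplication == 0:
            raise ParameterError(
                "paralog collapse requires duplication: p_collapse_in_reference"
                " > 0 with p_focal_duplication = 0 is impossible"
            )
        if self.orf_length_aa <= _PSEUDO_FRAGMENT_RANGE[1] + 50:
            raise ParameterError(
                f"orf_length_aa must exceed {_PSEUDO_FRAGMENT_RANGE[1] + 50} "
                f"so intact ORFs dominate pseudogene fragments"
            )

    @property
    def assemblies(self) -> tuple[str, ...]:
        return tuple(f"asm{i + 1}" for i in range(self.n_focal_assemblies))

    @property
    def ingroup_species(self) -> tuple[str, ...]:
        return tuple(f"aphid{i + 1:02d}" for i in range(self.n_ingroup_species))

    @property
    def outgroup_species(self) -> tuple[str, ...]:
        others = tuple(
            f"outgrp{i + 2:02d}" for i in range(self.n_outgroup_species - 1)
        )
        return (REQUIRED_SPECIES_ID, *others)

    def group_config(self) -> SpeciesGroupConfig:
        conspecific = (*self.assemblies, REFERENCE_ID)
        ingroup = (*conspecific, *self.ingroup_species)
        return SpeciesGroupConfig(
            proteomes=(*ingroup, *self.outgroup_species),
            focal_assemblies=frozenset(self.assemblies),
            conspecific=frozenset(conspecific),
            ingroup=frozenset(ingroup),
            required_species=REQUIRED_SPECIES_ID,
            counting_unit="species",
        )


@dataclass(frozen=True)
class CopyTruth:
    """One planted gene copy (cluster) in one focal assembly."""

    cluster_id: str
    protein_ids: tuple[str, ...]
    orf_aa: int

    @property
    def coding(self) -> bool:
        return self.orf_aa >= MIN_CODING_AA


@dataclass
class FamilyTruth:
    """Planted structure and event labels of one gene family."""

    family_id: str
    og_id: str
    duplicated: bool
    missing_in_reference: bool
    collapsed_in_reference: bool
    pseudogene: bool
    full_length_aa: int
    copies: dict[str, tuple[CopyTruth, ...]]  # assembly -> copies
    reference_proteins: tuple[str, ...]
    relative_members: dict[str, tuple[str, ...]]  # species -> protein IDs

    def census_units(self) -> dict[str, tuple[str, ...]]:
        """Countable entries per proteome, mirroring the gene-level table:
        coding cluster IDs for assemblies, verbatim protein IDs elsewhere."""
        units: dict[str, tuple[str, ...]] = {
            asm: tuple(c.cluster_id for c in copies if c.coding)
            for asm, copies in self.copies.items()
        }
        units[REFERENCE_ID] = self.reference_proteins
        for sp, members in self.relative_members.items():
            units[sp] = members
        return units


@dataclass
class SyntheticTruth:
    params: ScenarioParams
    config: SpeciesGroupConfig
    families: list[FamilyTruth] = field(default_factory=list)

    def expected_novel_og_ids(self, min_outgroup: int = 10) -> list[str]:
        """Orthogroups the novel-gene filter must return, from events alone."""
        out = []
        for fam in self.families:
            units = fam.census_units()
            if not fam.missing_in_reference:
                continue
            if not all(units[a] for a in self.params.assemblies):
                continue
            n_outgroup = sum(
                (1 if self.config.counting_unit == "species" else len(units[sp]))
                for sp in self.config.outgroup
                if units.get(sp)
            )
            if n_outgroup < min_outgroup:
                continue
            if not units.get(REQUIRED_SPECIES_ID):
                continue
            out.append(fam.og_id)
        return sorted(out)

    def pseudogene_og_ids(self) -> set[str]:
        return {f.og_id for f in self.families if f.pseudogene}

    def planted_orf_lengths(self) -> dict[str, int]:
        """Transcript ID -> planted longest-ORF length (aa), all assemblies."""
        out: dict[str, int] = {}
        for fam in self.families:
            for copies in fam.copies.values():
                for copy in copies:
                    for pid in copy.protein_ids:
                        out[pid] = copy.orf_aa
        return out


@dataclass
class ScenarioPaths:
    """Locations of every file a scenario emits."""

    outdir: Path
    orthogroups: Path
    cluster_map: Path
    group_config: Path
    truth: Path
    protein_fasta: dict[str, Path]
    transcript_fasta: dict[str, Path]
    gff3: dict[str, Path]


def _no_a_run(rng: np.random.Generator, n: int) -> str:
    return "".join(_NO_A[rng.integers(0, 3, size=n)])


def _build_transcript(
    rng: np.random.Generator, orf_aa: int, total_aa: int
) -> str:
    """One transcript whose unique longest sense ORF has ``orf_aa`` residues.

    The CDS spans ``total_aa`` codons; if ``orf_aa < total_aa`` a premature
    stop is planted at codon index ``orf_aa`` (the pseudogene case).
    """
    codons = list(_CODING_CODONS[rng.integers(0, len(_CODING_CODONS), total_aa)])
    codons[0] = "ATG"
    if orf_aa < total_aa:
        codons[orf_aa] = _STOPS[rng.integers(0, 3)]
        if orf_aa + 1 < total_aa:
            # no spurious ATG across the stop boundary
            codons[orf_aa + 1] = str(
                _CODING_CODONS_NO_TG[rng.integers(0, len(_CODING_CODONS_NO_TG))]
            )
    final_stop = _STOPS[rng.integers(0, 3)]
    utr5 = _no_a_run(rng, int(rng.integers(20, 61)))
    utr3 = "C" + _no_a_run(rng, int(rng.integers(19, 60)))
    return utr5 + "".join(codons) + final_stop + utr3


def _random_protein(rng: np.random.Generator, n: int) -> str:
    body = "".join(_AA20[rng.integers(0, len(_AA20), n - 1)])
    return "M" + body


_SPECIES_LABELS = {REQUIRED_SPECIES_ID: "Drosophila melanogaster"}


def _species_label(sp: str) -> str:
    return _SPECIES_LABELS.get(sp, sp)


def generate_scenario(
    params: ScenarioParams, outdir: str | Path
) -> tuple[ScenarioPaths, SyntheticTruth]:
    """Emit a full scenario file set and its ground truth.

    Deterministic for a given ``params`` (including the seed): the same
    parameters produce byte-identical files.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(params.seed)
    config = params.group_config()
    truth = SyntheticTruth(params=params, config=config)

    proteins: dict[str, list[ProteinRecord]] = {p: [] for p in config.proteomes}
    transcripts: dict[str, list[FastaRecord]] = {a: [] for a in params.assemblies}
    cmap_entries: dict[str, tuple[str, str]] = {}
    membership_rows: dict[str, dict[str, list[str]]] = {}

    lo = max(170, params.orf_length_aa - 50)
    hi = params.orf_length_aa + 50
    frag_lo, frag_hi = _PSEUDO_FRAGMENT_RANGE

    for idx in range(1, params.n_families + 1):
        family_id = f"fam{idx:04d}"
        og_id = f"OG{idx:07d}"
        u_dup, u_miss, u_coll, u_pseudo = rng.random(4)
        duplicated = u_dup < params.p_focal_duplication
        missing = u_miss < params.p_missing_in_reference
        collapsed = (
            duplicated and not missing and u_coll < params.p_collapse_in_reference
        )
        pseudogene = u_pseudo < params.p_pseudogene
        full_aa = int(rng.integers(lo, hi + 1))
        # assembly-specific intact-ORF lengths, guaranteed distinct
        fragments = rng.choice(
            np.arange(frag_lo, frag_hi + 1),
            size=params.n_focal_assemblies,
            replace=False,
        )

        n_copies = 2 if duplicated else 1
        copies: dict[str, tuple[CopyTruth, ...]] = {}
        for ai, asm in enumerate(params.assemblies):
            asm_copies = []
            for c in range(n_copies):
                cluster_id = f"{asm}_f{idx:04d}c{c + 1}"
                orf_aa = (
                    int(fragments[ai]) if (pseudogene and c == 0) else full_aa
                )
                protein_ids = tuple(f"{cluster_id}_t{t}" for t in (1, 2))
                asm_copies.append(CopyTruth(cluster_id, protein_ids, orf_aa))
                for pid in protein_ids:
                    seq = _build_transcript(rng, orf_aa, full_aa)
                    transcripts[asm].append(
                        FastaRecord(
                            pid, f"gene cluster {cluster_id}", seq
                        )
                    )
                    cmap_entries[pid] = (asm, cluster_id)
                    if orf_aa >= MIN_CODING_AA:
                        cds_start = seq.index("ATG")
                        protein = coding.translate(
                            seq[cds_start : cds_start + 3 * orf_aa]
                        )
                        proteins[asm].append(
                            ProteinRecord(
                                pid,
                                f"predicted protein, cluster {cluster_id}",
                                protein,
                            )
                        )
            copies[asm] = tuple(asm_copies)

        if missing:
            reference_proteins: tuple[str, ...] = ()
        elif duplicated and not collapsed:
            reference_proteins = (
                f"{REFERENCE_ID}_f{idx:04d}",
                f"{REFERENCE_ID}_f{idx:04d}b",
            )
        else:
            reference_proteins = (f"{REFERENCE_ID}_f{idx:04d}",)
        for pid in reference_proteins:
            proteins[REFERENCE_ID].append(
                ProteinRecord(
                    pid,
                    f"annotated protein {family_id} "
                    f"[{_species_label(REFERENCE_ID)}]",
                    _random_protein(rng, full_aa),
                )
            )

        relative_members: dict[str, tuple[str, ...]] = {}
        for sp in (*params.ingroup_species, *params.outgroup_species):
            pid = f"{sp}_f{idx:04d}"
            relative_members[sp] = (pid,)
            proteins[sp].append(
                ProteinRecord(
                    pid,
                    f"conserved protein {family_id} [{_species_label(sp)}]",
                    _random_protein(rng, full_aa),
                )
            )

        fam = FamilyTruth(
            family_id=family_id,
            og_id=og_id,
            duplicated=duplicated,
            missing_in_reference=missing,
            collapsed_in_reference=collapsed,
            pseudogene=pseudogene,
            full_length_aa=full_aa,
            copies=copies,
            reference_proteins=reference_proteins,
            relative_members=relative_members,
        )
        truth.families.append(fam)

        units_row: dict[str, list[str]] = {}
        for asm in params.assemblies:
            units_row[asm] = [
                pid
                for copy in copies[asm]
                if copy.coding
                for pid in copy.protein_ids
            ]
        units_row[REFERENCE_ID] = list(reference_proteins)
        for sp, members in relative_members.items():
            units_row[sp] = list(members)
        membership_rows[og_id] = units_row

    table = OrthogroupTable(
        proteomes=list(config.proteomes), orthogroups=membership_rows
    )

    # --- write everything -------------------------------------------------
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "proteins").mkdir(exist_ok=True)
    (outdir / "transcripts").mkdir(exist_ok=True)
    (outdir / "intervals").mkdir(exist_ok=True)

    paths = ScenarioPaths(
        outdir=outdir,
        orthogroups=outdir / "orthogroups.tsv",
        cluster_map=outdir / "cluster_map.tsv",
        group_config=outdir / "groups.cfg",
        truth=outdir / "truth.tsv",
        protein_fasta={
            p: outdir / "proteins" / f"{p}.faa" for p in config.proteomes
        },
        transcript_fasta={
            a: outdir / "transcripts" / f"{a}.fa" for a in params.assemblies
        },
        gff3={a: outdir / "intervals" / f"{a}.gff3" for a in params.assemblies},
    )

    write_orthogroup_table(table, paths.orthogroups)
    write_cluster_map(GeneClusterMap(cmap_entries), paths.cluster_map)
    write_group_config(config, paths.group_config)
    for proteome, records in proteins.items():
        write_fasta(records, paths.protein_fasta[proteome])
    for asm in params.assemblies:
        write_fasta(transcripts[asm], paths.transcript_fasta[asm])
        features = []
        offset = 1
        for rec in transcripts[asm]:
            length = len(rec.sequence)
            features.append(
                IntervalFeature(
                    seqid="scaffold_1",
                    source="synth",
                    feature_type="mRNA",
                    start=offset,
                    end=offset + length - 1,
                    score=None,
                    strand="+",
                    phase=".",
                    attributes={
                        "ID": rec.id,
                        "cluster": cmap_entries[rec.id][1],
                    },
                )
            )
            offset += length + 100
        write_gff3(features, paths.gff3[asm])

    novel = set(truth.expected_novel_og_ids())
    with paths.truth.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "family_id",
                "orthogroup_id",
                "duplicated",
                "missing_in_reference",
                "collapsed_in_reference",
                "pseudogene",
                "full_length_aa",
                *(f"{a}_orf_aa" for a in params.assemblies),
                "expected_novel",
            ]
        )
        for fam in truth.families:
            writer.writerow(
                [
                    fam.family_id,
                    fam.og_id,
                    int(fam.duplicated),
                    int(fam.missing_in_reference),
                    int(fam.collapsed_in_reference),
                    int(fam.pseudogene),
                    fam.full_length_aa,
                    *(fam.copies[a][0].orf_aa for a in params.assemblies),
                    int(fam.og_id in novel),
                ]
            )
    return paths, truth


def expected_census(
    truth: SyntheticTruth,
    config: SpeciesGroupConfig | None = None,
    criteria: Sequence[Criterion] = DEFAULT_CRITERIA,
) -> CensusResult:
    """Census counts derived from event labels alone (the recovery target).

    Recomputed family by family with plain loops over the planted membership,
    never touching the emitted files or the census implementation.
    """
    config = config or truth.config
    sources = tuple(p for p in config.proteomes if p in config.conspecific)
    result = CensusResult(sources=sources, criteria=tuple(criteria))
    for source in sources:
        for criterion in criteria:
            result.counts[(source, criterion.name)] = 0
    for fam in truth.families:
        units = fam.census_units()
        for source in sources:
            mine = units.get(source, ())
            if not mine:
                continue
            for criterion in criteria:
                n = 0
                for proteome in config.proteomes:
                    if criterion.group == "conspecific-others":
                        in_group = (
                            proteome in config.conspecific and proteome != source
                        )
                    elif criterion.group == "non-conspecific":
                        in_group = proteome not in config.conspecific
                    else:  # non-ingroup
                        in_group = proteome not in config.ingroup
                    if not in_group:
                        continue
                    members = units.get(proteome, ())
                    if config.counting_unit == "species":
                        n += 1 if members else 0
                    else:
                        n += len(members)
                if n >= criterion.min_members:
                    result.counts[(source, criterion.name)] += len(mine)
    return result


def perturb_clustering(
    table: OrthogroupTable,
    truth: SyntheticTruth,
    p_split: float,
    seed: int,
) -> OrthogroupTable:
    """Split the divergent assembly out of pseudogene-bearing orthogroups.

    With probability ``p_split`` per pseudogene family, the members of the
    assembly with the shortest planted intact ORF (the most fragmented copy,
    hence the one whose protein clusters worst) move to a new singleton
    orthogroup appended after the original rows. Families whose divergent
    copy fell below the coding threshold have nothing to move and are left
    unchanged.
    """
    if not 0.0 <= p_split <= 1.0:
        raise ParameterError(f"p_split={p_split} outside [0, 1]")
    rng = np.random.default_rng(seed)
    orthogroups = {
        og: {p: list(cell) for p, cell in membership.items()}
        for og, membership in table.orthogroups.items()
    }
    appended: list[tuple[str, dict[str, list[str]]]] = []
    for fam in truth.families:
        if not fam.pseudogene:
            continue
        u = rng.random()
        if u >= p_split or fam.og_id not in orthogroups:
            continue
        divergent = min(
            truth.params.assemblies, key=lambda a: fam.copies[a][0].orf_aa
        )
        cell = orthogroups[fam.og_id][divergent]
        if not cell:
            continue
        split_membership = {p: [] for p in table.proteomes}
        split_membership[divergent] = list(cell)
        orthogroups[fam.og_id][divergent] = []
        appended.append((f"{fam.og_id}x", split_membership))
    for og_id, membership in appended:
        orthogroups[og_id] = membership
    return OrthogroupTable(
        proteomes=list(table.proteomes),
        orthogroups=orthogroups,
        id_column=table.id_column,
    )
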