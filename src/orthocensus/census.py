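"""Gene-cluster censusing of orthogroup tables and novel-gene extraction.

The census collapses protein-level orthogroup membership to gene-cluster
level (many proteins per locus -> one cluster entry), then counts, per
censused proteome, the distinct clusters that fall in orthogroups whose
membership satisfies criteria of increasing evolutionary distance:

* >= 1 member from another conspecific source (other assemblies or the
  same-species reference annotation),
* >= 1 / >= 10 members from outside the species (non-conspecific),
* >= 1 / >= 10 members from outside the ingroup clade (non-ingroup).

A count is a conservative gene-number estimate for its assembly: clusters
with no support beyond the assembly itself are excluded. Novel-gene
extraction flips the reference requirement around — orthogroups with clusters
in every focal assembly, broad outgroup support including a required species,
but no member in the reference annotation are candidate genes the reference
misses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, ConsistencyError, ParameterError
from .formats import GeneClusterMap, OrthogroupTable, SpeciesGroupConfig

__all__ = [
    "Criterion",
    "DEFAULT_CRITERIA",
    "GeneLevelTable",
    "CensusResult",
    "NovelRecord",
    "NovelGeneReport",
    "collapse_to_gene_table",
    "orthogroup_group_counts",
    "census_counts",
    "extract_novel",
    "cluster_og_map",
]

logger = logging.getLogger(__name__)

GROUP_NAMES = ("conspecific-others", "non-conspecific", "non-ingroup")


@dataclass(frozen=True)
class Criterion:
    """One census predicate: >= ``min_members`` members from ``group``."""

    group: str
    min_members: int

    def __post_init__(self) -> None:
        if self.group not in GROUP_NAMES:
            raise ParameterError(f"unknown census group {self.group!r}")
        if self.min_members < 1:
            raise ParameterError("criterion threshold must be >= 1")

    @property
    def name(self) -> str:
        return f"{self.group.replace('-', '_')}_ge{self.min_members}"


#: The five membership criteria of the study, in increasing stringency of
#: evolutionary distance.
DEFAULT_CRITERIA: tuple[Criterion, ...] = (
    Criterion("conspecific-others", 1),
    Criterion("non-conspecific", 1),
    Criterion("non-ingroup", 1),
    Criterion("non-conspecific", 10),
    Criterion("non-ingroup", 10),
)


@dataclass
class GeneLevelTable:
    """Orthogroup table with focal cells collapsed to gene-cluster IDs.

    Focal-assembly cells hold deduplicated cluster IDs in first-occurrence
    order; all other cells are copied verbatim from the protein-level table.
    """

    proteomes: list[str]
    orthogroups: dict[str, dict[str, list[str]]]
    focal: frozenset[str]

    def members(self, orthogroup_id: str, proteome_id: str) -> list[str]:
        return self.orthogroups[orthogroup_id][proteome_id]


def collapse_to_gene_table(
    table: OrthogroupTable, cmap: GeneClusterMap, config: SpeciesGroupConfig
) -> GeneLevelTable:
    """Replace focal-assembly proteins by their gene clusters, one entry each.

    A cluster whose proteins land in more than one orthogroup is retained in
    each (and logged); deciding which orthogroup is "right" is not this
    package's business.
    """
    unmapped: list[str] = []
    cluster_ogs: dict[tuple[str, str], set[str]] = {}
    orthogroups: dict[str, dict[str, list[str]]] = {}
    for og_id, membership in table.orthogroups.items():
        new_membership: dict[str, list[str]] = {}
        for proteome in table.proteomes:
            cell = membership[proteome]
            if proteome not in config.focal_assemblies:
                new_membership[proteome] = list(cell)
                continue
            clusters: list[str] = []
            for pid in cell:
                if pid not in cmap:
                    unmapped.append(pid)
                    continue
                asm, cluster = cmap.lookup(pid)
                if asm != proteome:
                    raise ConsistencyError(
                        f"protein {pid!r} listed under {proteome!r} but mapped "
                        f"to assembly {asm!r}"
                    )
                if cluster not in clusters:
                    clusters.append(cluster)
                cluster_ogs.setdefault((proteome, cluster), set()).add(og_id)
            new_membership[proteome] = clusters
        orthogroups[og_id] = new_membership
    if unmapped:
        raise ConsistencyError(
            f"{len(unmapped)} focal proteins without a cluster mapping, e.g. "
            f"{sorted(set(unmapped))[:10]}"
        )
    for (proteome, cluster), ogs in cluster_ogs.items():
        if len(ogs) > 1:
            logger.warning(
                "cluster %s/%s spans %d orthogroups: %s",
                proteome,
                cluster,
                len(ogs),
                sorted(ogs),
            )
    return GeneLevelTable(
        proteomes=list(table.proteomes),
        orthogroups=orthogroups,
        focal=frozenset(config.focal_assemblies),
    )


def _group_proteomes(
    config: SpeciesGroupConfig, group: str, source: str
) -> set[str]:
    if group == "conspecific-others":
        return set(config.conspecific) - {source}
    if group == "non-conspecific":
        return set(config.proteomes) - set(config.conspecific)
    if group == "non-ingroup":
        return set(config.proteomes) - set(config.ingroup)
    raise ParameterError(f"unknown census group {group!r}")


def _count_group(
    membership: Mapping[str, Sequence[str]],
    proteomes: Iterable[str],
    counting_unit: str,
) -> int:
    if counting_unit == "species":
        return sum(1 for p in proteomes if membership.get(p))
    return sum(len(membership.get(p, ())) for p in proteomes)


def orthogroup_group_counts(
    membership: Mapping[str, Sequence[str]],
    config: SpeciesGroupConfig,
    focal: str,
) -> dict[str, int]:
    """Member counts of one orthogroup for the three census groups.

    ``conspecific-others`` is evaluated relative to ``focal`` (conspecific
    proteomes excluding the censused source itself). With
    ``counting_unit='species'`` a group's count is the number of distinct
    proteomes with at least one member; with ``'proteins'`` it is the total
    number of member entries.
    """
    return {
        group: _count_group(
            membership, _group_proteomes(config, group, focal),
            config.counting_unit,
        )
        for group in GROUP_NAMES
    }


@dataclass
class CensusResult:
    """Distinct-cluster counts per censused source and criterion."""

    sources: tuple[str, ...]
    criteria: tuple[Criterion, ...]
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def count(self, source: str, criterion: Criterion | str) -> int:
        name = criterion if isinstance(criterion, str) else criterion.name
        return self.counts[(source, name)]

    def as_frame(self) -> pd.DataFrame:
        """Long-format table: assembly, criterion, count."""
        rows = [
            {"assembly": s, "criterion": c.name, "count": self.counts[(s, c.name)]}
            for s in self.sources
            for c in self.criteria
        ]
        return pd.DataFrame(rows)


def census_counts(
    gene_table: GeneLevelTable,
    config: SpeciesGroupConfig,
    criteria: Sequence[Criterion] = DEFAULT_CRITERIA,
) -> CensusResult:
    """Count distinct qualifying gene clusters per source and criterion.

    Sources are all conspecific proteomes: focal assemblies (entries are
    cluster IDs) and reference proteomes (entries are their verbatim table
    members). A cluster found in several qualifying orthogroups counts once.
    """
    sources = tuple(
        p for p in gene_table.proteomes if p in config.conspecific
    )
    result = CensusResult(sources=sources, criteria=tuple(criteria))
    for source in sources:
        qualifying: dict[str, set[str]] = {c.name: set() for c in criteria}
        for membership in gene_table.orthogroups.values():
            entries = membership.get(source)
            if not entries:
                continue
            group_counts = orthogroup_group_counts(membership, config, source)
            for criterion in criteria:
                if group_counts[criterion.group] >= criterion.min_members:
                    qualifying[criterion.name].update(entries)
        for criterion in criteria:
            result.counts[(source, criterion.name)] = len(
                qualifying[criterion.name]
            )
    return result


@dataclass(frozen=True)
class NovelRecord:
    """One orthogroup absent from the reference annotation."""

    orthogroup_id: str
    clusters: Mapping[str, tuple[str, ...]]  # focal assembly -> cluster IDs
    outgroup_count: int
    required_proteins: tuple[str, ...]


@dataclass
class NovelGeneReport:
    records: list[NovelRecord]

    @property
    def orthogroup_ids(self) -> list[str]:
        return [r.orthogroup_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict[str, object] = {"orthogroup": r.orthogroup_id}
            for asm, clusters in r.clusters.items():
                row[asm] = ",".join(clusters)
            row["outgroup_count"] = r.outgroup_count
            row["required_proteins"] = ",".join(r.required_proteins)
            rows.append(row)
        return pd.DataFrame(rows)


def extract_novel(
    gene_table: GeneLevelTable,
    config: SpeciesGroupConfig,
    min_outgroup: int = 10,
) -> NovelGeneReport:
    """Orthogroups with clusters in every focal assembly but no reference member.

    Requires additionally >= ``min_outgroup`` non-ingroup members (counted per
    the config's counting unit) and at least one member from the required
    outgroup species. Records are sorted by orthogroup ID.
    """
    if not config.reference_proteomes:
        raise ConfigError(
            "novel-gene extraction undefined without a reference proteome "
            "(conspecific minus focal assemblies is empty)"
        )
    focal = [p for p in gene_table.proteomes if p in config.focal_assemblies]
    records: list[NovelRecord] = []
    for og_id in sorted(gene_table.orthogroups):
        membership = gene_table.orthogroups[og_id]
        if not all(membership.get(a) for a in focal):
            continue
        if any(membership.get(r) for r in config.reference_proteomes):
            continue
        n_outgroup = _count_group(
            membership, config.outgroup, config.counting_unit
        )
        if n_outgroup < min_outgroup:
            continue
        required = tuple(membership.get(config.required_species, ()))
        if not required:
            continue
        records.append(
            NovelRecord(
                orthogroup_id=og_id,
                clusters={a: tuple(membership[a]) for a in focal},
                outgroup_count=n_outgroup,
                required_proteins=required,
            )
        )
    return NovelGeneReport(records=records)


def cluster_og_map(
    table: OrthogroupTable, cmap: GeneClusterMap, config: SpeciesGroupConfig
) -> dict[str, str]:
    """Map each focal gene-cluster ID to the first orthogroup containing it."""
    out: dict[str, str] = {}
    for og_id, membership in table.orthogroups.items():
        for proteome in config.focal_assemblies:
            for pid in membership.get(proteome, []):
                if pid in cmap:
                    _, cluster = cmap.lookup(pid)
                    out.setdefault(cluster, og_id)
    return out
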