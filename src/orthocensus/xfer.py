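"""Ortholog annotation transfer onto gene-cluster interval files.

For each transcript feature belonging to a gene cluster, the header text of
the first protein listed for each chosen reference species in the cluster's
orthogroup is appended as a ``<Species>_ortholog`` attribute; species with no
member in that orthogroup are annotated with the literal ``none``. "First
listed" means first in the orthogroup table cell, i.e. file order — never
alphabetical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConsistencyError
from .formats import IntervalFeature, OrthogroupTable, ProteinRecord

__all__ = [
    "NONE_ANNOTATION",
    "AnnotationMap",
    "build_annotation_map",
    "transfer_annotations",
    "TRANSCRIPT_FEATURE_TYPES",
]

NONE_ANNOTATION = "none"

#: Feature types treated as transcript-level records; exons, CDS and other
#: children are never annotated.
TRANSCRIPT_FEATURE_TYPES = frozenset({"mRNA", "transcript"})


@dataclass
class AnnotationMap:
    """(orthogroup, species) -> transferable annotation string.

    Total over the table's orthogroups and the configured species; the value
    is ``"protein_id description"`` of the first-listed protein, or ``none``.
    Orthogroup IDs outside the map (e.g. the no-orthogroup sentinel) also
    resolve to ``none``.
    """

    species: tuple[str, ...]
    entries: dict[tuple[str, str], str]

    def get(self, orthogroup_id: str | None, species: str) -> str:
        if orthogroup_id is None:
            return NONE_ANNOTATION
        return self.entries.get((orthogroup_id, species), NONE_ANNOTATION)


def build_annotation_map(
    table: OrthogroupTable,
    proteins_by_species: Mapping[str, Mapping[str, ProteinRecord]],
    species: Sequence[str],
) -> AnnotationMap:
    """Collect the first-listed protein header per orthogroup and species."""
    entries: dict[tuple[str, str], str] = {}
    missing: list[str] = []
    for og_id, membership in table.orthogroups.items():
        for sp in species:
            cell = membership.get(sp, [])
            if not cell:
                entries[(og_id, sp)] = NONE_ANNOTATION
                continue
            first = cell[0]
            record = proteins_by_species.get(sp, {}).get(first)
            if record is None:
                missing.append(f"{sp}:{first}")
                continue
            annotation = record.protein_id
            if record.description:
                annotation += f" {record.description}"
            entries[(og_id, sp)] = annotation
    if missing:
        raise ConsistencyError(
            f"{len(missing)} first-listed proteins unresolved in the protein "
            f"FASTA sets, e.g. {missing[:10]}"
        )
    return AnnotationMap(species=tuple(species), entries=entries)


def transfer_annotations(
    features: Iterable[IntervalFeature],
    cluster_to_og: Mapping[str, str],
    amap: AnnotationMap,
    species: Sequence[str],
    cluster_key: str = "cluster",
    transcript_types: frozenset[str] = TRANSCRIPT_FEATURE_TYPES,
) -> list[IntervalFeature]:
    """Append one ``<Species>_ortholog`` attribute per species to transcripts.

    Feature count, order, coordinates and pre-existing attributes are
    preserved; non-transcript features pass through untouched. Clusters
    absent from ``cluster_to_og`` (not clustered into any orthogroup) get
    ``none`` for every species.
    """
    out: list[IntervalFeature] = []
    for feature in features:
        new = feature.copy()
        if new.feature_type in transcript_types:
            cluster = new.attributes.get(cluster_key)
            if cluster is None:
                fid = new.attributes.get("ID", "<no ID>")
                raise ConsistencyError(
                    f"transcript feature {fid} lacks the {cluster_key!r} "
                    f"attribute"
                )
            og_id = cluster_to_og.get(cluster)
            for sp in species:
                new.attributes[f"{sp}_ortholog"] = amap.get(og_id, sp)
        out.append(new)
    return out
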