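"""Transfer ortholog header annotations onto assembly-1 interval features.

For every transcript feature, appends the header of the first-listed
protein of each chosen reference species in the cluster's orthogroup as a
``<Species>_ortholog`` attribute ('none' where the species is absent).
Writes the annotated GFF3 under scratch/ and a coverage summary to
results/annotation_summary.tsv.
"""

import pandas as pd

from _common import RESULTS, SCRATCH, study_scenario
from orthocensus import (
    build_annotation_map,
    load_group_config,
    read_cluster_map,
    read_gff3,
    read_orthogroup_table,
    read_protein_fasta,
    transfer_annotations,
    write_gff3,
)
from orthocensus.census import cluster_og_map

SPECIES = ["dmel", "outgrp02"]


def main() -> None:
    paths, truth = study_scenario()
    table = read_orthogroup_table(paths.orthogroups)
    cmap = read_cluster_map(paths.cluster_map)
    config = load_group_config(paths.group_config)
    proteins = {
        sp: {r.protein_id: r for r in read_protein_fasta(paths.protein_fasta[sp])}
        for sp in SPECIES
    }
    amap = build_annotation_map(table, proteins, SPECIES)
    c2og = cluster_og_map(table, cmap, config)

    asm = truth.params.assemblies[0]
    features = read_gff3(paths.gff3[asm])
    annotated = transfer_annotations(features, c2og, amap, SPECIES)
    out_gff = SCRATCH / f"{asm}.annotated.gff3"
    write_gff3(annotated, out_gff)

    rows = []
    for sp in SPECIES:
        transcripts = [f for f in annotated if f.feature_type == "mRNA"]
        with_ortholog = sum(
            1 for f in transcripts if f.attributes[f"{sp}_ortholog"] != "none"
        )
        rows.append(
            {
                "species": sp,
                "n_transcripts": len(transcripts),
                "with_ortholog": with_ortholog,
                "none": len(transcripts) - with_ortholog,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(RESULTS / "annotation_summary.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))
    example = next(
        f for f in annotated
        if f.feature_type == "mRNA" and f.attributes["dmel_ortholog"] != "none"
    )
    print(f"\nexample transcript {example.attributes['ID']}: "
          f"dmel_ortholog={example.attributes['dmel_ortholog']!r}")
    print(f"wrote {out_gff} and {RESULTS / 'annotation_summary.tsv'}")


if __name__ == "__main__":
    main()
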