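import pytest

from orthocensus import (
    collapse_to_gene_table,
    load_group_config,
    read_cluster_map,
    read_orthogroup_table,
)
from orthocensus.synthdata import ScenarioParams, generate_scenario


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """A mixed-event scenario small enough for every unit test to share."""
    params = ScenarioParams(
        n_families=40,
        n_outgroup_species=12,
        n_ingroup_species=3,
        n_focal_assemblies=3,
        p_focal_duplication=0.3,
        p_missing_in_reference=0.15,
        p_collapse_in_reference=0.5,
        p_pseudogene=0.2,
        orf_length_aa=250,
        seed=11,
    )
    outdir = tmp_path_factory.mktemp("scenario")
    paths, truth = generate_scenario(params, outdir)
    return paths, truth


@pytest.fixture(scope="session")
def small_pipeline(small_scenario):
    """The small scenario read back through the formats layer and collapsed."""
    paths, truth = small_scenario
    table = read_orthogroup_table(paths.orthogroups)
    cmap = read_cluster_map(paths.cluster_map)
    config = load_group_config(paths.group_config)
    gene_table = collapse_to_gene_table(table, cmap, config)
    return paths, truth, table, cmap, config, gene_table
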