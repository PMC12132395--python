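"""Gene-cluster collapse, census counting, and novel-gene extraction."""

import logging

import numpy as np
import pytest

from _oracles import census_bruteforce, qualifying_clusters_bruteforce, random_gene_table
from orthocensus.census import (
    DEFAULT_CRITERIA,
    Criterion,
    GeneLevelTable,
    census_counts,
    collapse_to_gene_table,
    extract_novel,
    orthogroup_group_counts,
)
from orthocensus.errors import ConfigError, ConsistencyError, ParameterError
from orthocensus.formats import (
    GeneClusterMap,
    OrthogroupTable,
    SpeciesGroupConfig,
)


def _config(counting_unit="species", **kw):
    base = dict(
        proteomes=("A1", "A2", "R", "M", *(f"O{i}" for i in range(1, 13))),
        focal_assemblies=frozenset({"A1", "A2"}),
        conspecific=frozenset({"A1", "A2", "R"}),
        ingroup=frozenset({"A1", "A2", "R", "M"}),
        required_species="O1",
        counting_unit=counting_unit,
    )
    base.update(kw)
    return SpeciesGroupConfig(**base)


def _table(og_cells):
    """Build an OrthogroupTable over the _config proteome set."""
    config = _config()
    return OrthogroupTable(
        list(config.proteomes),
        {og: dict(cells) for og, cells in og_cells.items()},
    )


# ---------------------------------------------------------------------------
# collapse
# ---------------------------------------------------------------------------


def test_collapse_dedupes_in_first_occurrence_order():
    table = _table({"OG1": {"A1": ["p1", "p2", "p3"], "R": ["r1"]}})
    cmap = GeneClusterMap(
        {"p1": ("A1", "c1"), "p2": ("A1", "c1"), "p3": ("A1", "c2")}
    )
    gt = collapse_to_gene_table(table, cmap, _config())
    assert gt.members("OG1", "A1") == ["c1", "c2"]
    assert gt.members("OG1", "R") == ["r1"]  # non-focal untouched


def test_collapse_identity_when_one_protein_per_cluster():
    table = _table({"OG1": {"A1": ["p1", "p2"]}})
    cmap = GeneClusterMap({"p1": ("A1", "g1"), "p2": ("A1", "g2")})
    gt = collapse_to_gene_table(table, cmap, _config())
    assert gt.members("OG1", "A1") == ["g1", "g2"]


def test_collapse_unmapped_focal_protein_is_error():
    table = _table({"OG1": {"A1": ["p1", "ghost"]}})
    cmap = GeneClusterMap({"p1": ("A1", "c1")})
    with pytest.raises(ConsistencyError, match="ghost"):
        collapse_to_gene_table(table, cmap, _config())


def test_collapse_wrong_assembly_mapping_is_error():
    table = _table({"OG1": {"A1": ["p1"]}})
    cmap = GeneClusterMap({"p1": ("A2", "c1")})
    with pytest.raises(ConsistencyError, match="mapped to assembly"):
        collapse_to_gene_table(table, cmap, _config())


def test_collapse_cluster_spanning_orthogroups_is_kept_and_logged(caplog):
    table = _table({"OG1": {"A1": ["p1"]}, "OG2": {"A1": ["p2"]}})
    cmap = GeneClusterMap({"p1": ("A1", "c1"), "p2": ("A1", "c1")})
    with caplog.at_level(logging.WARNING, logger="orthocensus.census"):
        gt = collapse_to_gene_table(table, cmap, _config())
    assert gt.members("OG1", "A1") == ["c1"]
    assert gt.members("OG2", "A1") == ["c1"]
    assert any("spans 2 orthogroups" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# group counts
# ---------------------------------------------------------------------------


def test_group_counts_focal_only_orthogroup_is_all_zero():
    table = _table({"OG1": {"A1": ["p1"]}})
    counts = orthogroup_group_counts(table.orthogroups["OG1"], _config(), "A1")
    assert counts == {
        "conspecific-others": 0,
        "non-conspecific": 0,
        "non-ingroup": 0,
    }


def test_group_counts_species_vs_proteins():
    cells = {f"O{i}": ["x1", "x2"] for i in range(1, 13)}
    table = _table({"OG1": cells})
    membership = table.orthogroups["OG1"]
    by_species = orthogroup_group_counts(membership, _config(), "A1")
    assert by_species["non-ingroup"] == 12
    by_proteins = orthogroup_group_counts(
        membership, _config(counting_unit="proteins"), "A1"
    )
    assert by_proteins["non-ingroup"] == 24


def test_conspecific_others_is_relative_to_source():
    table = _table({"OG1": {"A1": ["p1"], "A2": ["q1"]}})
    membership = table.orthogroups["OG1"]
    assert orthogroup_group_counts(membership, _config(), "A1")[
        "conspecific-others"
    ] == 1
    assert orthogroup_group_counts(membership, _config(), "R")[
        "conspecific-others"
    ] == 2


def test_criterion_validation():
    with pytest.raises(ParameterError):
        Criterion("not-a-group", 1)
    with pytest.raises(ParameterError):
        Criterion("non-ingroup", 0)


# ---------------------------------------------------------------------------
# census_counts
# ---------------------------------------------------------------------------


def _gene_table(og_cells, config):
    table = _table(og_cells)
    return GeneLevelTable(
        proteomes=list(table.proteomes),
        orthogroups=table.orthogroups,
        focal=config.focal_assemblies,
    )


def test_census_singleton_orthogroup_counts_nothing():
    config = _config()
    gt = _gene_table({"OG1": {"A1": ["c1"]}}, config)
    result = census_counts(gt, config)
    assert all(v == 0 for v in result.counts.values())


def test_census_two_assembly_orthogroup():
    config = _config()
    gt = _gene_table({"OG1": {"A1": ["c1"], "A2": ["g2"]}}, config)
    result = census_counts(gt, config)
    assert result.count("A1", "conspecific_others_ge1") == 1
    assert result.count("A2", "conspecific_others_ge1") == 1
    for crit in DEFAULT_CRITERIA[1:]:
        assert result.count("A1", crit) == 0


def test_census_cluster_in_multiple_orthogroups_counts_once():
    config = _config()
    gt = _gene_table(
        {
            "OG1": {"A1": ["c1"], "R": ["r1"]},
            "OG2": {"A1": ["c1"], "R": ["r2"]},
        },
        config,
    )
    assert census_counts(gt, config).count("A1", "conspecific_others_ge1") == 1


def test_census_matches_bruteforce_on_random_tables():
    rng = np.random.default_rng(2024)
    for _ in range(30):
        gt, config = random_gene_table(rng, max_orthogroups=25, max_proteomes=12)
        result = census_counts(gt, config)
        assert result.counts == census_bruteforce(gt, config, DEFAULT_CRITERIA)


def test_census_nesting_monotonicity_on_random_tables():
    """Counts fall (weakly) as the distance requirement grows."""
    rng = np.random.default_rng(99)
    for _ in range(30):
        gt, config = random_gene_table(rng, max_orthogroups=25, max_proteomes=12)
        res = census_counts(gt, config)
        for src in res.sources:
            assert (
                res.count(src, "non_ingroup_ge10")
                <= res.count(src, "non_ingroup_ge1")
                <= res.count(src, "non_conspecific_ge1")
            )
            assert res.count(src, "non_ingroup_ge10") <= res.count(
                src, "non_conspecific_ge10"
            )


def test_census_idempotent_under_recollapse():
    """Collapsing an already-collapsed table changes nothing."""
    rng = np.random.default_rng(5)
    gt, config = random_gene_table(rng, max_orthogroups=15, max_proteomes=10)
    identity_entries = {
        entry: (p, entry)
        for og in gt.orthogroups.values()
        for p in config.focal_assemblies
        for entry in og.get(p, [])
    }
    as_protein_table = OrthogroupTable(
        list(gt.proteomes),
        {og: {p: list(c) for p, c in m.items()} for og, m in gt.orthogroups.items()},
    )
    re_collapsed = collapse_to_gene_table(
        as_protein_table, GeneClusterMap(identity_entries), config
    )
    assert census_counts(re_collapsed, config).counts == census_counts(
        gt, config
    ).counts


# ---------------------------------------------------------------------------
# extract_novel
# ---------------------------------------------------------------------------


def _novel_cells(with_required=True, with_ref=False, n_out=12):
    cells = {"A1": ["c1"], "A2": ["g1"]}
    if with_ref:
        cells["R"] = ["r1"]
    start = 1 if with_required else 2
    for i in range(start, start + n_out):
        if i <= 12:
            cells[f"O{i}"] = [f"o{i}"]
    return cells


def test_novel_requires_reference_absence():
    config = _config()
    gt = _gene_table({"OG1": _novel_cells(with_ref=True)}, config)
    assert extract_novel(gt, config).orthogroup_ids == []
    gt2 = _gene_table({"OG1": _novel_cells()}, config)
    report = extract_novel(gt2, config)
    assert report.orthogroup_ids == ["OG1"]
    rec = report.records[0]
    assert rec.clusters == {"A1": ("c1",), "A2": ("g1",)}
    assert rec.outgroup_count == 12
    assert rec.required_proteins == ("o1",)


def test_novel_requires_required_species():
    config = _config()
    gt = _gene_table({"OG1": _novel_cells(with_required=False, n_out=11)}, config)
    assert extract_novel(gt, config).orthogroup_ids == []


def test_novel_requires_every_focal_assembly():
    config = _config()
    cells = _novel_cells()
    cells["A2"] = []
    gt = _gene_table({"OG1": cells}, config)
    assert extract_novel(gt, config).orthogroup_ids == []


def test_novel_outgroup_threshold():
    config = _config()
    gt = _gene_table({"OG1": _novel_cells(n_out=9)}, config)
    assert extract_novel(gt, config).orthogroup_ids == []
    assert extract_novel(gt, config, min_outgroup=9).orthogroup_ids == ["OG1"]


def test_novel_without_reference_proteome_is_config_error():
    config = _config(conspecific=frozenset({"A1", "A2"}))
    gt = _gene_table({"OG1": _novel_cells()}, config)
    with pytest.raises(ConfigError, match="reference"):
        extract_novel(gt, config)


def test_novel_subset_of_distant_census_on_random_tables():
    """Every novel cluster also satisfies the >=10 non-ingroup criterion."""
    rng = np.random.default_rng(77)
    crit = Criterion("non-ingroup", 10)
    for _ in range(30):
        gt, config = random_gene_table(rng, max_orthogroups=25, max_proteomes=15)
        if not config.reference_proteomes:
            continue
        report = extract_novel(gt, config)
        for rec in report.records:
            for asm, clusters in rec.clusters.items():
                qualifying = qualifying_clusters_bruteforce(gt, config, crit, asm)
                assert set(clusters) <= qualifying
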