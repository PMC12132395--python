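"""Independent brute-force oracles and random-instance generators.

These deliberately avoid the implementation's machinery: the census oracle
loops over (source, criterion, orthogroup, entry) with list membership only,
and the ORF oracle enumerates every ATG..stop span in every permitted frame.
"""

from __future__ import annotations

import numpy as np

from orthocensus.census import Criterion, GeneLevelTable
from orthocensus.coding import OrfParams
from orthocensus.formats import SpeciesGroupConfig

STOPS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def census_bruteforce(
    gene_table: GeneLevelTable,
    config: SpeciesGroupConfig,
    criteria,
) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    sources = [p for p in gene_table.proteomes if p in config.conspecific]
    for source in sources:
        for crit in criteria:
            seen: list[str] = []
            for membership in gene_table.orthogroups.values():
                n = 0
                for p in gene_table.proteomes:
                    if crit.group == "conspecific-others":
                        in_group = p in config.conspecific and p != source
                    elif crit.group == "non-conspecific":
                        in_group = p not in config.conspecific
                    else:
                        in_group = p not in config.ingroup
                    if not in_group:
                        continue
                    cell = membership.get(p, [])
                    if config.counting_unit == "species":
                        if len(cell) > 0:
                            n += 1
                    else:
                        n += len(cell)
                if n >= crit.min_members:
                    for entry in membership.get(source, []):
                        if entry not in seen:
                            seen.append(entry)
            counts[(source, crit.name)] = len(seen)
    return counts


def qualifying_clusters_bruteforce(
    gene_table: GeneLevelTable,
    config: SpeciesGroupConfig,
    crit: Criterion,
    source: str,
) -> set[str]:
    """Distinct entries of ``source`` in orthogroups satisfying ``crit``."""
    out: set[str] = set()
    for membership in gene_table.orthogroups.values():
        n = 0
        for p in gene_table.proteomes:
            if crit.group == "conspecific-others":
                in_group = p in config.conspecific and p != source
            elif crit.group == "non-conspecific":
                in_group = p not in config.conspecific
            else:
                in_group = p not in config.ingroup
            if in_group:
                cell = membership.get(p, [])
                n += (1 if cell else 0) if config.counting_unit == "species" else len(cell)
        if n >= crit.min_members:
            out.update(membership.get(source, []))
    return out


def longest_orf_bruteforce(sequence: str, params: OrfParams):
    """All ATG..stop spans in all permitted frames, best by (len, strand,
    start, frame). Returns (protein_len, strand, nt_start, nt_end, frame)
    or None."""
    seq = sequence.upper()
    strands = [("+", seq)]
    if not params.stranded:
        strands.append(("-", seq.translate(_COMPLEMENT)[::-1]))
    best = None
    for si, (strand, s) in enumerate(strands):
        for frame in range(3):
            codons = [
                s[i : i + 3] for i in range(frame, len(s) - 2, 3)
            ]
            for i, codon in enumerate(codons):
                if codon != "ATG":
                    continue
                for j in range(i + 1, len(codons)):
                    if codons[j] in STOPS:
                        plen = j - i
                        if plen >= params.min_protein_length:
                            key = (-plen, si, frame + 3 * i + 1, frame)
                            if best is None or key < best[0]:
                                best = (
                                    key,
                                    (
                                        plen,
                                        strand,
                                        frame + 3 * i + 1,
                                        frame + 3 * j + 3,
                                        frame,
                                    ),
                                )
                        break
    return None if best is None else best[1]


def random_dna(rng: np.random.Generator, max_len: int = 2000) -> str:
    n = int(rng.integers(1, max_len + 1))
    letters = np.array(list("ACGTN"))
    probs = [0.245, 0.245, 0.245, 0.245, 0.02]
    return "".join(letters[rng.choice(5, size=n, p=probs)])


def random_gene_table(
    rng: np.random.Generator,
    max_orthogroups: int = 50,
    max_proteomes: int = 25,
) -> tuple[GeneLevelTable, SpeciesGroupConfig]:
    """A random collapsed table plus a compatible nested group config."""
    n_prot = int(rng.integers(4, max_proteomes + 1))
    proteomes = [f"P{i}" for i in range(n_prot)]
    # nested group sizes, leaving >= 1 outgroup proteome for required_species
    k_focal = int(rng.integers(1, max(2, n_prot - 2)))
    k_focal = min(k_focal, n_prot - 3) if n_prot > 3 else 1
    k_focal = max(1, k_focal)
    k_consp = int(rng.integers(k_focal, n_prot - 1))
    k_in = int(rng.integers(k_consp, n_prot))
    config = SpeciesGroupConfig(
        proteomes=tuple(proteomes),
        focal_assemblies=frozenset(proteomes[:k_focal]),
        conspecific=frozenset(proteomes[:k_consp]),
        ingroup=frozenset(proteomes[:k_in]),
        required_species=proteomes[-1],
        counting_unit="species" if rng.random() < 0.5 else "proteins",
    )
    n_og = int(rng.integers(1, max_orthogroups + 1))
    orthogroups = {}
    for g in range(n_og):
        membership = {}
        for pi, p in enumerate(proteomes):
            if rng.random() < 0.5:
                membership[p] = []
                continue
            k = int(rng.integers(1, 4))
            if pi < k_focal:
                # cluster IDs from a small per-assembly pool -> repeats
                # across orthogroups, none within a cell
                pool = [f"{p}_c{i}" for i in range(8)]
                picks = rng.choice(8, size=min(k, 8), replace=False)
                membership[p] = [pool[i] for i in picks]
            else:
                membership[p] = [f"{p}_og{g}_m{i}" for i in range(k)]
        orthogroups[f"OG{g:04d}"] = membership
    table = GeneLevelTable(
        proteomes=proteomes,
        orthogroups=orthogroups,
        focal=config.focal_assemblies,
    )
    return table, config
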