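# Methods

## The census model

The unit of counting is the gene cluster: a group of overlapping aligned
transcripts treated as one locus by transcript-clustering annotation
pipelines. Because one cluster typically codes for several isoform
proteins, protein-level orthogroup membership over-counts genes; the first
step therefore replaces every focal-assembly protein in an orthogroup cell
by its cluster ID and deduplicates in first-occurrence order. Cells of
non-focal proteomes (the reference annotation, ingroup and outgroup
species) are left verbatim.

Proteomes are partitioned by declared configuration into nested groups —
focal assemblies ⊆ conspecific ⊆ ingroup ⊆ all proteomes — and the census
evaluates, per censused source *s*, five membership predicates of
increasing evolutionary distance:

| criterion | group relative to *s* | threshold |
|---|---|---|
| conspecific_others_ge1 | conspecific \ {s} | ≥ 1 |
| non_conspecific_ge1 / _ge10 | outside conspecific | ≥ 1 / ≥ 10 |
| non_ingroup_ge1 / _ge10 | outside ingroup | ≥ 1 / ≥ 10 |

A source's count under a criterion is the number of *distinct* entries of
that source appearing in at least one qualifying orthogroup; a cluster that
(after collapse) spans several orthogroups is counted once and logged,
since the counts are of clusters, not of rows. Censused sources are all
conspecific proteomes: the focal assemblies by cluster ID and the reference
annotation by its own entries, so the reference appears as a fourth column
beside three assemblies and the collapse asymmetry between them is visible
in one table.

Group counts default to **distinct species** (a proteome contributes at
most 1 regardless of how many paralogs it holds); a `proteins` counting
unit is a configuration switch that sums member entries instead. The
"at least one other conspecific member" criterion is implemented as ≥ 1
member from a conspecific source other than the censused one — the
censused cluster itself is always a member, so a self-inclusive reading
would make the criterion vacuous.

Novel-gene extraction inverts the reference requirement: it returns
orthogroups with ≥ 1 cluster in *every* focal assembly, zero members in
every reference proteome, ≥ `min_outgroup` (default 10) non-ingroup
members, and ≥ 1 member of a designated required outgroup species. The
required species pins the candidates to deeply conserved genes (the study
design uses *Drosophila melanogaster*), filtering lineage-specific
expansions out of the "missing from the reference" list. Every novel
orthogroup necessarily satisfies the ≥ 10 non-ingroup census criterion, so
the novel set is a subset of the most stringent census, assembly-wise.

## Coding classification

Transcripts are called coding by a longest-ORF scan with a minimum protein
length (default 100 aa), sense strand only by default, under the universal
nuclear code. Only complete ORFs — ATG-initiated and stop-terminated —
compete; this is deliberately conservative:

* ORFs running off the 3' end are never reported, so truncated transcripts
  do not inflate coding calls.
* 5'-partial ORFs (a frame-initial stop-free prefix with no ATG) are
  available behind `allow_5prime_partial` and are off by default.
* Codons containing N translate to 'X' unconditionally — even where the
  residue would be unambiguous — and never act as start or stop, keeping
  the call invariant under masking.
* Ties between equal-length ORFs are broken by strand (sense first), then
  smaller start coordinate, then lower frame index. The scan keeps only
  the earliest ATG per stop-delimited segment, which provably contains the
  maximum; a brute-force enumeration of all ATG→stop spans serves as the
  test oracle.

Coordinates are 1-based and inclusive everywhere in the package; for
antisense calls they refer to the reverse complement of the transcript.

## Annotation transfer

For each transcript feature carrying a `cluster` attribute, the transfer
step appends one `<Species>_ortholog` attribute per configured species,
whose value is the FASTA header (`protein_id description`) of the *first
protein listed* for that species in the cluster's orthogroup, or the
literal `none` when the species is absent or the cluster is unclustered.
First-listed means file order in the orthogroup table cell. Values are
percent-encoded per the GFF3 attribute grammar on write and decode back
verbatim; feature count, order, coordinates and pre-existing attributes
are untouched. Gene, exon and CDS features are not annotated — the
annotation belongs to the transcript record.

## The synthetic scenario generator

The generator emulates the *data shape* a multi-assembly re-annotation
produces, not its sequences: an orthogroup table with one orthogroup per
gene family, per-proteome protein FASTA, per-assembly transcript FASTA and
GFF3 intervals, a cluster map and a group config. Each family is present
once in every proteome unless an event modifies it:

* **duplication** (prob. `p_focal_duplication`, default 0.2): two clusters
  per focal assembly, two reference entries;
* **missing-in-reference** (`p_missing_in_reference`, 0.05): empty
  reference cell — the planted target of novel-gene extraction;
* **paralog collapse** (`p_collapse_in_reference`, 0.5 of duplicated
  families): both focal paralog clusters but a single reference entry, so
  the reference census gains one where the assemblies gain two;
* **pseudogene** (`p_pseudogene`, 0.05): a premature stop planted at an
  assembly-specific position in one designated copy, with fragment lengths
  drawn without replacement from 40–160 aa so the intact-ORF length
  *differs between assemblies* and straddles the 100-aa threshold; copies
  below it drop out of the proteome and hence the orthogroup table.

Default scale (500 families, 3 assemblies + reference, 5 ingroup, 15
outgroup species, ~300-aa ORFs) keeps every stage under a few seconds
while planting enough of each event (~100 duplications, ~20 missing, ~25
pseudogenes) for exact recovery to be a meaningful test.

Two constructions make the planted truth *exact* rather than approximate.
First, transcripts restrict UTRs and sense codons to the alphabet
{C, G, T}; adenine occurs only in the planted ATG and in stop codons, and
the codon following any stop is resampled if it begins "TG". A short case
check shows no other ATG can then occur in any frame, so the planted ORF is
the unique longest ORF by construction. Second, the expected census is
recomputed from event labels alone (`expected_census`), with plain loops
that never touch the emitted files or the census implementation — pipeline
versus expectation is a genuine two-route comparison, asserted as integer
equality.

`perturb_clustering` emulates the downstream effect of differential
pseudogene fragmentation on orthology inference: with probability
`p_split` per pseudogene family, the members of the assembly with the
shortest intact ORF move to a new singleton orthogroup. It takes the
scenario truth as an argument because the table alone cannot identify
which families bear pseudogenes or which assembly is divergent.

What the generator does **not** model: sequence similarity or a
substitution process (orthogroup membership is ground truth, not inferred),
introns and isoform structure beyond two identical-length isoforms per
cluster, unassigned proteins (every emitted coding protein is clustered),
reference-side pseudogene degradation, and contamination. Passing the
recovery tests therefore demonstrates that the bookkeeping from files to
counts is exact under known family structure — not that orthology
inference on real proteomes would be error-free.

## Numerical and design choices

* The orthogroup dialect joins cells with `", "` and tolerates bare commas
  on read; header row required; within-cell order is preserved because the
  first-listed rule depends on it.
* Degenerate inputs: an empty orthogroup table censuses to all zeros; an
  orthogroup containing only the censused source satisfies no criterion;
  a config without a reference proteome makes novel-gene extraction a
  configuration error rather than an empty result.
* Translation is table-driven from the universal code; Biopython's
  translator is used as an independent cross-check on unambiguous codons
  only, since its ambiguity resolution (e.g. CGN → R) differs from the
  strict N → X rule here.
* All randomness flows through one seeded NumPy generator per scenario; the
  same parameters yield byte-identical files.

## Known limitations

* Orthology inference itself is out of scope; the package consumes
  orthogroup tables and treats them as given.
* The species/proteins counting ambiguity for the ≥ 10 criteria is exposed
  as a switch (default: species) rather than resolved.
* Pseudogene planting touches one copy per assembly; scenarios where every
  copy of a duplicated family degrades are not generated.
* The GFF3 layer handles flat feature lists, not feature hierarchies; it
  is sufficient for transcript-level interval annotation, not for general
  GFF3 graph manipulation.
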