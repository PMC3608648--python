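# Methods

This note documents the models behind each stage, the parameters that
matter, the synthetic-data generators and what a green test does and does
not establish, and the numerical conventions.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Proteogenomic annotation validation

**Model.**  Sequencing reads carry coding signal independent of assembly
and gene calling.  Each read is translated in frames +1..+3 and, on the
reverse complement, −1..−3 under the standard codon table; codons containing
N translate to X.  Splitting each frame's translation at stop symbols gives
maximal stop-free *elements*; the split is lossless (elements rejoined with
single stop separators reproduce the frame translation), which is asserted
as a property test.  Elements are digested in silico with trypsin — cleave
C-terminal to K or R except before P — keeping products with at most
`missed_cleavages` internal uncleaved sites and lengths in
`[min_len, max_len]`.  The union over reads is the *naive* database; the
same digestion of the translated annotated CDS is the *annotated* database.
Observed peptides are classified by exact normalized lookup: `annotated`
(present in the annotated database, with precedence over the naive one),
`naive_unique`, or `unmatched`.

**Peptide normalization.**  I and L are isobaric and indistinguishable by
MS/MS, so both databases and all lookups collapse I→L by default
(configurable, but both databases must share one policy; a mismatch is an
error).  Peptides containing X are discarded: an observed peptide is a fully
determined residue string.

**Retention-time concordance.**  Observed retention time is regressed
(ordinary least squares) on the additive hydrophobicity
H(p) = Σ Rc(aaᵢ).  The default per-residue coefficient table is the
published 2004 SSRCalc set for 100 Å / 0.1 % TFA RP-HPLC; the table is a
pluggable argument everywhere because retention coefficients are
instrument- and gradient-specific.  A peptide is an *outlier* when its
absolute residual exceeds `outlier_sd` (default 3) standard deviations of
the residuals; everything else is *concordant*.  The fit requires ≥ 3
peptides with hydrophobicity variance.

**Anomaly adjudication.**  An anomaly ledger row is a category
(`missing_gene` or `truncated_gene`) plus the true interval and strand.
An anomaly is *supported* when at least `min_support` (default 2 — single
peptide identifications are weak evidence) distinct naive-unique,
retention-concordant peptide sequences map exactly (six-frame search,
normalization honored) to loci overlapping the anomaly interval by ≥ 1 base
on the anomaly's strand.  Frame agreement is not required for missing genes
(the frame is unknown to the annotator); strand agreement is.  The negative
verdict is *no evidence*, never *refuted*: absence of peptides cannot refute
a predicted gene (expression, detectability and sampling all intervene).

**Edge effects.**  A protein's N-terminal tryptic peptide appears in the
naive database only when a read starts at (or an in-frame stop immediately
precedes) the coding start; internal peptides only need a read covering the
peptide plus one flanking codon on each side.  The containment property
(naive ⊇ annotated) is therefore asserted for internal peptides short
enough to fit inside one read; the adjudication logic is unaffected because
it needs any two supporting peptides, not all of them.

## Functional-profile clustering

Counts of genes per functional term per genome form the profile matrix
(terms absent from a genome are zero-filled; term order lexicographic;
duplicate gene ids within a genome are an error).  Distances: `correlation`
(1 − Pearson r, range [0, 2]) or `euclidean`, optionally on row-normalized
("relative") counts so genome size drops out.  The defaults — correlation on
relative counts with average linkage — are the classic profile-clustering
defaults; the configuration the original analysis used is not recorded, so
all three linkage choices and both metrics are exposed.  Clustering is
implemented in-package because the contract requires a deterministic
smallest-label-pair tie-break and input-order invariance; it is cross-checked
against the scipy implementation on tie-free random matrices.  Merge heights
are monotone under the supported linkages, so cutting the k−1 highest merges
yields k clades; labels are integers ordered by smallest member.  Newick
export uses the half-height convention (node height = merge height / 2) so
leaf-to-leaf path length equals the merge height and branch lengths read
like a phylogram.

## Pathway scoring and concordance

A pathway definition is a conjunction of disjunctive term groups; scoring is
pure boolean evaluation, verified against exhaustive enumeration over all
term subsets for small definitions and monotone by construction (removing
terms can never turn "−" into "+").  Pathway definitions ship as an editable
YAML with abstract term keys (no external ontology needed): the glycolysis
backbone (with a pyruvate-kinase / PPDK disjunction), a cellobiose
hydrolysis group (β-glucosidase families GH1/GH3/GH4/GH5 or cellobiose
phosphorylase), the five-gene Leloir cluster for galactose,
mannose-6-phosphate isomerase, *xylAB* plus the non-oxidative pentose
phosphate entry for xylose, the three-gene arabinose cluster, and the
five-gene glucuronate cluster.

Concordance compares a "+"/"−" prediction matrix cell-by-cell with a
phenotype table in {"+", "−", "NR"}: agree, disagree (both directions of
conflict count equally), or not_reported; the three counts partition
genomes × substrates.  The published 11-genome × 7-substrate prediction and
phenotype matrices are packaged as TSV fixtures encoded cell-by-cell from
the printed table (unicode minus variants normalized); they are input data,
not code.  The per-cell gene evidence behind the published "+" calls lives
in supplementary material that is not redistributable, so the packaged
matrix tests the concordance operation directly, while
`analysis/04_score_pathways.py` additionally reconstructs term sets that
reproduce the prediction matrix through the scoring path.  The CAZyme
inventory (one row per genome/locus with a modular architecture string and a
localization label) is likewise a packaged fixture; the one entry described
in prose as cell-bound is labelled `cell-bound`, all others
`extracellular`.

## Phylogenetics

p-distances use pairwise deletion: per pair, columns where either sequence
has a gap are dropped; zero comparable columns is an error.  The Poisson
correction `d = −ln(1 − p)` (computed as `−log1p(−p)`) assumes equal
substitution rates across sites and no back-substitution bias; `p ≥ 1` is
saturated and an error.  Neighbor joining follows Saitou–Nei with the
standard Q criterion; ties break on the smallest (label, label) pair, where
a cluster's label is its smallest leaf name, making output deterministic
and input-order invariant.  Negative branch-length estimates are clamped to
zero with the deficit transferred to the sister branch (pair distance
preserved); a flag to allow negative lengths is deliberately not offered —
the clamping convention is the package's single behavior.  The tree is
unrooted, represented with a trifurcating root.  On additive matrices NJ is
exact; this is tested against an independent path-length construction
oracle and cross-checked against scikit-bio's implementation.

Bootstrap replicates resample alignment columns with replacement, rebuild
distances and the NJ tree, and count, for each internal split of the
full-data tree (not a consensus tree), the fraction of replicates containing
it.  Replicates with an undefined pairwise distance are skipped and counted
with a logged warning; supports are percentages of *successful* replicates.
The original analysis used 10,000 replicates; the desk-scale default here is
100–1,000, and the number is a parameter.

Sequence clusters are maximal subtrees whose defining split meets the
support threshold.  Because the NJ trifurcation lands arbitrarily, the walk
runs on a midpoint-rooted copy of the tree (so a long internal branch
separates families at the root) while supports are looked up by split,
which re-rooting preserves; trivial splits count as 100.  Leaves under no
supported subtree become singletons.

## Synthetic data: what it emulates, and what not

Every generator is a pure function of its spec, which carries its own seed
(numpy `default_rng`); repeated calls are byte-identical.

* **Genome** (`GenomeSpec`, defaults 3 contigs / 100 kb / 30 CDS of
  300–1500 bp / G+C 0.3435): background bases i.i.d. at the G+C target
  (matching the deposited genome's 34.35 %); planted CDS get an ATG start, a
  terminal stop, and single-base edits removing internal in-frame stops, so
  the empirical G+C stays within binomial sampling error of the target.
  CDS are non-overlapping, on either strand, greedily packed
  (largest-first) into contigs; infeasible packing is an error.  Real
  genomes have operons, codon bias and repeats; none are modeled.
* **Annotation corruption** (`AnomalySpec`): `round(drop_fraction·n)` CDS
  removed, `round(truncate_fraction·n_survivors)` clipped at the 3′ end by
  `truncate_amount` of their length rounded down to whole codons.  Rounded
  deterministic counts make the stated-count examples exact.  The ledger
  records every change with its true interval, standing in for an external
  annotation-QC report; ledger + survivors reconstruct the truth exactly.
* **Reads** (`ReadSimSpec`, defaults 150 bp / 30× / error-free):
  `ceil(coverage·L/read_length)` substitution-only reads uniform over both
  strands.  The real data mixed long pyrosequencing reads (~626 bp, known
  for homopolymer indels) with short paired-end reads; indels, quality
  strings and coverage bias are deliberately out of scope — the naive
  database reads frames within single reads, and an indel would merely
  fragment an element.
* **Observed peptides** (`PeptideObsSpec`, defaults detect 0.8 / slope 1
  min per hydrophobicity unit / intercept 5 min / noise SD 0.5 min /
  5 % outliers): a deterministic `round(detect_fraction·N)` sample of the
  true tryptic peptides, RT linear in hydrophobicity with Gaussian noise;
  outliers get RT uniform over the observed range and keep a ground-truth
  flag.  Real detectability depends on abundance, charge and length; the
  uniform Bernoulli model is a simplification, so a green recovery test
  establishes the adjudication logic, not instrument realism.
* **Profiles** (`CladeProfileSpec`, defaults clades 6/2/3 — the reported
  clade sizes — 200 terms, within-clade SD 1, between-clade SD 5, centroid
  mean 10): clade centroids `max(0, N(10, between))` per term, genome rows
  centroid + `N(0, within)`, rounded and truncated at zero.  The 5:1
  separation ratio is the regime the recovery criterion states; recovery at
  that ratio says nothing about weaker structure.
* **Protein families** (`FamilySimSpec`, default guide tree two trios
  separated by a 0.8-substitutions/site internal path, 200 residues): root
  uniform over 20 residues; along a branch of length d each site
  substitutes with probability 1 − e^(−d), replacement uniform over the
  other 19.  This is exactly the process the Poisson correction inverts (up
  to back-substitution, handled by comparison with a Monte-Carlo oracle of
  the same update rule); no rate heterogeneity, no indels.

## Numerical conventions

Coordinates are 0-based half-open internally; GFF3 I/O converts to/from
1-based inclusive and accepts only single-exon CDS with explicit strand.
TSVs are tab-separated, header mandatory, no quoting; floats are written
with 6 significant digits everywhere so outputs are byte-stable, which the
pipeline manifest (config hash + SHA-256 per output) verifies across runs.
The run-level seed derives per-stage seeds by small offsets and stays below
2³¹.

## Known limitations

* No MS/MS spectrum scoring or FDR control: observed peptide lists are
  inputs, matching is exact string lookup.
* Genome assembly, external annotation services, HMM-based family
  assignment, localization prediction and transporter classification are
  out of scope; their outputs are modeled as inputs (ledgers, term tables,
  architecture/localization fixtures).
* The deposited-assembly statistics check needs a 2.5 Mb download and so
  cannot run offline; `analysis/06_deposited_genome.py` performs it when
  network access is available.
* Real-data headline counts (unique-peptide totals, anomaly counts, CAZyme
  inventories per strain) depend on raw data that is not redistributable
  here; the test suite substitutes planted-ground-truth recovery at stated
  scales.
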