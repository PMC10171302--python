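# Methods

## Problem setting

Fermentation strains (lactic acid bacteria, *Bacillus subtilis*, and — as a
comparison group — Enterobacteriaceae) differ widely in which antinutritional
factors (ANFs) they can degrade. Given a collection of annotated genomes, the
pipeline answers three questions: which ANF-metabolism genes does each genome
carry, how is that gene content structured across the collection (pan-genome
partition, gene-content clustering), and which small set of strains would, as
a mixed starter culture, cover the most ANF classes and genes.

## Detection model

A catalog partitions screened enzymes into ANF **categories** (eight in the
default catalog: phytate degradation, myo-inositol production, tannin
degradation, phenolic compounds, lectin metabolism, trypsin-like proteases,
saponin degradation via β-glucuronidase, α-GOS degradation via
α-galactosidase). Each enzyme carries lowercase annotation keywords, optional
EC numbers (metadata only — matching never depends on them, so unverifiable
EC assignments cannot change results), and optional reference protein
sequences.

A protein is reported as a hit for an enzyme when either evidence route
passes, with at most one hit per (protein, enzyme):

* **keyword** — some keyword is a case-insensitive substring of the
  whitespace-normalised product annotation;
* **homology** — the optimal global alignment (Needleman–Wunsch/Gotoh,
  BLOSUM62; a gap of length L costs 11 + L) against one of the enzyme's
  references reaches `min_identity` (default 0.40, identical columns / total
  alignment columns) and `min_coverage` (default 0.70) on **both** sequences
  (residue-aligned columns / sequence length). The best-scoring passing
  reference is kept.

Alignment is attempted for proteins passing a keyword prefilter (or carrying
an empty product); `full_scan=True` aligns everything, which is how the
planted-gene benchmarks are run. The thresholds are conventional
ortholog-screen values; the screen has no E-value model (alignments are
scored, not statistically calibrated), and no HMM profiles.

Keyword promiscuity is tolerated by design: a product such as "trypsin-like
serine protease" matches both the trypsin and the TLP enzyme entries and
yields two keyword hits on one protein. Enzyme-mode matrices absorb this
(presence is per enzyme), and category-level tallies are unaffected.

### Exact pre-alignment filters

Most pairs in a screen are unrelated, and the Gotoh traceback is the cost
bottleneck, so two provable upper bounds are checked first; a pair is skipped
only when it cannot reach the thresholds, so filtered results equal brute
force exactly (verified against an all-vs-all oracle in the tests):

* **coverage bound**: at most `min(la, lb)` columns align
  residue-to-residue, so the longer sequence's coverage is at most
  `min(la, lb) / max(la, lb)`;
* **identity bound**: the matched columns of any alignment appear in both
  sequences in the same order, i.e. they form a common subsequence, so
  matches `m ≤ LCS(a, b)`; total columns are at least `max(la, lb)`, hence
  `identity ≤ LCS(a, b) / max(la, lb)`. The LCS length is computed with the
  Allison–Dix bit-parallel recurrence with per-subject character masks
  cached. For unrelated protein pairs this bound sits near 0.32–0.37,
  comfortably below the 0.40 default threshold, which is what makes
  full-scan screening desk-scale.

## Orthology and pan-genome partition

Between two genomes, proteins x and y are orthologs (BBH) when each is the
other's best-scoring partner among partners passing the identity/coverage
thresholds; ties are resolved by higher identity, then lexicographic protein
id, so the best partner is always unique and runs are deterministic. The
thresholds are applied **before** best-hit selection (a below-threshold
partner cannot shadow a passing one). Multi-genome ortholog clusters are
connected components of the union of all pairwise BBH graphs — single
linkage, the simplest defensible choice; stricter clique-based clustering
would split promiscuous families but is not offered in v1.

Clusters are classified by the number of *distinct* genomes they span:
core (all), singleton (one — including a cluster of several paralogs from
one genome), dispensable (in between). The counts always sum to the total
cluster count, and cluster sizes always sum to the total protein count;
both conservation laws are asserted in the acceptance tests.

## Matrices and profiles

Enzyme-mode features are catalog enzymes (paralogs collapse to one cell);
cluster-mode features are ortholog clusters containing at least one hit
(paralogs stay separate only if BBH separates them). A cluster inherits the
category of its member hits; if members disagree (possible with promiscuous
keywords), the category of the highest-scoring member wins and a warning is
logged. Per-genome profiles count distinct features per category, the total,
and the number of categories covered. Group tallies ("x of n genomes of this
group carry ≥ m features of category c") default to m = 1.

## Gene-content clustering

Distances between genome rows are Jaccard by default — shared absences carry
no signal in sparse gene-content data — with simple matching as the
alternative. UPGMA agglomerates with the size-weighted Lance–Williams update
`d(i∪j, k) = (nᵢ d(i,k) + nⱼ d(j,k)) / (nᵢ + nⱼ)`; node height is half the
merge distance, so the tree is exactly ultrametric and the cophenetic
distance between two leaves reproduces their merge distance. Determinism
conventions: merge ties go to the lexicographically smallest pair of cluster
representatives (a cluster is represented by its smallest leaf label), and
the child holding the smaller representative is placed first, which fixes
the heatmap leaf order. Newick branch lengths are parent-child height
differences. Equivalence with a per-step full-recomputation oracle and with
scipy's average linkage is asserted in the tests.

## Consortium selection

A consortium S is scored by its union profile (element-wise OR of the
selected rows): categories covered and distinct genes. The default objective
is lexicographic (categories, then genes) because "best mixture" has two
natural readings — most ANF classes neutralised, or most distinct genes
contributed — and the lexicographic order honours both; a genes-only switch
is provided. Exhaustive search enumerates subsets in lexicographic genome-id
order (cap 2,000,000 subsets), returns the first optimum, and reports all
ties. Greedy adds the genome with the largest marginal (categories, genes)
gain, breaking ties by genome id; it carries the classic (1 − 1/e)
max-coverage guarantee, asserted against exhaustive search on randomized
instances. Consortium analyses default to cluster-mode matrices, where
"genes" means distinct ortholog clusters.

## Synthetic collections

The generator emulates group-structured presence patterns: per
(taxon group, category) a probability that a genome carries the category;
carriers plant `1 + Binomial(max_extra, p_extra)` copies, each a reference
protein with independent per-residue substitutions at `mutation_rate`
(no indels, so expected identity to the reference is ≈ 1 − rate and the
acceptance math stays closed-form). Decoys are uniform-random sequences of
length 80–400 with product "hypothetical protein"; 25 per genome by default —
enough to exercise false-positive rejection while keeping all-vs-all
orthology desk-scale. Randomness is a per-genome substream seeded by
(seed, crc32(genome_id)), so output is byte-identical across runs and
independent of genome insertion order.

The four-group layout fixes the qualitative pattern of the study system:
phytase universal in the Bacillus-like group and absent from the
Lactobacillus- and Pediococcus-like groups (which instead carry myo-inositol
pathway genes); lectin, tannase and β-glucuronidase absent from the
Bacillus- and Pediococcus-like groups; fractional presence elsewhere taken
from the observed group tallies (e.g. Enterobacteriaceae phytase
91/150 ≈ 0.607, α-Gal 81/150; Lactobacillaceae myo-inositol 119/155, α-Gal
95/155). The Pediococcus myo-inositol probability (0.75) and the copy-number
distributions are modelling choices in the same spirit: common categories get
more extra copies (myo-inositol and α-Gal up to 7 per genome) than rare ones.

**What the synthetic model does not emulate** — and hence what passing
benchmarks do not show about real data: no shared housekeeping background
(so the synthetic "core genome" is empty and partitions are
singleton-dominated), no indels or domain shuffling, no annotation noise
(planted products always contain the keyword in the annotated regime), no
horizontal transfer, and decoys are compositionally uniform rather than
proteome-like. Recovery rates on real genomes will depend on annotation
quality and true divergence and will be lower than the near-perfect recovery
seen at 5% synthetic divergence.

## Numerical and degenerate-input choices

* Jaccard distance of two all-zero rows is defined as 0 (identical absence).
* Translation uses the bacterial code (table 11); ambiguous codons and
  internal stops map to X, terminal stops are stripped; CDS lengths not
  divisible by three are truncated with a logged warning.
* A single-leaf tree renders as `label;` in Newick; labels with reserved
  characters are quoted.
* Screening an empty genome returns an empty hit list; a matrix with no hits
  is a zero-width matrix and profiles report zero coverage.
* All tie-breaks (best reference, BBH partner, UPGMA merges, consortium
  enumeration, greedy picks) resolve by score, then identity, then
  lexicographic id — never by hash or insertion order.

## Problem sizes

The test suite and the reproduction script size their simulations for a
single CPU: recovery benchmarks run 20 (tests) or 5 (script) collections of
40 genomes; group tallies run one full-size collection of 351 genomes
(37/155/9/150 per group, keyword-prefiltered screening); all-vs-all BBH
clustering and consortium selection run on 20-genome subsets, since pairwise
orthology is quadratic in collection size. Oracle-equivalence checks use 200
random instances each for UPGMA (≤ 7 leaves) and consortium selection
(6–12 genomes × 10–30 features, k ≤ 3).

## Known limitations

* BBH + connected components is a stand-in for heavier orthology pipelines;
  it has no synteny awareness and single linkage can chain clusters.
* The default catalog's reference sequences are synthetic placeholders;
  real screens should load a catalog with curated references.
* Headline counts from any specific published collection are not reproduced
  here: they depend on the exact genome set, annotation source and ortholog
  criteria of that study. The pipeline reproduces the *patterns* under
  controlled synthetic conditions instead.
* No virulence/AMR screening: candidate consortia (especially anything
  Enterobacteriaceae-like) still need safety assessment.
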