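# Methods

This note documents the models, conventions, and numerical choices behind
`cladeprimer`, and what the synthetic benchmarks do and do not demonstrate.

## Distances and trees

Pairwise divergence is the Jukes-Cantor estimate d = −(3/4) ln(1 − (4/3)p),
where p is the proportion of differing sites under **pairwise deletion**:
only columns in which both sequences carry a concrete base (A/C/G/T) enter
the numerator and denominator; gaps and degenerate codes are excluded. The
JC model assumes equal base frequencies and a single exchange rate — a
deliberate simplification matched by the sequence simulator, so simulated
divergences are estimated without model misspecification. Pairs at or past
the correction's domain boundary (p ≥ 3/4) raise a saturation error in the
scalar API; matrix construction instead caps them at a configurable distance
(default 5.0 substitutions/site) and sets a per-pair saturation flag, which
keeps distant-phylum pairs usable in tree building.

Neighbor joining follows the Studier–Keppler formulation. Ties in the Q
criterion are broken toward the lowest index pair, making tree construction
deterministic for a fixed input order. Negative branch-length estimates are
clamped to zero with the deficit transferred to the sister branch, so the
path length between the two joined nodes is preserved. On additive inputs
NJ reproduces the generating tree's bipartitions and path lengths exactly;
this is tested against brute-force path matrices and against an independent
NJ implementation (scikit-bio).

Bootstrap support resamples alignment columns with replacement, rebuilds the
distance matrix and NJ tree per replicate, and reports for each internal
edge the percentage of valid replicates containing the same bipartition.
Replicates in which some pair has no comparable columns are skipped and
counted. Monophyly of a tip set is evaluated on the tree rooted at a
designated outgroup (midpoint rooting when none is given): the set is
monophyletic iff it is exactly the leaf set of one clade, and that clade's
support is reported.

## Iterative collection

The collection routine grows the target set from a labelled backbone
(seeds of the target taxon, references for the other groups, an outgroup).
Queries are processed in batches (default batch size 500). Within a batch
the working set is backbone + remaining queries; after each bootstrapped NJ
tree, every clade with support above the threshold (default 80%, strict
inequality) that contains at least one seed or previously collected target
and **zero** backbone non-target sequences donates its queries to the
collected set. Any supported clade qualifies, not only the smallest clade
containing all seeds: collection is per-sequence and robust to seed
paraphyly in individual replicates. Collected queries are removed from the
working set and the loop repeats until a round collects nothing, which
guarantees termination. After each batch, monophyly of the collected set
plus seeds is re-verified on the batch's combined alignment, and once all
batches are done, on the final combined alignment; the inner-loop tree is
re-bootstrapped every round rather than reusing supports.

Queries never collected are screened for placement stability: across the
final round's bootstrap replicates, each query votes for the backbone phylum
of its nearest backbone tip (tree path distance). If no phylum reaches the
stability threshold (default 50% of replicates), the query is reported as
unclassified rather than non-target. The stability rule is this package's
own operational criterion; the underlying idea — sequences near the root
with no reproducible affiliation stay unassigned — has no unique
formalisation, so the threshold is exposed in the configuration.

## Phylotypes, distance statistics, rarefaction

UPGMA (average linkage, via scipy) records merge heights on the distance
scale: two sequences merging at average distance d have cophenetic distance
d, so thresholds compare directly to JC distances. The species-level
phylotype cutoff is expressed as the JC distance equivalent to 2% sequence
dissimilarity, −(3/4) ln(1 − (4/3)·0.02) ≈ 0.0203. A raw cophenetic
threshold can be supplied instead; the identity-based default governs
because a "0.2 ↔ 98% similarity" equivalence is not internally consistent
on the JC scale (JC 0.2 corresponds to roughly 82% identity), and the 98%
species-level criterion is the scientifically meaningful one. Each
phylotype's representative is its medoid (minimum mean within-cluster
distance; ties resolved by longest degapped sequence, then lexicographic
id).

Group distance summaries are means ± sample SD over all within-group or
cross-group pairs; the SD is omitted below two pairs and singleton groups
have no intra estimate. The two-sample comparison uses Welch's unequal-
variance t-test. Rarefaction is the analytic individual-based form
E[S_n] = S_obs − Σ_i C(N−N_i, n)/C(N, n), computed with log-gamma functions
to avoid overflow; it is validated against Monte-Carlo subsampling.

## Word classifier

The classifier is the naive Bayes word-presence scheme of the RDP
classifier: training counts m(v,D) record how many taxon-D sequences
*contain* 8-mer v (presence, not multiplicity); the word prior
P_v = (n(v)+0.5)/(N+1) smooths the conditional
P(v|D) = (m(v,D)+P_v)/(M_D+1), so scores stay finite for unseen words.
Class priors are treated as constant, so classification maximises
Σ log P(v_i|D) over the query's word set. Queries are scored in both
orientations and the better orientation kept, making classification
invariant to reverse complementation; score ties go to the
lexicographically smallest label. Hierarchical labels (phylum/subgroup) are
trained flat at each rank independently. No bootstrap confidence is
attached to calls; the full per-taxon log-score vector is returned instead.

## Primer metrics

- **%GC** is computed over non-degenerate positions only (degenerate
  positions excluded from numerator and denominator); this is the only
  convention that reproduces published %GC values for degenerate primers.
- **Matching** is IUPAC-aware: a primer base matches a concrete subject base
  contained in its base set; degenerate subject bases match by set
  intersection (default) or subset containment (option). Both strands are
  searched (database records may be deposited in either orientation) and
  the default mismatch allowance is zero; all three knobs are configurable.
- **Coverage/tolerance** percentages use the whole group as denominator,
  including records that do not span the primer locus; a spanning-only
  interpretation can be recovered by pre-filtering the database.
- **Primer pairs** match a record when a forward-strand site of the forward
  primer lies upstream of a reverse-strand site of the reverse primer and
  the implied amplicon — inclusive of both primer footprints — is strictly
  longer than the minimum (default 400 nt).
- **Candidates** are all gap-free, ambiguity-free consensus windows in the
  length range (default 15–25 nt; the pipeline scenario uses 18–20), ranked
  by coverage minus maximum tolerance, then fewer self-structure
  violations, then 5' position. The ranking formula is this package's
  choice; only the final primer of the motivating study is public, not its
  ranking rule.
- **Thermodynamics** use the unified nearest-neighbour ΔH/ΔS parameter set
  with the 0.368·(N−1)·ln[Na+] entropic salt correction and
  Tm = 1000·ΔH / (ΔS_corr + R ln(C_T/4)) − 273.15, defaults 50 mM Na+ and
  250 nM primer. Degenerate primers are evaluated on their most stable
  expansion. Hairpins require a perfectly paired stem of ≥ 3 bp and a loop
  of ≥ 3 nt; self-dimers are ungapped antiparallel self-alignments with
  ≥ 3 contiguous pairs; both report the sum of stack free energies of the
  most stable arrangement, 0.0 when no structure qualifies. Published
  melting temperatures computed by closed-source tools under unspecified
  conditions are not reproduction targets.
- The consensus is majority-rule per column over concrete bases; ties
  become the IUPAC code of the tied set, columns that are majority-gap are
  masked from candidate enumeration, and report percentages are rounded
  half-up to one decimal.

## Synthetic data

The generator emulates the measured landscape of archaeal 16S data: clades
evolve by independent-site JC substitution down a random bifurcating tree
whose branch lengths are rescaled so the expected within-clade pairwise
distance equals the configured intra-clade divergence (default 0.08
substitutions/site); clade roots sit at (inter − intra)/2 from a shared
ancestor so between-clade tip distances average the configured inter-clade
divergence (default 0.28). Both defaults mirror the intra-group and
inter-phylum distances reported for the real database the workflow was
developed on. Planted conserved windows are copied verbatim into retaining
sequences (per-clade retention probability) and randomized elsewhere,
giving exact expected coverage/tolerance targets; the default pipeline
scenario plants a 19-nt target-specific window (95% retention in the
target clade) and an 18-nt universal window (100% retention everywhere)
that supplies the reverse partner for pair evaluation. A configurable
fraction of records is truncated to a partial length, encoded as terminal
alignment gaps. A fixed seed yields byte-identical FASTA.

What the generator does **not** emulate: indels and alignment error, rRNA
secondary-structure-constrained evolution, compositional heterogeneity,
chimeras, and rate variation across sites. Passing recovery tests therefore
demonstrate the correctness of the algorithms under their own model
assumptions — clean clade structure at realistic divergence scales — not
robustness to real-data artefacts such as misalignment or chimeric reads.

## Problem sizes and determinism

The default synthetic scenario is five clades of 60/45/45/40/40 sequences
(alignment length 1400 nt) plus an outgroup; six records per clade seed the
backbone, leaving 200 unlabelled queries, and trees are evaluated with 100
bootstrap replicates. These sizes keep a complete end-to-end run in the
low minutes on one CPU while preserving the divergence structure of the
motivating task; the classifier benchmark uses an independent five-clade
pool of 120 sequences split half/half into training and hold-out. All
randomness flows from a single integer seed through numpy Generators;
repeated runs with the same configuration produce byte-identical outputs,
and the pipeline manifest records every parameter so each report cell can
be recomputed by calling the owning module directly.

## Known limitations

- NJ is the only tree estimator; no likelihood-based confirmation is
  provided, so deep-branch placements inherit NJ's known distortions at
  high divergence.
- The unclassified-query rule depends on the backbone's phylum sampling;
  a sparse backbone can make placements look stable when they are not.
- Coverage denominators counting non-spanning records understate coverage
  on partial-length databases; use the length filter (default ≥ 1200 nt)
  upstream, as the workflow intends.
- Hairpin/dimer scoring considers perfect Watson-Crick stems only (no G·U
  or mismatched stems, no loop entropy), so it ranks self-structure
  propensity rather than predicting folding free energies.
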