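# Methods

This note records the models and conventions the package implements, the
parameters that matter, and the choices made where more than one
reasonable convention exists.

## Read QC

Three discard rules are applied with first-failing attribution in fixed
order: length < 200 nt, arithmetic mean Phred < 25, any non-ACGT
character. "Mean quality" is the arithmetic mean of the Phred scores, not
the mean error probability: the thresholds are stated as score averages
and are treated literally. Discard thresholds are strict inequalities, so
a read of exactly 200 nt with mean quality exactly 25.0 passes. No primer
or quality trimming is performed; reads are filtered as received.

## The alignment contract

Both reference assignment and de novo clustering reduce to one primitive:
the optimal Smith–Waterman local alignment under BLASTN-like affine
scoring (match +2, mismatch −3, gap open −5, gap extend −2; a gap of
length k costs open + k·extend). From that alignment,

- identity = 100 · matches / alignment columns (gap columns count);
- coverage = 100 · (q_end − q_start + 1) / query length (query coverage —
  references may be longer than reads, so subject coverage would be
  meaningless for ~700 bp amplicons against full-length entries);

and the dual criterion is coverage ≥ 80% and identity ≥ 97%, both
inclusive. Only the single best local alignment per pair is used — no
multi-HSP stitching. This is what removes chimeras: a 50/50 splice of two
divergent parents aligns to either parent across its full length at ~95%
identity (or to half of it at ~50% coverage), failing the criterion either
way.

Determinism: among equal-score alignments, traceback prefers match-state
continuation over vertical over horizontal gaps and prefers extending over
terminating; among co-optimal endpoints the smallest
(q_start, s_start, q_end, s_end) wins. The kernels are numba-jitted; an
independent plain-Python DP oracle (tests/oracle_align.py) implements the
same contract and is compared exhaustively on short random pairs, and
Biopython's `PairwiseAligner` cross-checks scores.

Performance: candidate pairs are pre-screened with edlib's banded infix
edit distance. A pair can pass the dual criterion only if the whole query
fits in the subject within L·[(1 − cov) + (1 − id)/id] edits (unaligned
flanks plus in-alignment edits), so the filter can only discard provable
failures; every surviving pair is confirmed by the full DP.

## Assignment and clustering

Assignment takes the best passing hit, ordered by score, then identity,
then lexicographically smallest accession — the multi-hit tie policy is a
package convention, since best-hit resolution is not uniquely determined
by the criterion itself. Granularity is the reference lineage label, so
several accessions sharing a label pool into one taxon.

De novo clustering is greedy centroid (UCLUST-style): dereplicated
sequences are processed by decreasing multiplicity, then decreasing
length, then lexicographic order (content-based, so clustering is
invariant to input read order), and each sequence joins the first centroid
it passes the criterion against (query = member), else founds cluster
"de novo_k". Greedy centroid was chosen over single-linkage because it is
deterministic, cheap, and guarantees every member satisfies the criterion
against its centroid; a transitive single-linkage mode is available behind
`linkage="single"`, and on well-separated families (≥ 10% between, ~1%
within) the two agree exactly. Cluster numbers are run-local identifiers,
not comparable across datasets. Centroid annotation against a local
labeled database uses laxer genus-level thresholds (coverage ≥ 80,
identity ≥ 90) with fallback "uncultured Glomeromycota".

## Community tables

Rarefaction is subsampling without replacement (multivariate
hypergeometric) to 8,000 reads per replicate; replicates below the depth
are retained unchanged and flagged rather than dropped, since the survey
design keeps a 2,492-read replicate. Presence in a (soil, time) cell
requires ≥ 10 reads in at least one of the five replicates and counts the
taxon once per cell. The abundance filter keeps taxa whose within-cell
median count exceeds zero (with five replicates, the third order
statistic; with an even number of available replicates the midpoint rule
applies). The presence rule is applied to rarefied tables (rarefy →
filter); the opposite order is equally defensible but is not what this
package does. Taxonomic rollups bin each taxon at its most specific
non-empty rank, jointly or separately for known and de novo taxa;
lineage-less taxa fall in "Glomeromycota (unresolved)".

## Diversity and ordination

Shannon entropy is in nats and Simpson is the Gini–Simpson index 1 − Σp²,
the phyloseq conventions. The rarefaction curve is the exact expectation
under draws without replacement, computed via log-gamma to avoid overflow;
it is non-decreasing, concave, and ends at the observed richness. Group
tests are one-way ANOVA (parametric) and tie-corrected Kruskal–Wallis with
the χ² approximation (nonparametric).

PCoA double-centers −D²/2 and eigendecomposes; axes with negative
eigenvalues (Bray–Curtis is not Euclidean-embeddable) are reported in the
spectrum but dropped from the coordinates, and proportions explained are
over the positive part. PERMANOVA uses the standard one-way pseudo-F on
within/between sums of squared distances with seeded label permutations
and p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm); 999 permutations by
default, so the smallest attainable p is 0.001. PERMANOVA is implemented
in-package because the surrounding libraries expose no seedable
permutation generator; scikit-bio's implementation serves as an
independent cross-check in the tests. Beta analyses run on the rarefied
per-replicate table (20 columns).

## Differential abundance

The heat-tree comparison aggregates counts over a root → family → genus →
leaf tree and reports, per node, log2((median_A + ε)/(median_B + ε)) with
ε = 0.5 (bounded effects with preserved sign when a median is zero) and an
exact two-sided Wilcoxon rank-sum p; nodes with p < 0.05 carry the sign of
the effect as a flag. Medians make the effect robust to a single aberrant
replicate by construction.

LEfSe is implemented in its single-level form (no subclass /
one-against-all stage): counts are converted to relative abundance × 10⁶;
features are screened by Kruskal–Wallis; p-values are Benjamini–Hochberg
adjusted (cutoff 0.05); survivors are scored over 30 stratified ⅔
bootstrap subsamples by fitting a linear discriminant on the single
feature and measuring the absolute gap between the two extreme group
means on the unit-normalized discriminant axis, which keeps the effect in
abundance units; the reported score is log10(max(effect, 1)) with cutoff
1.0. Features constant across all samples are excluded with p = 1.
Published LDA scores from interactive tools are treated as ordering
evidence only — this implementation guarantees that larger group
separations receive larger scores, not that absolute scores match any
particular tool's internals.

## Trouvelot colonization scoring

Class weights are fixed as the contract: intensity weights 0/1/5/30/70/95
for colonization classes 0–5 and richness weights 10/50/100 for
arbuscule (and vesicle) classes 1–3. With n_k fragments in class k of N
total: F = 100(N − n₀)/N; M = Σ w_k n_k / N; m = M·N/(N − n₀);
a = (100·mA₃ + 50·mA₂ + 10·mA₁)/100 where mA_j is the percentage of
colonized-part intensity contributed by fragments of arbuscule class j;
A = a·M/100; v and V analogously. All indices are scale-free in N,
A ≤ M always, and M is capped at 95 by the class-5 weight. Vesicles use
the same machinery as arbuscules. Group comparison is a per-index one-way
ANOVA with means ± SD.

## The simulator

The generator emulates the survey's structure: a mock database of
`n_ref_taxa = 12` random taxa of 600–800 bp enforced to ≥ 10% pairwise
divergence, of which 60% are species-level "known" entries (the assignment
database) and the rest genus-level uncultured taxa reachable only through
de novo clustering; a 1/rank base abundance profile; per-replicate
compositions drawn from a Dirichlet with concentration 120 around the
group target (a realistic between-replicate coefficient of variation of
~20–40% for mid-abundance taxa); multiplicative group effects — three
soil-effect taxa at 4-fold (alternating direction) and one time-effect
taxon at 4-fold — so ordination and differential tests have constructible
positives and nulls; reads of mean length 700 bp (SD 40) as reference
prefixes with 0.5% substitutions and 0.05% indels; 2% chimeras (uniform
breakpoint in the middle 30–70%), 2% off-target random sequences; and 1%
each of reads engineered to fail exactly one QC rule (truncation below
200 nt, qualities drawn from 15–24, a single N), which makes the QC
report's per-rule counts exactly recoverable. Replicate depths are drawn
uniformly from 2,000–12,000 so the below-depth rarefaction branch is
exercised. All draws flow from a single seeded generator; identical
configurations give byte-identical outputs.

What the simulator does not model: homopolymer-specific 454 miscalls,
flowgram artifacts, primer context, phylogenetically structured reference
divergence, and compositional correlations beyond the Dirichlet. Passing
recovery tests therefore demonstrates the algorithms are implemented
correctly under the stated noise model, not that the pipeline is robust
to every pathology of real pyrosequencing data.

## Problem sizes in the test and acceptance runs

The end-to-end checks run the full pipeline at reduced depth — 40–80
(noiseless) or 100–200 (noisy) reads per replicate across all 20
replicates, with full-length ~700 bp amplicons — and the oracle
comparisons use 200 random pairs of ≤ 30 nt plus planted clustering
problems of 30–42 sequences at 300 nt. These sizes keep the suites quick
on a single CPU while exercising every code path; the statistical
recovery targets (composition error, LEfSe sensitivity, calibration
bands) are computed at exactly these sizes.

## Known limitations

- The alignment stage is exact DP over all candidate pairs surviving the
  edit-distance screen; for databases of thousands of references a seeded
  word-index heuristic would be needed. The DP contract, not the speed,
  is normative here.
- Multi-hit assignment resolves by best hit, never by lowest common
  ancestor; reads matching references with different labels follow the
  score/identity/accession order.
- LEfSe subclass designs, E-values, Chao1/ACE, UniFrac, and NMDS are out
  of scope.
- The published survey's absolute taxon counts depend on its deposited
  reads and a non-distributed 3,803-sequence reference database, so the
  package validates against ground-truthed simulations and closed forms
  rather than attempting to reproduce those counts.
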