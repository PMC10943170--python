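# Methods

This note documents the models, statistics and design choices behind
`tcrgroups`, and what its synthetic-data tests do and do not establish.

## Convergence grouping

Grouping operates on productive CDR3β amino-acid sequences of length ≥ 6.
All sequence comparisons use the *interior* of the loop: by default the 4
N-terminal and 1 C-terminal residues are trimmed (`trim_n=4, trim_c=1`,
configurable). The rationale is structural — the membrane-proximal flanks
(canonically `CASS…F`) contact the MHC helices, while the loop apex
contacts the peptide — so convergence evidence is restricted to the apex.
The minimum CDR3 length of 6 guarantees a non-empty interior.

**Local motifs.** The sample's distinct CDR3β interiors are scanned for
k-mers (k ∈ {3,4} by default; 2-mers are indexed but not used by the
default search). A k-mer seen in x of n sample interiors is compared with
its presence rate q in a reference repertoire: fold = (x/n)/q, and the
enrichment p-value is the one-sided binomial tail P(X ≥ x),
X ~ Binomial(n, q). Counting is *presence* counting — an interior
containing a k-mer twice contributes one — so q is a per-sequence
probability and the binomial model is coherent. Defaults: minimum sample
occurrence 3, fold ≥ 10, p ≤ 10⁻³, mirroring the stringency of published
paratope-hotspot groupers. K-mers absent from the reference get the floor
rate 1/(N_ref + 1) rather than zero, which keeps fold finite and biases
against, not toward, calling motifs unseen in the reference. Gapped
(discontinuous) motifs are deliberately not searched: single-position
variability is already captured by the global route, and gapped k-mers
multiply the candidate space with no clear gain at the cohort sizes this
package targets.

**Global homology.** Identical-length sequences whose pairwise differences
are confined to one shared interior position form a cluster; the pattern
replaces that position with `%`. Sequences differing in a trimmed flank
never cluster — the flank is part of the (implicit) pattern identity even
though the display string shows only the interior.

**Assembly.** A group's members are all clonotype records whose CDR3β
satisfies the pattern, so identical sequences observed in different
samples are distinct members but count once toward "distinct CDR3β".
Groups with identical member CDR3β sets are deduplicated (local motifs
take precedence over global clusters); group ids are assigned in a
deterministic pattern order, so assembly is invariant to input record
order.

**Reference repertoire.** No third-party naive repertoire is bundled. The
caller supplies one, or generates a synthetic background with
`generate_reference`. A warning is emitted below 100 sequences; the
defaults use 2,000.

## Group statistics

With member category frequencies p_i (V genes, or CDR3 lengths), the
Simpson concentration Σp_i² measures bias; global groups have
length-Simpson exactly 1 by construction. Significance is by permutation:
draw the same number of records uniformly without replacement from the
whole dataset, recompute the statistic, and report
p = (1 + #{perm ≥ observed}) / (n_perm + 1). The add-one form keeps p in
[1/(n_perm+1), 1], and per-group seeds are spawned from one root seed so
results are reproducible bit for bit and independent of group order.

Clonal expansion uses the same estimator with observed statistic = summed
member clone counts and null = summed counts of a uniform same-size draw
of clonotype records. The null is deliberately a *clonotype* draw (not a
resampling of counts or of member numbers); this choice is recorded in
every run manifest. Note that the identical draw ties the observed sum, so
even a group holding the largest counts has expected p ≈ 1/C(n, m), not
the estimator floor.

HLA enrichment: for each two-field allele carried by ≥ 2 distinct member
patients, a one-sided Fisher exact test on (carrier vs non-carrier) ×
(in-group vs all other profiled patients). The ≥ 2 threshold avoids
singleton artifacts. Alleles are normalized to two-field resolution
(`B*44:02 → B*44`) before testing, because enrichment at finer resolution
is not identifiable at the cohort sizes involved.

At n_perm = 10,000 the permutation estimates agree with exhaustive
enumeration over all C(n, m) subsets within three binomial standard errors
(verified on datasets of ≤ 8 records); n_perm = 500–1,000 is ample for the
0.05 decision thresholds used by the filters.

## Filtering cascade and cohorts

High-confidence: ≥ 3 distinct CDR3β, ≥ 3 distinct patients, V-bias
p < 0.05. Clonal-expanded: expansion p < 0.05. Both inequalities are
strict — a group at exactly 0.05 is dropped. Tumor-infiltrating: every
member record from a tumor sample; a single NAT member reassigns the group
to the tumor/normal-common class. The three stages nest by construction.
Length-bias p is computed and reported but not filtered on by default (its
role overlaps the global-group definition).

Patients are stratified by carriage: CE ⇔ the patient appears in ≥ 1
clonal-expanded group, TI ⇔ in ≥ 1 tumor-infiltrating group. Because TI
groups are a subset of CE groups, TI ⇒ CE, and the five cohort views
satisfy |CE| = |TI| + |CE-nonTI| and |TI| + |CE-nonTI| + |nonCE| = N on
every input (enforced, not just documented).

Diversity is per sample: Gini–Simpson 1 − Σp_i² over clonotype count
frequencies with clonotype identity (CDR3β, V, J), the convention of
standard repertoire-analysis tooling. How to summarize patients with
multiple samples is left to the caller (the comparison helpers take an
explicit sample→patient map); the natural choice is the primary-tumor
sample. Cohort comparisons use Kruskal–Wallis across strata and two-sided
Wilcoxon rank-sum pairwise (exact distribution where sample sizes permit),
with the conventional star mapping (ns > 0.05 ≥ \* > 0.01 ≥ \*\* > 0.001 ≥
\*\*\* > 10⁻⁴ ≥ \*\*\*\*).

## Annotation, network, consistency

Annotation is an exact amino-acid match between any member CDR3β and a
tetramer reference entry; one match annotates the whole group, and all
matching entries are kept. The V gene and MHC allele of the reference
record are carried as attributes but do not gate the match — HLA context
is evaluated separately, which keeps the match criterion transparent and
the HLA concordance statistic an independent check rather than a built-in
tautology.

The group network has an edge whenever two groups share ≥ 1 identical
CDR3β (undirected, no self-loops). Tetramer consistency: among annotated
groups with at least one edge ("eligible"), the fraction with a *direct*
neighbor sharing an identical tetramer entry, reported to one decimal;
direct neighbors (not whole components) because the edge itself is the
evidence of shared specificity. With no eligible group the statistic is
reported as not applicable rather than 0 or 100.

Supertype concordance: supertype membership is a two-field prefix match
(any `A*02:xx` → `A*02`), optionally through an editable allele→supertype
map. For each supertype, among groups annotated by a tetramer of that
supertype, the percentage whose own significant HLA enrichments (p < 0.05)
include an allele of the same supertype; groups annotated only with other
tetramers provide the comparison percentage.

## Metadata enrichment

Per (group, attribute) with ≥ 2 group carriers: hypergeometric upper tail
P(X ≥ k) with universe N, attribute carriers K, group size n, group
carriers k; Benjamini–Hochberg across all tests of the same kind;
significant at adjusted p < 0.05. The default universe is the union of
patients carrying the tested groups (the tumor-infiltrating patient set),
since the question is which attributes distinguish groups *within* that
compartment; the whole cohort can be passed explicitly, and the choice is
recorded in the output manifest.

## Synthetic cohorts

The generator emulates: per-sample background clonotypes (`CASS` + random
interior + `F`, lengths 11–17 uniform, uniform residue usage, geometric
clone counts with mean ≈ 1.7, Poisson(30) clonotypes per sample), 20
patients with one tumor sample each and NAT samples for 25%, one HLA
allele per locus drawn from per-locus frequency pools (the remainder of
the frequency mass means "no call"), categorical subtypes and Bernoulli
gene mutations. Planted groups implant a dedicated 4-mer motif and a
shared V gene into 6 distinct member sequences spread over 4 patients;
tumor-only groups place members exclusively in tumor samples, shared
groups place at least one member in a NAT sample; expanded groups multiply
member counts by 10; HLA-restricted groups force the restricting allele
into their patients. The default planted set (two expanded tumor-only, one
of them A\*11-restricted; one expanded shared; one unexpanded tumor-only
and one unexpanded shared as nulls) gives the calibration suite both
signal and controls.

Uniform residue usage makes the background *more* permissive to spurious
k-mer enrichment than real repertoires (real interiors are biased, so a
uniform reference understates some k-mer rates); passing the specificity
test under this null is therefore conservative in that one respect. What
the synthetic tests do not show: robustness to V(D)J-rearrangement
sequence biases, sequencing-depth variation, real HLA linkage
disequilibrium, or repertoire sharing driven by public clonotypes rather
than antigen convergence. Results on real cohorts depend on the quality of
the supplied reference repertoire in exactly the way the fold/p thresholds
suggest.

Problem sizes were chosen so the whole calibration (20 seeds × ~790
records, n_perm = 500) completes in seconds while keeping every planted
effect at the scale the statistics are meant to detect (fold ≈ 15–20
motifs, 10× expansion against geometric-1.7 background counts).

## HLA genotype model

The HLA reader keeps one call per (patient, locus): multiple rows for the
same locus are treated as conflicting calls from repeated genotyping of
multi-sample patients, resolved by quality rank (pass > ambiguous > low
coverage) and then first occurrence (logged). This is a single-haplotype
simplification — heterozygous genotypes collapse to one allele per locus —
which is consistent at two-field resolution for the carrier/non-carrier
statistics computed here, and the simulator draws genotypes the same way.

## Numerical and degenerate-input conventions

Permutation p-values can never be 0 or exceed 1. Groups with < 2 members
are not scoreable (error). All-zero member counts give expansion p = 1
with a warning. Empty tetramer databases or missing HLA tables degrade to
"nothing annotated/enriched" with warnings, not errors. Filters reject
unscored groups by name. Readers validate required columns and fail with
the column name; rows lacking a CDR3 are skipped and counted. Ties in
HLA-call quality and in group deduplication are broken by first occurrence
to keep runs deterministic.

## Known limitations

- The grouping is CDR3β-only; paired-chain information is out of scope.
- The local-motif route depends on an explicit reference repertoire; none
  is bundled.
- Exact Fisher/hypergeometric tests are conditional on margins and
  conservative at small cohort sizes.
- The expansion null draws clonotypes uniformly, ignoring per-sample depth
  differences; strongly uneven sampling depth across samples could inflate
  expansion calls for groups concentrated in deep samples.
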