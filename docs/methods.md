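# Methods

`straindiff` analyzes inter-strain differential gene expression from
short-probe hybridization arrays, where sequence polymorphism between
strains corrupts individual probes. This note records the models,
estimators, numerical conventions and design choices behind each module,
and what the synthetic-data tests do and do not demonstrate.

## Probe-level model and the SFP/DE estimator

A transcript is interrogated by a probe set of P >= 3 probes, hybridized in
two strains A and B with n_A, n_B >= 2 replicate arrays (unequal counts
allowed). After quantile normalization, the model for the log2 intensity of
probe p in strain s, replicate r is

    y_{s,p,r} = g_s + a_p + sigma_p * 1[s = B, p in SFP] + eps_{s,p,r},

with gene level g_s, probe affinity a_p shared across strains, a
probe-specific single-feature-polymorphism (SFP) shift sigma_p caused by
sequence mismatch (not expression), and iid Gaussian noise. The quantity of
interest is delta = g_B - g_A; SFP probes must be identified and excluded
because their shift masquerades as differential expression.

The estimator iterates:

1. per probe, m_{s,p} = median over replicates; d_p = m_{B,p} - m_{A,p};
2. delta-hat = median of d_p over non-flagged probes. The median's 50%
   breakdown point makes delta-hat *exact* under arbitrary contamination of
   fewer than half the probes at zero noise (a tested invariant);
3. per probe, t_p = (d_p - delta-hat) / se with a two-sided p-value from
   Student t; flag probes with p < `sfp_alpha` (default 0.001, uncorrected:
   the per-probe stringency is chosen for probe universes of 10^5-10^6);
4. repeat 2-3 until the flag set stabilizes (at most 10 rounds);
5. if flagged probes reach half the set, the transcript is unmeasurable and
   no delta is reported.

**Pooled variance.** The standard error in step 3 pools the within-probe
replicate variances across the entire probe set:
se^2 = c(n_A) vbar_A / n_A + c(n_B) vbar_B / n_B, where vbar_s is the mean
over probes of the per-probe replicate variance (floored at 1e-6 so
zero-noise fixtures remain finite) and the Satterthwaite degrees of freedom
use the pooled component dfs P(n_s - 1). Pooling is justified because log2
array noise is approximately homoscedastic across the probes of a set, and
it is robust to SFPs: a probe-level shift is constant across replicates and
therefore does not inflate the within-probe variance. A per-probe Welch
statistic (df ~ 4 at 3v3 replicates) has only ~0.40 power against a -2 log2
shift at noise sd 0.25 and per-probe alpha 0.001; the pooled statistic has
power ~1.0 at the same operating point while holding the null false-flag
rate at alpha (both verified by simulation in the test suite).

**Median efficiency correction.** d_p is a difference of sample medians,
whose variance exceeds sigma^2/n by the factor c(n) = n Var(median of n
standard normals). The constants c(1..12) = 1, 1, 1.346, 1.193, 1.434,
1.288, 1.473, 1.345, 1.495, 1.383, 1.509, 1.410 were computed once by
numerical integration of the order-statistic densities and are hardcoded;
beyond n = 12 the asymptotic pi/2 is used. Without this correction the
null SFP statistic is overdispersed by ~16% at n = 3 and the false-flag
rate exceeds its nominal level.

**Expression summarization and DE call.** For a measurable fit, the
expression value per replicate array is the median over non-SFP probes, and
the per-strain expression value is the mean of those replicate summaries.
The DE p-value is a Welch two-sample t-test between the replicate summaries
(variance floored as above). A gene is DE only when all three criteria hold
strictly: p < 0.05, linear fold change 2^|delta| > 2.5, and log2 expression
value > 7 in at least one strain. "Highly expressed" always means strictly
greater than 7; "did not exceed 7" (the silent-gene clause) means <= 7, so
a value of exactly 7.0 counts as not expressed.

## Tissue atlases, silent genes and classification

A strain's atlas is a gene x tissue matrix of log2 expression values. A
gene is silent in strain S when its maximum over all of S's atlas tissues
is <= 7 while the other strain expresses it (> 7) in at least one tissue.
Silent genes are **global** DE genes — the difference is tissue-independent
— and are added to the DE set regardless of the per-tissue test outcomes,
which can miss them. DE genes detected in one or more homologous tissues
that are silent in neither strain are **changed-tissues** DE genes;
everything else is similar. A gene silent in both strains is outside the
highly-expressed universe and rejected as a validation error.

## Tissue-specificity index tau

    tau = sum_{i=1}^{N} (1 - x_i) / (N - 1),   x_i = value_i / max(value),

computed on log2 intensities with negative values clamped to 0. tau = 0
for uniform expression, 1 for single-tissue expression. The orientation
follows the index's defining boundary behavior; the source literature
contains a transcription of the equation with the complement taken once
more (1 - sum(...)), which contradicts that behavior and is not used. tau
on the log2 scale (not linear) is deliberate: typical housekeeping genes
then land in the 0.15-0.7 range rather than saturating near 1. An all-zero
vector has undefined tau; eligibility additionally requires max > 7.

The through-origin regression of changed-tissues DE counts on
tissue-specific gene counts uses slope = sum(xy)/sum(x^2) and the
uncentered R^2 = 1 - SS_res/sum(y^2) (the through-origin convention; the
centered formula can go negative and is not comparable).

## Array clustering and homologous tissues

Arrays are clustered on 1 - Pearson r between arrays over a set of
similarly-expressed genes (per-gene Z-scaled, sample sd). Ward linkage is
applied with the Lance-Williams recurrence directly on the unsquared
dissimilarities — the classical "ward.D" behavior of early R `hclust` —
because the squared-distance variant (ward.D2, scipy's `ward`) produces a
different tree; a `squared=True` switch provides the D2 variant, which is
cross-checked against scipy in the tests. Merge-height ties break on the
smallest leaf index for determinism. Cutting at height 0.75 partitions the
arrays; a tissue is homologous across strains when every required strain's
arrays for that tissue fall into one common cluster.

## Ortholog classification and Ka/Ks

CDS pairs are classified by a first-match cascade: coverage < 0.8 (edlib
edit-distance identity against the query) -> no ortholog; no ATG -> ORF not
detected; frameshift (length difference not a multiple of 3), internal
stop, lost terminal stop, or changed protein length -> different protein
length; then identical vs substituted protein.

Ka/Ks uses Nei-Gojobori (1986): per-codon synonymous site fractions
(stop-creating changes count as non-synonymous so sites sum to 3 per
codon), averaged over both sequences; substitution differences averaged
over all shortest mutational pathways with equal weights, excluding
pathways through stop codons (if every pathway is blocked, all are used);
Jukes-Cantor correction K = -(3/4) ln(1 - 4p/3) applied when p < 0.75,
otherwise the raw proportion is returned with a saturation flag. Codons
containing gaps or ambiguity codes are excluded pairwise. The ratio is
undefined at Ks = 0. Rate classes: conserved < 0.75 <= neutral < 1.25 <=
rapid. The implementation is verified against an independent brute-force
pathway enumerator on every codon pair with <= 2 differences and against
Biopython's NG86 routine on random pairs. Note that counting-method
families (NG86 vs Li-type) can differ by several percent on diverged
pairs; published values computed with another estimator are comparable only
approximately.

## Genome windows and cluster detection

Two geometries: base-pair windows [k*step, k*step + window) per chromosome
(defaults 1 Mb / 0.1 Mb), and gene-index windows of 100 mapped genes with
step 10, per chromosome, dropping trailing partial windows. A gene belongs
to a window iff its *start* coordinate lies in the half-open interval
(start-based assignment is unambiguous for boundary-spanning genes). The
flag ratio is flagged / highly-expressed (undefined at 0 highly expressed;
such windows are excluded from the quartile pool). A window is part of a
cluster when its ratio strictly exceeds 3 x Q3(ratios) and its
highly-expressed count strictly exceeds Q1(counts); quartiles use linear
interpolation between order statistics (R type-7 / numpy default).
Overlapping flagged windows merge into maximal regions.

## Downstream statistics

Term enrichment is a one-sided (greater) hypergeometric test per annotation
term, restricted to terms with strictly more than 5 background genes, at
raw p < 0.01 with no multiplicity correction by default (a deliberate
faithfulness choice; the background set is always supplied explicitly by
the caller because class-level and per-tissue analyses use different
backgrounds). The three-way expected count is E = common x MZ / HE
(proportional mixing), and the observed-vs-expected test is Fisher's exact
test on [[obs, common - obs], [MZ, HE - MZ]], two-sided by default (sum of
tables at most as probable), implemented via hypergeometric pmf sums and
cross-checked against both exact binomial-coefficient tail sums and
scipy's `fisher_exact`.

Three-strain DE patterns per gene and tissue (pairwise calls NM, NZ, MZ):
three-way = all three DE; common = NM and NZ but not MZ; indica-indica =
MZ plus exactly one of NM/NZ; similar = none; remaining logically
intransitive combinations are reported as inconsistent. Genes not highly
expressed in any strain, unmeasurable genes, and silent genes are dropped
first.

eQTL summaries: per gene, the simple sum of variance-explained percentages
over all its records; a record is cis when its interval overlaps the gene
body expanded by 1 Mb (configurable — the source mapping study's exact cis
criterion is not restated, so a conventional margin is used). Groups:
sum > 80% well-explained, < 40% unexplained, else intermediate (both
strict). Cohort means +/- sd are reported overall and cis-only, per
supplied gene class.

## Synthetic data: what it emulates, and what it does not

The generator plants ground truth for every input. Study conditions are
fixed once: gene baselines N(8, 2) log2 (straddling the threshold 7 so the
expression criterion is exercised), probe affinities N(0, 1), noise sd
0.25, replicates 3v3, SFP shift -2 (negative: mismatches reduce
hybridization) with probe-to-probe heterogeneity sd 0.5, DE shifts +/-2,
SFP fraction 10% of probes, DE fraction 10% of genes. Atlas profiles:
broad genes ~N(10, 0.3) across tissues (tau ~ 0.05), specific genes one
dominant tissue ~12 over a ~1.2 floor (tau ~ 0.9), silent genes clamped at
<= 7 in the designated strain, changed-tissues genes shifted by -3 in one
homologous tissue of strain B. The noise-free atlas profiles are the
biological truth; the emitted atlas matrices add measurement noise (sd
0.25) on top, and the probe-level experiment realizes the same truth with
a small inter-strain scatter (sd 0.1, far below the fold threshold). One
root seed drives independent per-stage streams, so identical (config,
seed) yields byte-identical files.

Not emulated: probe sequences and their thermodynamics, spatial array
artifacts, batch effects, correlated noise across probes, RIL genotypes
(eQTL records are emitted directly with planted cis/trans structure), and
annotation-term overlap structure. Passing the planted-truth tests
therefore demonstrates the estimators' correctness and calibration under
the stated noise model, not performance on real arrays with probe-specific
variances or batch structure.

Problem sizes used by the test suite and the acceptance script — chosen to
exercise every code path at desk scale: probe-level recovery at 1000 genes
x 11 probes x 3v3 over 20 seeds; cluster recovery at 3000 genes over 50
seeds; the end-to-end pipeline at 300 genes, 8 probes, 2 strains x 5
homologous (+3 strain-specific) tissues. The published genome-scale counts
(e.g. dataset-level DE totals) depend on the original array data and are
treated as data-dependent references, not desk-reproducible targets.

## Known limitations

- The SFP test assumes within-set homoscedastic noise; strongly
  heteroscedastic probes would mis-calibrate the pooled statistic.
- Symmetric probe sets with exactly half the probes shifted by identical
  amounts are fundamentally ambiguous; the unmeasurable guard catches
  heterogeneous majority contamination but an adversarial exactly-equal
  split can yield a biased measurable fit.
- Ward.D on non-Euclidean dissimilarities can produce height inversions;
  the cut operation is defined directly on merge heights and is unaffected.
- NG86 equal pathway weighting ignores transition/transversion bias; Ka/Ks
  near saturation (p >= 0.75) is reported uncorrected with a flag.
- The eQTL cis call uses interval overlap only; linkage disequilibrium
  beyond the margin is not modeled.
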