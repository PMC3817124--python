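# Methods

`popstruct` re-implements, as one tested toolchain, the analysis stack
used to resolve fine-grained substructure in large SNP-array cohorts:
two genotyping platforms are harmonized into one matrix, markers are
quality-controlled, population relationships are summarised by
bootstrap neighbor-joining trees on allele frequencies, individuals are
assigned to subpopulations by unsupervised iterative-pruning PCA,
ancestry proportions are estimated under the admixture likelihood, and
differentiation is quantified by Weir–Cockerham Fst with permutation
significance.  Because cohort-scale genotype data of this kind are
access-restricted, the package ships a synthetic-data generator whose
ground truth makes every stage testable end to end.

## Synthetic genotypes

Subpopulation allele frequencies follow the Balding–Nichols model:
around an ancestral frequency `p ~ Uniform(0.05, 0.5)` (configurable;
the lower bound avoids near-fixed loci), each subpopulation draws

    p_k ~ Beta( p(1-F)/F, (1-p)(1-F)/F ),

so `E[p_k] = p` and `Var[p_k] = F p(1-p)`; genotypes are
`Binomial(2, p_k)`, independent across loci (no linkage
disequilibrium).  Draws are clamped to `[0.001, 0.999]` so no locus is
degenerate.  Default conditions are four subpopulations of 250
individuals at 20,000 loci with `F = 0.05` — drift strong enough that
the structure is recoverable at this marker count.  Real dense-array
studies resolve pairwise Fst near 0.002 by using an order of magnitude
more markers; the generator reproduces that regime by lowering `F`
(pairwise parametric Fst for two populations drifted at `F` is
approximately `2F/(1+F)` here) and raising the locus count.

Additional features layered on the base draw:

* **Admixed individuals** — per-individual `q ~ Dirichlet(alpha)`,
  genotypes `Binomial(2, q·p_l)`; the majority component is recorded as
  the nominal membership.
* **Planted divergent loci** — at selected markers one subpopulation's
  frequency is shifted by `+delta` (clamped to `[0.01, 0.99]`) and the
  genotype column re-drawn, emulating the strongly differentiated SNPs
  that dominate per-locus Fst rankings.
* **Outliers** — individuals drawn from one *private* Balding–Nichols
  vector at a large drift (default 0.3): a small genetically distinct
  group (recent ancestry from elsewhere) belonging to none of the K
  subpopulations and far below any plausible subpopulation size.  Real
  unassignable samples can also arise from cryptic relatedness, which
  the generator does not emulate.
* **Platform splits** — samples are divided into two cohorts sharing a
  configurable fraction of markers; a fraction of shared markers has
  one cohort's allele pair strand-complemented (dosage codes are allele
  counts and survive relabeling), and a fraction is rewritten to
  self-complementary A/T or C/G pairs that no harmonizer can reconcile.
* **Missingness** — completely at random per call; downstream QC
  filters on per-marker missingness only.

The ground truth (memberships, true `Q`, true frequencies, planted
marker ids, outlier ids, and the pairwise parametric Fst implied by the
true frequencies) is returned alongside the matrix.  What passing tests
show is therefore recovery under an idealised unlinked HWE model; they
do not certify behaviour under LD, genotyping artefacts or family
structure.

## Harmonization and QC

Merging keys on rs-id.  A shared marker survives when the two allele
pairs agree directly or after strand complement (cohort A is always
complemented into cohort B's frame); if the surviving orientation swaps
reference and alternate, cohort A's dosages are recoded `g -> 2-g`.
A/T and C/G markers are excluded in either cohort.  Cross-platform
consistency is summarised by the Pearson correlation of per-cohort
minor-allele frequencies.

Marker QC applies, in fixed order for reproducible counts: the
Hardy–Weinberg exact test (Levene's conditional distribution of the
heterozygote count; two-sided tail as the sum of configurations no more
probable than the observed one, no mid-p; default threshold `p < 1e-3`),
a per-marker missingness cap (default 5%), and sliding-window LD
pruning at `r^2 > 0.5` on dosage correlation.  The window (50 markers)
and step (5) are the common convention for array data — the pruning
threshold itself is the only quantity the upstream method pins down.
Within a pruned pair the marker with more missing data (ties: the later
position) is dropped.  Systematic frequency bias between collection
cohorts is screened per marker with a 1-df chi-squared on the 2x2
allele-count table (no continuity correction) at a Bonferroni-corrected
threshold, default `1e-7`.

## Frequency trees

Nei's standard genetic distance is computed from biallelic frequencies
(`Jxy`, `Jx`, `Jy` averaged over loci, `D = -ln(Jxy/sqrt(Jx Jy))`); a
fixed difference at every locus gives `Jxy = 0`, which is clamped to a
configurable maximum (default 10) and logged.  Neighbor-joining follows
Saitou–Nei with the standard Q-criterion; ties are broken by the
lexicographically smallest pair of representative leaf labels so the
topology is platform-independent, and negative branch lengths are
clamped to zero with the excess moved to the sister branch.  Bootstrap
replicates resample markers with replacement (the natural unit for
frequency-based distances); the consensus is majority-rule (extended)
by default, with strict-majority available, supports are integer
percentages, and an outgroup can be supplied for rooted display.  The
default of 100 replicates matches common practice for population trees.

## Iterative-pruning PCA

Genotype columns are mean-imputed, centred by `2p` and scaled by
`sqrt(2p(1-p))`; the spectrum of the `(1/L) X X^T` covariance is
examined at each node.  The stopping statistic,

    EigenDev = RMS deviation of the top min(N-1, 100) eigenvalues
               around their mean,

is near the Marchenko–Pastur bulk dispersion for a homogeneous sample
and grows with the spiked eigenvalues that population structure
produces.  Nodes at or below the threshold become terminal
subpopulations; otherwise members are split by fuzzy c-means (c = 2,
fuzzifier 2, k-means++-style seeded initialisation) on the top two PC
scores, with hard maximum-membership assignment; plain 2-means and more
PCs are available by flag.  The default threshold 0.21 is retained from
the published procedure, but it was calibrated for dense marker panels:
its null value grows as N/L grows, so `calibrate_threshold` simulates
homogeneous matrices of the data's own shape and returns a null
quantile (default 0.99) as a principled substitute.  At desk-test
scales (hundreds of individuals, a few thousand loci) the fixed 0.21
oversplits, which is the expected behaviour of the fixed constant, not
a defect of the recursion.

Children smaller than `min_subpop_size` (default 20) become outlier
terminal nodes — the individuals that cannot be assigned; if both
children fall below the minimum the node is kept whole as a terminal
subpopulation rather than dissolved into outliers.  The per-node RNG
seed is derived from the member-id *set*, not the recursion path, so a
node with identical members splits identically wherever it occurs —
this makes the main partition invariant to injecting outliers that are
pruned along the way, and makes the whole procedure invariant to region
labels, which are used only in reports.  A `max_depth` guard (20)
bounds pathological recursion.

## Admixture model

The standard unlinked binomial admixture likelihood: genotype
`g_il ~ Binomial(2, sum_k q_ik f_kl)`.  Optimisation is plain EM on
expected allele-origin counts — the contract is the maximised
likelihood, not the iteration path, and EM's closed-form updates are
monotone and easy to verify (the trace is asserted non-decreasing).
`Q` rows are renormalised each step; `F` is clamped to
`[1e-6, 1 - 1e-6]`; missing calls are excluded from the likelihood.
Initialisation draws `Q` from a flat Dirichlet and perturbs the global
allele frequencies for `F`; three restarts by default, best final
likelihood wins.  Convergence is declared when the relative likelihood
gain falls below `tol` (default 1e-6).  `K` is user-chosen (sweeps over
a range are provided); no automatic selection is attempted.  Component
labels are arbitrary, so a greedy correlation matcher aligns a result
against a reference for plotting and truth comparison.

## Fst and significance

Per locus, Weir–Cockerham (1984) diploid variance components `a`
(among populations), `b` (among individuals within populations) and `c`
(within individuals) are computed from per-population sizes,
frequencies and observed heterozygosities; `theta = a/(a+b+c)` and can
be slightly negative under no differentiation.  Loci monomorphic across
the pooled groups are excluded.  Genome-wide `theta` is the
ratio-of-sums `sum(a)/sum(a+b+c)` — not a mean of per-locus ratios.
Significance is one-sided by permuting individuals between the two
groups (default 1023 permutations, add-one p-value, so the floor is
1/1024); the rendered pairwise table stars p < 0.01.  Per-SNP rankings
sort per-locus `theta` descending with dense ranks (ties by chromosome,
position) and report minor-allele frequencies in every subpopulation.

## Pipelines, sizes and reproducibility

`run_stage1` (two sparse platform cohorts: harmonize, concordance, NJ
bootstrap, ipPCA, K sweep 2–10) and `run_stage2` (one dense matrix: QC,
cohort-bias screen, ipPCA, outlier exclusion, admixture K 2–4, Fst
matrix and rankings, region-by-subpopulation proportions) run from one
YAML config; every artifact is TSV/Newick/JSON and a manifest records
config, seeds, wall-clock and SHA-256 checksums.  Given a seed, both
stages are bit-reproducible.

Validation sizes were chosen so the whole suite runs on a laptop: Fst
calibration uses 200 individuals per group at 20,000 loci across drift
0.005–0.05; ipPCA recovery uses the generator defaults (4 x 250 at
20,000 loci, F = 0.05) and 20 homogeneous null runs at 400 x 20,000;
admixture recovery uses 200 individuals at 10,000 loci; the cohort-bias
null screen runs at the full 438,503-marker scale with 100 individuals
per cohort.  The EigenDev-vs-drift monotonicity check runs at 300
individuals and 10,000 loci, where even the F = 0.002 step is resolved.

Outlier isolation has a detection floor: a group of g outliers drifted
at F contributes a spike of roughly `1 + (2g + 1)F` to the node
spectrum, and the EigenDev of a single spike λ among ~100 bulk
eigenvalues is about `(λ - 1)/10`.  At the default threshold 0.21 this
means an outlier fragment must carry a spike above ≈ 3, so pairs at
drift 0.3 sit at the boundary — if an intermediate split fragments the
outlier group, a stray pair can be absorbed into a subpopulation.
Larger drift, larger outlier groups or a calibrated (lower) threshold
all move the fragment safely above the floor.

## Known limitations

* No LD in the generator, so LD pruning is exercised only on duplicated
  or correlated-by-construction columns.
* The EigenDev constant 0.21 is inherited, not derived; use the
  calibration routine off the published marker scale.
* EM admixture is slower than quasi-Newton block relaxation at large
  N·L·K; no acceleration is implemented.
* Nei distance, NJ and the consensus operate on biallelic loci only.
* Sample-level QC (relatedness, heterozygosity outliers) and genome
  builds/liftover are out of scope.
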