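# Methods

## Model overview

`lumoscall` classifies candidate variant sites in an unmatched tumor sample
as somatic, germline heterozygous, germline homozygous-reference, or other,
by modeling how allele fractions shift with tumor purity and allelic copy
number. The pipeline has four stages that mirror how the data are used:

1. **Panel of unmatched controls** — per-position reliability scores and
   per-exon reference depths.
2. **Site quality filtering** — 16 quality metrics, threshold-seeded
   training labels, and per-class quadratic discriminant models giving
   two-tier posteriors (PT strict, PV lenient).
3. **Copy number and clonal fractions** — CBS segmentation of
   tumor/control depth ratios, then EM over clone fractions f, dispersion
   W and centering C, with per-segment integer copy states (N, M) and
   per-variant clone assignments.
4. **Calling** — four-way Bayesian posteriors per site; stages 3 and 4
   alternate until the somatic and germline candidate sets stop changing
   (at most `max_outer_iters`, default 10).

## Assumptions

- A fixed number K of clonal cell subsets (default 3); every variant and
  copy alteration belongs to one subset.
- At most one clone carries a copy alteration in a given segment; all
  other cells are diploid there.
- A somatic variant in the copy-altered clone rides on the major allele;
  somatic variants in other clones occupy exactly one copy.
- Control samples are diploid at reliable positions; positions that do not
  look diploid across controls are down-weighted via the reliability score.
- Sites are independent given the clone model.

## Key parameters (defaults)

| parameter | default | meaning |
|---|---|---|
| K | 3 | number of clonal subsets |
| f_pi, alpha_pi | 0.5, 1.5 | mode/shape of the Beta prior on sample fractions |
| pi(N=0..3, >=4) | 0.1, 0.15, 0.5, 0.15, 0.1 | copy-number prior |
| pi(M=0,1,>=2) | 0.25, 0.5, 0.25 | minor-allele copy prior |
| alpha_seg | 1e-5 | CBS significance cutoff |
| rho_SNV / rho_indel | 1e-5 / 1e-6 | somatic prior scale, pi_S = rho(omega+1) |
| F_p_SNV / F_p_indel | 7.14e-5 / 1.43e-5 | frequency assigned to alleles unseen in the population reference |
| F_max_somatic | 1e-3 | maximum population frequency for a somatic candidate |
| Qm_min / Qb_min | 10 / 5 | read/base inclusion cutoffs for counts extraction |
| T_PASS | 0.99 | PT/PV tier threshold |
| T_somatic / T_germline | 0.8 | posterior calling thresholds |
| pi_U | 0.05 | prior that a position is unreliable (mappability-scale constant; configurable) |

Bounds used in the M-step: f in (0.01, 0.99), W in (2, 1e4), C in
(0.5, 4); C is initialized at 2 because the depth model implies C ≈ 2 for
centered diploid data.

## Numerical and design choices

- **All pmfs in log space** (scipy `betabinom`, `binom`, `poisson`); no
  underflow for depths up to 1e5. `pmf(0, 0, ·) = 1` by convention. Exon
  depth likelihoods round both the observation and the expectation and
  floor zero expectations at 1e-3.
- **Rounding of copy states** is half-away-from-zero, avoiding banker's
  rounding at .5 ties; M is clamped to [0, floor(N/2)].
- **Minor-copy inversion.** The het band is defined by
  `phi_G = fM/N + (1−f)/2`; the expectation step estimates `phi_hat` as
  the folded (minor) het allele fraction of the segment and inverts the
  band definition exactly: `M = round(N (phi_hat − (1−f)/2) / f)`. An
  alternative form that subtracts `(1−f)/2` *after* dividing by f is
  biased by `(1−f)(N−f)/(2f)` and mis-recovers states such as (2,0) at
  f=0.3; the exact inverse is used.
- **Two-band het likelihood.** Folding het counts to `min(R_B, R_A)`
  biases the folded fraction below 1/2 by O(1/sqrt(n)), which an EM can
  exploit with a spurious low-fraction copy-neutral-LOH clone. Likelihood
  terms therefore use the raw B count under an equal-weight mixture of the
  two parental bands (phi and 1−phi); folded counts are used only for the
  integer M inversion, where a minor-allele summary is required. The
  public single-band `het_af_loglik` primitive is unchanged.
- **Shared dispersion.** By default one W is shared across clones
  (`shared_W: true`). Fitting an independent W per clone admits degenerate
  optima in which one clone's W collapses to the lower bound and acts as a
  flat catch-all likelihood, which then corrupts the homozygous/other
  error models downstream (their Beta parameter `W·10^(−Qb/10)` drops
  below 1 and becomes extremely heavy-tailed). Per-clone fitting can be
  re-enabled in the config.
- **M-step** is bounded Nelder-Mead on logit/log-transformed parameters,
  run from the current parameters; the whole EM is restarted from three
  deterministic starts (evenly spaced f grids, W=30, C=2). A warm start
  from the previous outer iteration is *added* to these starts, not
  substituted. The M-step never accepts a worse objective; because the
  expectation step makes hard integer/argmax assignments, a full iteration
  could in principle lower the objective, in which case the previous state
  is kept and the fit stops (generalized-EM safeguard). The reported
  objective trace is therefore non-decreasing.
- **Objective normalization** divides by `3X + X* + V + 2Y` (X exons, X*
  exons in copy-altered segments, V hets, Y somatics), with prior terms
  for copy states per exon, and Beta-prior terms for the sample fraction
  of each somatic variant and each copy-altered exon.
- **Segmentation** is a circular binary segmentation recursion on log2
  depth ratios, per chromosome, with minimum segment width 5 exons. The
  arc significance test uses a Bonferroni-corrected normal tail bound on
  the max-t statistic rather than permutations: at alpha = 1e-5 a
  permutation test would need >1e5 permutations per split to resolve, and
  the bound is conservative (it only ever under-splits noise). Profiles
  under 10 exons are kept whole.
- **Quality models.** PT comes from a QDA fit on PASS vs REJECT training
  sites (PASS = all strict cutoffs hold; REJECT = any reject cutoff;
  REJECT wins conflicts); PV from a lenient QDA of everything-but-REJECT
  vs REJECT. The two-fit construction realizes the two-tier filtering
  behavior; the original construction of PV is not documented, so this is
  an explicit interpretation. Covariances are ridge-regularized
  (lambda = 1e-6 · trace/d, escalated tenfold until Cholesky succeeds).
  SNVs and indels get separate models; with too few labeled indels the
  SNV model scores them (warned).
- **Outer-loop seeding**: likely germline = high-quality sites with
  population frequency ≥ 0.01 and B-allele fraction in [0.2, 0.8];
  likely somatic = high-quality sites with frequency ≤ F_max_somatic.
  The exact database-frequency seeding rule is not specified beyond
  "likely germline and somatic by database frequency"; these cutoffs are
  this package's documented choice. Convergence is defined as set-
  membership stability of the two sets.
- **Known-germline flags** are carried to the VCF INFO but do not veto
  calling (cancer databases and germline databases overlap).

## The synthetic cohort generator

`simulate.synthesize_cohort` emulates the generative model the caller
assumes: lognormal-ish control exon depths around the target coverage,
Poisson tumor depths around the clonal-mixture expectation with true
centering C=2, Hardy-Weinberg germline hets with population frequencies
from a common/private mixture (common: Beta(0.5, 0.5); private:
F_p_SNV = 7.14e-5, absent from the database), beta-binomial het and
somatic B counts with a truth concentration W (default 200, a
clean-library value), and artifact sites with degraded base/mapping
qualities (Phred ~12/~15), strand skew (97% one strand), and noisy control
signal so the panel flags them. Clean site qualities are ~Q33 base / ~Q58
mapping. Default study conditions used in the tests: 600x cohorts with
150–250 hets, 40–60 somatics cycled across clones, two controls.

What it does **not** emulate: read-level errors and mapping (there are no
reads), FFPE damage, indel realism, GC/mappability depth waves,
multi-allelic sites, or linkage between neighboring sites. Passing tests
therefore demonstrate correctness of the statistical machinery under its
own assumptions, not robustness to real-library pathologies.

An in-silico dilution helper mixes tumor and matched-normal read counts by
binomial thinning; the fitted sample fraction scales linearly with the
dilution (asserted within 0.08).

## Power simulation

Per condition (coverage, f, N, M): depths are lognormal with arithmetic
mean equal to the target coverage and log-sd 0.5 (a typical exome-like
depth dispersion; the mean is preserved exactly via
mu = ln(cov) − sigma²/2), B reads are Binomial(R_T, phi_S), and each
variant is scored with the four-way posterior assuming the true (f, N, M)
are known (K=1), dispersion W=50, priors omega=0 and F_B = F_p_SNV, base
quality Q30. Detection = fraction with P(S|D) ≥ 0.8. The full
8-state × 19-fraction × 7-coverage grid at 1000 variants per condition
runs in a few seconds.

A consequence of evaluating with a fixed, depth-independent W: the
somatic and germline beta-binomial likelihoods keep fixed widths
(variance phi(1−phi)/(W+1)) while the observed allele fraction sharpens
as 1/sqrt(depth), so the achievable log-likelihood ratio between
overlapping bands saturates with coverage. Under W=50 the separation
between phi_S = 0.375 (f=0.75, diploid) and the het band at 0.5 never
reaches the posterior-0.8 threshold at any depth, and detection at
sample fractions ≥ 0.75 is ~0 on the whole grid; likewise the
homozygous-reference error model's second Beta parameter W·10^(−Qb/10) =
0.05 is below 1 and heavy-tailed, which suppresses detection at low
sample fractions. These are properties of the fixed-W evaluation, not of
the fitted caller (which estimates W from the data, typically 150–300 on
the synthetic cohorts).

## Known limitations

- The panel's control model has three states (hom-ref, het, unreliable)
  with Hardy-Weinberg priors F_A² and 2F_A·F_B; a control that is
  homozygous for the B allele fits none of the diploid states and inflates
  the position's unreliable score. Common-SNP positions are therefore
  often panel-flagged and excluded from calling. Such sites are already
  ineligible to be somatic (F_B > F_max_somatic), but their loss removes
  some usable hets from the copy-number fit.
- One copy event per segment; no sub-exon breakpoints; no sex-chromosome
  ploidy handling; single-sample only.
- The CBS p-value bound is conservative; very small or low-contrast
  events may be merged into neighboring segments.
- Hard-assignment EM over a multimodal objective: multi-starts mitigate
  but cannot guarantee the global optimum, and gain-in-large-fraction vs
  higher-gain-in-small-fraction explanations of the same depth ratio are
  genuinely ambiguous.
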