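# Methods

`cavityepp` implements the full inference chain from SNP genotypes and nest
records to extra-pair-paternity (EPP) classification and its spatiotemporal
correlates, for socially monogamous cavity-nesting passerines (blue tits
*Cyanistes caeruleus* and great tits *Parus major*) breeding in two plots —
one with natural tree cavities, one supplemented with nestboxes.  This note
documents the models, the defaults and why they were chosen, the numerical
choices, and what the synthetic-data generator does and does not emulate.

## Genomic relatedness (GCTA estimator)

Relatedness between individuals *j* and *k* is estimated from allele
dosages *x* ∈ {0, 1, 2} at *m* biallelic SNPs:

    G_jk = (1 / m_jk) Σ_i (x_ji − 2p_i)(x_ki − 2p_i) / (2 p_i (1 − p_i))

with the diagonal

    G_jj = 1 + (1 / m_j) Σ_i (x_ji² − (1 + 2p_i) x_ji + 2 p_i²) / (2 p_i (1 − p_i))

where *p_i* is the sample alternate-allele frequency.  Design choices:

* **Pooled frequencies.** *p* is estimated from the full post-QC sample,
  adults and nestlings together and both plots pooled.  Family structure
  inflates kinship estimates slightly; the wide classification bands below
  absorb this.
* **Pairwise-complete loci.** Missing genotypes are handled by restricting
  each pair to the loci called in both (*m_jk* per pair), never by
  imputation, matching the behaviour of the common GDS-based GRM
  implementations.
* **Monomorphic guard.** Loci with *p* < 1/(2n) or > 1 − 1/(2n) are
  dropped before estimation to avoid division by ≈0 in the
  standardisation.
* **QC order.** The call-rate filter (default 70%) removes individuals
  then loci and iterates to a fixed point, making the result insensitive
  to which side is filtered first.

The vectorised implementation is checked against a naive per-pair
scalar-loop oracle to 1e-10 on every instance with ≤10 individuals, and
against pedigree expectations on simulated families (parent–offspring mean
in [0.45, 0.55]; regression of G on pedigree relatedness with slope in
[0.9, 1.1] at 5,000 loci).

## Social pedigree and expected relatedness

The field pedigree (who attended which nest) yields expected additive
relatedness via the tabular method: a_ii = 1 + a_{sire,dam}/2 and
a_ij = (a_{i,sire(j)} + a_{i,dam(j)})/2 with unknown parents contributing
zero.  Inbreeding is handled by the same recursion even though the study
populations are effectively outbred — correctness is free.  Individuals
with no pedigree link have expected relatedness 0; recruits ringed in
earlier years keep their natal links, which is what makes the
full-sibling false-positive screen (below) possible.

## Parentage classification (threshold bands)

Classification compares the realized GRM value with the social
expectation:

| pair type (social r) | GRM band | call |
|---|---|---|
| father–offspring (0.5) | > 0.35 | within-pair |
| father–offspring (0.5) | < 0.15 | extra-pair offspring (EPO) |
| father–offspring (0.5) | [0.15, 0.35] | ambiguous (reported, excluded) |
| male × other-nest offspring (0) | > 0.35 | extra-pair father (EPF) link |
| within-brood siblings (0.5) | > 0.35 / (0.15, 0.35) / < 0.15 | full / half / unrelated-flag |
| nestling × all parents and siblings | all < 0.1 | brood parasitism |

Numerical conventions:

* **Strict inequalities.** Values exactly at a cut-off fall into the
  ambiguous/negative class.  The bands are measure-zero events in
  practice; fixing the convention keeps behaviour reproducible.
* **Ambiguous band.** No positive rule covers (0.15, 0.35) for
  father–offspring pairs, so those pairs are excluded from both the EPO
  numerator and denominator and always reported.  Inventing a mid-band
  cut-off would manufacture calls the data cannot support.
* **An EPO does not require a found sire.**  The EPO call depends only on
  the offspring–father GRM value; identifying the genetic sire is a
  separate (and much rarer) event, since the sire must himself be
  genotyped.
* **EPF false-positive screen.** A male whose pedigree shows him to be a
  full sibling of the offspring from a previous cohort is removed from the
  EPF links and reported, mirroring the field-record check.
* **Unsampled fathers.** Nests whose social father was not genotyped get
  brood-level EPP status from sibling evidence (any half-sibling pair ⇒
  EPP-positive) and are excluded from per-nest EPO-proportion models,
  where the denominator would be undefined.

## Sexing (ZW system)

Females are the heterogametic sex (ZW): at Z-linked loci a female carries
one allele, which diploid callers emit as a homozygous genotype.  Two
consequences drive the method: female observed heterozygosity at Z loci is
zero (before genotyping error), and the pooled sample shows a strong
heterozygote deficit at those loci.

* **Discovery.** Per-locus screen on known-sex adults: |het_M − het_F| ≥
  0.2 AND a sex-vs-pooled fixation index 1 − H_obs/H_exp above the 99th
  percentile of its empirical distribution.  A pure allele-frequency
  differentiation estimator (Weir–Cockerham θ) carries no signal here —
  under the hemizygous-as-homozygous coding the sexes share allele
  frequencies exactly — so the fixation index, which responds to the
  heterozygote deficit (≈0.5 at a Z locus, ≈0 at an autosomal HWE locus),
  is the right screen.  Permutation p-values (999 label shuffles) are
  attached per panel locus using the label-sensitive heterozygosity
  difference.
* **Assignment.** Per-sex genotype-frequency naive Bayes over the panel
  with add-one smoothing and a flat prior; missing panel loci are skipped,
  and a nestling missing all of them is returned as unknown.  Accuracy is
  reported from Monte-Carlo cross-validation: repeated random 70/30
  train/test splits of the known-sex adults.
* **Irreducible ambiguity.** A male homozygous at (almost) every panel
  locus is genuinely indistinguishable from a hemizygous female; true
  females, carrying no heterozygous Z call, essentially never flip.  With
  an 11-locus panel and 1% allele-flip error the cross-validated accuracy
  is ≥0.95 in the simulations.

## Spatiotemporal metrics

Per nest, within its own species and year:

* **Nearest neighbor distance** — to the closest conspecific active nest;
  both plots are eligible and distance alone decides.
* **Neighbor density** — conspecific nests within a radius, focal
  excluded.
* **Synchronous neighbor density** — the subset of those neighbors whose
  female's fertile period overlaps the focal female's by ≥1 day
  (closed-interval, endpoint-inclusive; an exclusive-overlap flag is
  provided).

The fertile window is [laying − offset, laying + clutch − 2], with offset
2 days for blue tits and 5 for great tits and one egg laid per day, ending
on the penultimate laying day.  A clutch of one makes the window end
before laying begins; the formula is retained and the case flagged, as it
cannot produce synchrony.  Radii are derived from the data: the base
radius is the median distance between an EPF's own nest and the nest where
he sired extra-pair young (mean of the middle two for even counts), with
×2 and ×3 multiples; the species defaults (96 m blue tit, 72 m great tit)
are used when a dataset yields no located links.  Geographic coordinates
are projected to a local tangent plane (equirectangular, centred on the
site centroid), exact to ≪0.1% at the sub-kilometre scale of a study
plot, verified against a haversine oracle.

## Statistical models

* **2×2 chi-square** with Yates continuity correction by default — the
  convention that reproduces the published test statistics from their
  printed counts (0.267, 2.427, 1.230, 1.352), asserted to 3 decimals.
* **Mann–Whitney U** with the first-sample convention
  W = R₁ − n₁(n₁+1)/2; exact enumeration when both groups have ≤8
  observations and no ties, otherwise tie-corrected normal approximation
  with optional continuity correction.  The exact path is verified against
  full enumeration of all C(n₁+n₂, n₁) labelings.
* **Binomial GLM** (logit link, IRLS via statsmodels) for Bernoulli and
  binomial-proportion responses; aliased and constant design columns are
  dropped and reported; possible separation is flagged, never silenced.
* **Binomial GLMM** with a single random intercept, maximising the exact
  marginal likelihood by adaptive Gauss–Hermite quadrature (15 nodes by
  default; 1 node = Laplace).  Per-group integrals centre and scale the
  Hermite nodes at the mode and curvature of the integrand; the analytic
  gradient is the posterior expectation of the complete-data score under
  the same quadrature.  The implementation matches lme4's `glmer`
  (nAGQ = 15) to 4+ decimals on coefficients, standard errors, variance
  and log-likelihood on shared test data, and matches brute-force numeric
  integration of the marginal likelihood to 1e-6 on a tiny instance.  On
  optimisation failure the model returns the fixed-effects GLM carrying an
  explicit random-term-dropped flag.
* **Per-term p-values** are drop-one likelihood-ratio chi-squares
  (the "Pr(>Chisq)" convention); Wald tests are reported alongside.  Note
  that the finite-sample MLE of a truly zero random-intercept variance is
  small but positive (e.g. 0.08 at 40 groups × 10 observations — identical
  to lme4 on the same data); tests treat this as the correct behaviour.
* **VIF** = 1/(1 − R²) per predictor; **scaled mass index**
  SMI_i = mass_i (L₀/tarsus_i)^b with b the standardised-major-axis slope
  of ln mass on ln tarsus (OLS slope ÷ Pearson r) and L₀ the sample mean
  tarsus.  SMA deliberately overcorrects the OLS slope by 1/r, so SMI
  decorrelates from tarsus only when measurement scatter is small relative
  to the allometric range; the tests use that regime.

**Model battery and filters.**  `run_model_battery` applies the analysis
filters — first clutches only; proportion models drop nests with an
unsampled father and nests with under half the clutch sampled; z-scaled
spatiotemporal covariates — then fits, per species: three nest-level
occurrence models (one spatiotemporal covariate each, mother identity as
random intercept), three nest-level EPO-proportion models (binomial with
trials = sampled nestlings; overdispersion reported as the Pearson
dispersion ratio, no quasi-likelihood), an individual-level EP-status
model with a cavity×sex interaction that is dropped when its LRT p > 0.05,
and a fledging model.  A zero-variance response aborts with a named error
rather than a degenerate fit.

## The synthetic-data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream claim is demonstrated.  Per simulated season (one
species per call):

* two non-overlapping plots in a local metric frame — a ~50 ha "natural"
  plot with uniform-random nest placement and a ~15 ha "nestbox" plot on a
  50 m grid with jitter, ≥200 m apart;
* founder adults in Hardy–Weinberg proportions at frequencies drawn
  uniformly on [0.05, 0.5]; 5,000 autosomal and 20 Z-linked loci by
  default (locus counts and a 0.5% allele-flip error are defaults exposed
  in the config, since post-filter counts and error rates are rarely
  published for reduced-representation data);
* Mendelian transmission, one allele per parent per locus; Z transmission
  follows ZW genetics (sons: maternal Z + one paternal Z; daughters: one
  paternal Z, coded homozygous);
* each offspring is extra-pair with probability `epp_rate` (default 0.10,
  the magnitude seen in the two study species); the extra-pair sire is a
  same-plot male other than the social father, drawn with probability ∝
  exp(−d / 100 m) — consistent with observed median EPF distances of
  ~70–100 m;
* brood parasitism implants one unrelated, unsampled-parent offspring per
  affected nest (rate 0.01/nest, matching its rarity: one case in ~550
  sampled nestlings);
* 10% of social fathers are left ungenotyped; laying dates are normal
  (mean day 108, SD 5 — a mid-April season), clutches uniform on 8–12;
* genotyping error (each allele flips independently; hemizygous female Z
  dosages jump 0↔2 on a single flip) and missingness are applied last.

Truth tables record per-offspring sire, EPO/parasite flags and sex, and
per-nest EPP status.  A Mendelian-transmission checker (autosomal loci)
serves as an independent oracle: its per-trio incompatibility rate is 0
for clean data, matches an exact enumeration of the error channel within
3 SE under 1% error, and is sharply elevated for cuckolded trios.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium and chromosome structure
(loci are independent), restriction-site dropout and other
genotyping-platform artefacts (missingness is uniform at random),
population structure and immigration, mate switching within a season,
laying gaps, and any behavioural process behind extra-pair matings other
than distance decay.  Classification accuracy on real reduced-
representation data will be bounded by these omissions.

## Reference fixture

A label-encoded fixture carries a published two-species outcome directly
as classification labels (not genotypes): per-plot brood and nestling
counts with their extra-pair subsets, 25 cuckolded fathers + 3
half-sibling-evidence nests per species, and one brood-parasitism case.
It exercises the summary and test layers exactly — percentages and
chi-squares reproduce to the printed precision — independently of the
stochastic GRM layer, which is tested by simulation instead.

## Problem sizes

Stochastic checks use sizes chosen to make the statistical claims sharp
while keeping the suite quick to run: rate-recovery uses 15 pairs/plot ×
5,000 loci × 10 replicates per rate; sexing uses 30 pairs/plot with a
2,000-locus autosomal background behind 20 Z loci; mixed-model recovery
uses 60 groups × 8 observations.  The acceptance script repeats the same
computations at 3 replicates per rate.

## Known limitations

* Threshold-band classification assumes outbred populations; background
  relatedness (e.g. high immigration from related neighbours) would blur
  the bands.
* EPF links can only point at genotyped males; sires from outside the
  sampled population are invisible, so link counts underestimate true
  sire diversity (as in any study of this design).
* The GLMM supports exactly one random intercept — the only structure the
  analysis needs; crossed or nested random effects are out of scope.
* The naive-Bayes sexer treats panel loci as independent; linked Z loci
  would make its posteriors overconfident, though rankings (and hence
  assignments) are robust.
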