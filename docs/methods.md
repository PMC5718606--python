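# Methods

`gutcross` re-implements, as one tested pipeline, the intestinal-environment
chemistry and longitudinal microbiome statistics used in randomized crossover
bed-rest studies: three intervention arms (normoxic bed rest NBR, hypoxic bed
rest HBR, hypoxic ambulation HAmb), every participant crossing over through
all arms, stool sampled at days −5/−1 (run-in) and 3/10/18/21 of each 21-day
campaign. Because such studies' sequence data live in external archives, the
package ships a synthetic-data generator that emulates the design with known
planted structure, so every downstream statistic can be validated against
ground truth.

## Synthetic-data generator

**Design.** 9 participants × 3 arms × 6 sampling days = 162 samples.
Arm (campaign) order per participant follows a seeded Latin-square assignment
(cyclic shifts of the arm list). Campaign carryover is ignored: campaigns are
treated as independent, which matches how such crossover analyses treat
washed-out arms. A per-sample dropout rate is available (real studies lose
defecation events) but defaults to 0 so the full factorial layout is exercised.

**Counts.** Genus-level tables are Dirichlet-multinomial. The baseline is a
60-genus panel over five phyla with geometric-series abundances
(ratio 0.9), ordered so Firmicutes + Bacteroidetes carry ≥ 80% of the mass —
the canonical healthy-gut profile. Each participant gets a lognormal
concentration tilt (σ = 0.3 per taxon), standing in for the strong
subject-specific composition real cohorts show; each sample then draws
p ~ Dirichlet(c·π) with total concentration c = 50 (overdispersion θ ≈ 0.02,
a realistic within-subject day-to-day wobble for dominant gut taxa) and reads
~ Multinomial(depth, p). Depths are truncated-normal, mean 105,300, SD 39,200,
floor 1000 (all scaled by the `scale` factor for desk runs; tests use
scale = 0.05–0.1).

**Planted effect.** The genus *Bacteroides* has its *expected relative
abundance* multiplied by `bacteroides_fold` (default 2) in HBR samples at
days {18, 21}. The multiplier is applied with a renormalization-compensating
weight so the realized expectation is exactly fold × baseline, not
fold/(1 + (fold−1)·π). Fold 1 is the exact null. The effect ledger names the
perturbed taxon and samples.

**Chemistry inputs.** Absorbance spectra (200–800 nm, 5 nm step, dilutions
1:10/1:50/1:100) follow an exponential CDOM decay a₀·exp(−S(λ−275)) plus
Gaussian chromophore bands near 280 nm (aromatics) and 217 nm (indole-like),
converted to absorbance via A = a·l/2.303 with l = 2/3 cm, divided by the
dilution, plus additive noise (SD 0.003 A). TSOC (total soluble organic
carbon per g dry matter) is lognormal around 25. Conductivity runs mimic the
IEC protocol: per-participant baselines near 2.5 mS/cm, intervention samples
(day ≥ 3) raised by the configured week-1 fractions (HBR +67%, NBR +32%,
HAmb 0%), a slow multiplicative electrode gain drift, and 1 M KCl standards
plus 10-fold dilutions measured in triplicate every five samples. HPLC peak
tables (sterols, polyphenols) share a retention-time registry across samples
with lognormal areas and, by default, no group effect. Three metadata
matrices (109/12/110 variables) are standard normal noise except a configured
subset linearly coupled to the per-sample latent ln-*Bacteroides* gradient.

**What the generator does not emulate:** read-level errors, chimeras,
primer bias, archaeal detection limits, taxonomic misassignment, or true
temporal autocorrelation beyond the participant tilt. Passing tests therefore
demonstrate correctness of the statistics under a clean compositional model,
not robustness to sequencing artefacts.

## Chemistry

Napierian conversion a = 2.303·A/l with l = 2/3 cm. Per sample the working
dilution is the least-diluted spectrum whose maximum absorbance over
217–420 nm lies in [0.05, 1.0] (the photometrically reliable band); when no
dilution qualifies the nearest-to-range spectrum is used with a warning.
Indices: indole ratios a(217)/a(365) and a(287)/a(365); SUVA = A(254)/TSOC
(254 nm, the standard SUVA254 convention); SViA = A(420)/TSOC;
cDOM = a(350)/TSOC; and the lignin-phenol model
ln(TDLP₉) = −2.282·ln a(350) − 8.209·ln a(275) + 11.365·ln a(295) + 2.909,
applied to the per-cm Napierian coefficients with no unit rescaling.
TSOC-normalized indices use dilution-corrected (undiluted-basis)
coefficients so all dilutions of a sample agree; the ratio indices are
dilution- and path-length-invariant by construction. Undefined indices
(non-positive denominators) propagate as NaN, never zero. IEC calibration is
a linear fit of measured vs nominal standard conductivity (warn below
R² = 0.99), sample readings mapped through the inverse fit; drift is the
relative change of per-batch mean standard readings against the first batch,
flagged above 5%.

## Alpha diversity

The 13-index suite (Taxa_S, Individuals, Dominance, Simpson 1−D, Shannon H,
Evenness e^H/S, Brillouin, Menhinick, Margalef, Equitability J, Fisher α,
Berger–Parker, Chao-1). Shannon uses the natural log (mothur convention).
Chao-1 is the bias-corrected form S + F₁(F₁−1)/(2(F₂+1)), defined even with
no doubletons. Fisher's α solves S = α·ln(1+N/α) by bracketed bisection with
Newton polish (residual < 1e−10). Margalef and Equitability return missing
for N = 1 / S = 1 instead of infinities. Count-only indices are reported as
missing in profile mode (chemical fingerprints). Default order of operations
is subsample-to-equal-depth first, then indices; the unrarefied order is also
supported.

## Distances and permutation tests

Depth normalization is one seeded multivariate-hypergeometric subsample per
sample (exact subsampling without replacement); the default depth is the
minimum column sum. Distances: Bray-Curtis, Jaccard (membership), Yue &
Clayton's ThetaYC dissimilarity 1 − Σpq/(Σ(p−q)² + Σpq), Morisita-Horn
1 − 2Σpq/(Σp² + Σq²), plus unweighted and weighted-normalized UniFrac
(delegated to scikit-bio). PERMANOVA uses the pseudo-F on squared distances;
AMOVA the Excoffier variance-component ratio σ²_among/σ²_within with the n₀
effective group size; HOMOVA the Bartlett-style
B = (N−K)·ln(pooled dispersion) − Σ(n_g−1)·ln(dispersion_g) on mean squared
within-group distances (B ≥ 0 by Jensen). Mantel is Pearson r over strict
upper triangles with joint row/column permutation, one-sided for positive
association. All permutation p-values use (1 + count)/(1 + N) and can never
be zero. Labels permute freely by default — the paired crossover layout can
be respected via an optional within-participant `strata` argument, off by
default. Default permutation counts: 9,999 (Mantel), 10,000 (group tests),
configurable. BH-FDR is the standard step-up (via statsmodels).

## Differential battery and congruency

Four per-taxon votes, a taxon is a hit only when all four fire:

1. **metastats-style**: Welch t on relative abundances with a label-permutation
   null (two-sided), sparse taxa (pooled count < 8) routed to Fisher's exact
   on the pooled 2×2; BH q across taxa; hit at q < 0.05. The permutation
   count defaults to 10,000: with m taxa the BH floor is m/(B+1), so B must
   comfortably exceed m/0.05 for the q-gate to be reachable at all.
2. **IndVal**: 100 · max over groups of specificity × fidelity, permutation p.
3. **KW-effect**: Kruskal-Wallis p < α plus an effect gate — the max pairwise
   |log₁₀(mean+ε) − log₁₀(mean+ε)| with ε = half the table-wide minimum
   nonzero relative abundance. This is a deliberate one-dimensional surrogate
   for LEfSe's "significant and large (LDA ≥ 2)" semantics. The default gate
   is 0.15 (≈ 1.4-fold): it admits the ~2-fold shifts the battery exists to
   flag (which score ≈ 0.3) and rejects smaller wobble. A stricter gate can
   be configured.
4. **AWKS core shift** (below), hit at p < 0.05.

The conjunction is monotone: tightening any threshold never adds a hit. The
Firmicutes:Bacteroidetes ratio is per-sample phylum-sum ratio (missing when
Bacteroidetes is zero); its rate of change is the least-squares slope of
ln(ratio) vs day within each participant × arm.

## Core microbiome

Ubiquity U(a) = fraction of cohort samples with relabund ≥ a over a 30-point
log-spaced grid from 1e−5 to the maximum observed relabund. The core surface
reports the fraction of taxa with U(a) ≥ u per grid cell (non-increasing in
both axes). Classification: major core if U(1e−3) ≥ 0.75; minor if not major
and U(1e−4) ≥ 0.5 (reference thresholds are configuration; published
analyses do not print their cutoffs). Variability on the
abundance–variability plot is the coefficient of variation. AWKS compares two
cohorts' ubiquity curves: D = Σ aₖ·|U_A(aₖ) − U_B(aₖ)| / Σ aₖ — an
abundance-weighted L1 gap in [0, 1], zero iff the curves coincide on the
grid; an unweighted sup-norm (classic KS) variant is available. p by
cohort-label permutation.

## Variation partitioning

Community counts are Hellinger-transformed; explained variance is RDA R²
(multivariate linear regression; R² = fitted SS / total SS), adjusted with
the Ezekiel correction using the predictor-matrix rank. Screening per
metadata matrix: marginal single-predictor RDA permutation p (default 5,000
permutations), drop p ≥ α (default 0.05) — or, in probe mode, keep only
variables beating the 95th percentile of a shuffled probe's statistic — then
prune co-correlated survivors (|r| > 0.8, dropping the member with the larger
mean absolute correlation to the rest). The three-way partition computes the
adjusted R² of all seven subsets and recovers the seven exclusive fractions
by inclusion–exclusion; fractions plus the unexplained remainder sum to 1
exactly, and negative adjusted fractions are reported as-is. The pipeline
refuses to partition when retained variables exceed n − 2.

## Pipeline

Stages simulate → chem → alpha → beta → diff → core → varpart run from one
YAML config; a single seed fans out per stage by stable name hashing so
toggling one stage never shifts another's stream. Output tables carry header
comments naming conventions (ln-Shannon, per-cm coefficients, rarefaction
depth). The manifest records config, per-stage seeds and wall times, and
SHA-256 digests of every output; two runs with one seed are byte-identical.

## Problem sizes used in the shipped tests

Simulation-based tests run the full 162-sample layout at depth scale
0.05–0.1: null calibration uses 1,000 generated datasets with 99
permutations per test; planted-effect recovery uses 50 datasets with
999-permutation votes (metastats at 10,000); screening checks use 199–499
permutations. These sizes were chosen to keep Monte-Carlo standard errors
well inside the asserted bands.

## Known limitations

* AWKS weighting is one documented interpretation of "difference of
  ubiquities across abundances"; the originating toolkit's exact weights are
  not published in the source narrative.
* The LEfSe surrogate ignores subclass conditioning and the LDA projection
  entirely; it preserves only the significance + effect-size gate semantics.
* Free permutation is approximate for crossover data (samples within a
  participant are exchangeable with each other, not with everyone); the
  constrained mode exists but is not the default, matching the source
  analyses.
* Enterotyping (Dirichlet-multinomial mixtures), Picrust-style functional
  imputation, and strain-level k-mer assignment are out of scope.
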