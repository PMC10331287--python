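# Methods

## Chemistry and mass arithmetic

All masses are monoisotopic, computed from a fixed atomic-mass table
(C 12.000000, H 1.0078250319, N 14.0030740052, O 15.9949146221,
P 30.97376151 Da) so results are bit-reproducible.  Lipid formulas are built
by condensation chemistry rather than looked up: glycerolipids are glycerol
plus the free fatty acids minus one water per ester bond; phosphatidic acid
starts from glycero-3-phosphate; PC/PE/PG/PI/PS attach their head alcohol
(choline, ethanolamine, glycerol, inositol, serine) with one more
condensation; lyso forms drop one acyl and one water; sphingolipids amidate
a fixed d18:1 sphingoid base (d18:0 for dihydroceramide) and optionally add
phosphocholine, hexose, or two anhydrohexose units (lactosylceramide).
These rules reproduce the masses of authentic standards such as
tripentadecanoin (C48H92O6, 764.6894 Da).

Unsaturation is positional-agnostic: a double bond removes two hydrogens
(2 Da nominal), so monounsaturated and diunsaturated species differ from the
saturated species by exactly 2 and 4 Da at nominal resolution.  Double-bond
positions, cis/trans geometry and sn-positions are not modeled — a
quadrupole MRM experiment cannot resolve them, and validated assignments
only claim the presence of an acyl, not its position.

Ion m/z includes the electron mass (±0.000549 Da per charge).  This is far
below unit resolution but costs nothing and keeps the arithmetic exact.
Adduct deltas: +NH₄ = +18.034374, +H = +1.007825, −H = −1.007825,
+CH₃COO = +59.013305 Da (before electron correction).

### Choices that were genuinely open

* **PC/LPC negative-mode precursor**: the acetate adduct [M+CH₃COO]⁻,
  consistent with an ammonium-acetate mobile phase; overridable per call,
  since some laboratories use formate or monitor PC in positive mode.
* **Sphingolipid product ions**: SM → protonated phosphocholine (184.0733);
  Cer/HexCer/LacCer → the doubly dehydrated d18:1 base ion (264.2686);
  dhCer → 266.2842.  These are the conventional class-diagnostic fragments.
* **Canonical acyl order** in names and transition sets is
  (carbons, double bonds) ascending; swapping sn labels never changes a
  transition set.

## ECN retention-time model

Within a subclass on reverse-phase LC, retention increases smoothly with
acyl carbon number and decreases with unsaturation.  The model is

    y = a + b·x + c·x²,  x = CN / CN_max,  y = RT / t_gradient

fitted by unweighted OLS.  Parameters:

* `gradient_minutes` — default 17.0 (total runtime of the emulated 17-min
  gradient).  The normalization denominator is ambiguous between "end of
  hold" (15 min) and total runtime; since y is only a scale, the choice does
  not affect R² or predictions, and it is user-settable.
* `CN_max` — the largest calibrated CN of the subclass, keeping x ∈ (0, 1].
* **Stratification** — one fit per (subclass, double-bond count).  Strata
  with fewer than three usable points inherit the saturated fit shifted by
  a constant per-stratum offset estimated from whatever points exist (or a
  pooled per-double-bond offset).  This encodes the empirical pattern that
  unsaturation shifts elution earlier by a roughly constant amount.
* Predictions more than 4 carbons outside the calibrated range are returned
  flagged EXTRAPOLATED rather than refused.

A 12-point panel with RT noise of 1 % of the gradient yields median R²
≈ 0.998 (the acceptance script measures this); coefficient bias is < 5 %
of the true values over 200 replicates.

## Scheduled-MRM design

* Window half-width: 0.5 min by default — the worst observed prediction
  error of the ECN model — widened per species when the deviation report
  flags a larger error.
* Dwell tiers: high/medium/low abundance get 1×/2×/3× the minimum dwell
  (3 ms) before rescaling.  Abundant lipids need fewer ions per cycle;
  giving scarce lipids longer dwells costs nothing until windows overlap.
* Cycle budget: 0.75 s, from requiring ≥ 8 points per peak at the narrowest
  plausible peak (0.1 min FWHM).  Within each connected cluster of
  overlapping windows, dwells are scaled down (never below the minimum) so
  that Σ(dwell + pause) ≤ budget at every time point; a budget infeasible
  even at minimum dwell raises an error naming the congested RT interval.
* Pause time 2 ms per transition (generic triple-quadrupole overhead).
* Transitions sharing (Q1, Q3, polarity) within one RT bin — acyl isomers
  of one sum composition — are merged into a single scheduled entry.

The budget invariant is verified exhaustively on a 0.01-min grid in the
tests; exports are deterministic and byte-identical for identical inputs.

## QC and quantification

Abundance = analyte area / matched-IS area per sample; because analyte and
IS share the injection, any global per-sample drift cancels exactly.
Filters (composable in any order):

* CV across ≥ 3 pooled-QC injections < 20 %, using the (n−1) sample
  standard deviation.
* Mean study signal > 5× mean blank signal.  The aggregation (mean vs
  median) is an option; mean is the default.
* Median S/N ≥ 10.

Species with > 30 % missing cells are dropped before statistics; remaining
gaps are imputed with half the species minimum (standard detection-floor
imputation; the floor choice matters little after log transform).

## Differential statistics

Preprocessing: drop the lowest-IQR 10 % of species, log₁₀ transform, Pareto
scale ((x − mean)/√sd).  The log base cancels in every downstream statistic.

Univariate: two-sided Welch t-test on processed data, Bonferroni adjustment
P_adj = min(1, m·P), fold change on raw-scale group means (direction encoded
as g2/g1).  The selection rule uses raw P by default — both raw and adjusted
are reported, and the threshold is configurable — because a Bonferroni
cutoff at m ≈ 250 species would require effect sizes no 12-subject design
can deliver, and the rule is a triage filter backstopped by VIP and FC.

Multivariate: two-class PLS-DA via NIPALS against a centered ±1 response.
Discriminant analysis is deliberately PLS-DA rather than OPLS-DA: the
orthogonal filter is a proprietary-software variant, and for two-class
problems with one predictive component the VIP ranking and S-plot are
equivalent in practice.  VIP_j = √(p · Σ_a SS_a w_ja² / Σ_a SS_a) with
unit-norm weights, so Σ_j VIP_j² = p exactly.  Q² uses 7-fold
cross-validation, stratified by group and seeded (default 20230529) for
reproducibility.  S-plot coordinates are (cov(t₁, x_j), corr(t₁, x_j));
the SUS-plot pairs the correlations from two comparisons, so species
regulated oppositely in the two comparisons fall in the second/fourth
quadrants.

Selection: differential ⇔ P < 0.05 ∧ VIP > 1 ∧ max(FC, 1/FC) ≥ 1.2
(the "FC ≥ 20 %" criterion read direction-agnostically); volcano ⇔
max(FC, 1/FC) ≥ 2 ∧ P < 0.1.

## Synthetic data: what it emulates and what it does not

The generator emulates the study conditions end to end: three groups
(CC-A/CC-B/CC-C = distant-normal / adjacent / tumor) of 12 samples, a
compact 282-species odd-chain library (TAG, DAG and six diacyl phospholipid
classes over odd acyls 15:x/17:x with even partners 16/18), 10 consecutive
pooled-QC injections, 3 solvent blanks, and an IS panel (9 standards per
subclass across both unsaturation strata) whose RTs lie on per-subclass ECN
curves.

Noise model and defaults:

* areas — multiplicative log-normal: biological σ = 0.25 (natural log,
  ≈ 25 % CV), QC injection σ = 0.07, per-sample drift σ = 0.05 shared
  between analytes and IS;
* planted effects — TAG ×2.0 and PA/PC/PG ×0.5 in the adjacent group only,
  so the two comparisons show mirrored fold changes;
* RT — Gaussian, sd 0.17 min (1 % of gradient) on calibration standards,
  0.05 min on observed peaks; FWHM uniform on 0.1–0.7 min; blanks at 5 % of
  the study signal with S/N 1–5.

The closed loop (simulate → QC → quantify → statistics) recovers ≥ 90 % of
planted species with ≤ 10 % false positives under the differential rule,
and the S-/SUS-plots show the planted TAG-up / phospholipid-down quadrant
pattern.

What the generator does **not** model — and therefore what passing tests do
not demonstrate about real data: ionization suppression and matrix effects,
correlated species (the covariance is diagonal), peak-integration errors,
batch effects beyond a scalar drift, missing peaks, isomer interference,
and real retention behavior beyond a quadratic trend.  Parameter-recovery
results on this generator are a check of the machinery, not a validation of
the method on tissue.

## Problem sizes

Deliberately desk-scale: the simulated study uses 282 species × 49
injections; ECN calibration checks use 200 replicates of 12-point panels;
QC checks 50 replicates of a 100 × 10 matrix; scheduler invariants are
checked on ~200 transitions over a 17-min gradient at 0.01-min resolution.

## Known limitations

* Fragmentation rules cover the implemented subclasses only; ether and
  vinyl-ether (plasmalogen) lipids, oxidized lipids and charge states > 1
  are out of scope.
* The sphingoid base is fixed at d18:1/d18:0; variable bases (d16:1, t18:0)
  would need additional backbone rules.
* The ECN fallback for sparse unsaturation strata assumes a constant RT
  offset per double bond, which degrades for polyunsaturated species.
* PLS-DA VIP with more than one predictive dimension can diverge from
  OPLS-DA VIP; for the two-class designs here the first component carries
  essentially all class variance.
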