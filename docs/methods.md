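# Methods

This note documents the models, defaults and design decisions behind
`domtrace`: what each stage computes, why the synthetic campaign looks the
way it does, and what the passing tests do and do not demonstrate about
real monitoring data.

## Processing chain

Stages run in a fixed order; each consumes and produces a valid centroided
spectrum. The order — S/N filter → recalibration → blank subtraction →
replicate intersection → TIC normalization — puts mass-scale correction
before any cross-spectrum m/z matching, so that the 2 ppm matching
tolerance is meaningful.

**Noise estimation and S/N filter.** Electronic noise has no chemistry: its
m/z values spread uniformly over the CH₂-based Kendrick defect scale,
while plausible CHNOS compositions avoid part of it. The noise level is the
10 %-trimmed mean intensity of peaks whose Kendrick defect
(`ceil(KM) − KM`, KM = m/z · 14/14.01565) falls in the void window, default
(0.90, 0.95). If fewer than 10 peaks lie there, the estimator falls back to
the median of the lowest-intensity quartile; the estimate records which
branch ran. Peaks with intensity strictly above 10× the level survive. The
fallback is deliberately conservative and is only expected to be accurate
when a spectrum actually contains a noise floor; on noise-free synthetic
spectra it overestimates noise, which is why the generator always plants
noise peaks by default.

**Recalibration.** The mass error is modelled as linear in m/z,
`error_ppm = a + b·m/z`, fitted by least squares on recalibrant pairs and
inverted on every peak. Recalibrants are picked internally: peaks receive
provisional CHO-only assignments at 3 ppm, and the longest CH₂-homologous
series (same O count and DBE, consecutive C) among *unique-candidate*
matches is used — a single mis-assigned recalibrant distorts the fit far
more than omitting a dim one, hence uniqueness rather than an intensity
cutoff. Ties between equal-length series go to the larger summed intensity.
A coverage flag is raised when the recalibrants do not span from ~m/z 110
up to the m/z where cumulative intensity reaches 80 % of the total. A
linear model suffices to bring the synthetic generator's error model (and
any error ≤ 5 ppm with sub-ppm curvature) below 1 ppm residual; a spline
upgrade would slot into the same interface.

**Blank subtraction.** The removal set is the smallest prefix of
highest-intensity blank peaks whose summed intensity reaches 95 % of the
blank total ("up to 95 %" is resolved toward inclusivity: the peak that
crosses the threshold is removed too). Sample peaks within 2 ppm of any
removal m/z are dropped. Multiple blanks are pooled before the rule is
applied.

**Replicate intersection.** Groundwater samples are measured in duplicate;
only features found in both replicates are kept. Matching is closest-first
one-to-one within 2 ppm; the consensus m/z is the intensity-weighted mean
and the consensus intensity the arithmetic mean (unbiased under symmetric
noise; min/max would bias the indicator).

**Tolerances.** 2 ppm everywhere downstream of recalibration (blank
matching, replicate matching, feature alignment): twice the guaranteed
post-recalibration accuracy. Duplicate peaks closer than 0.2 ppm — below
instrument resolution — are merged already on load.

## Formula assignment

Neutral masses (`m/z + 1.007276` for [M−H]⁻) are matched against all
CHON₀₋₄S₀₋₁ compositions within tolerance (default 1 ppm) that pass the
community-standard DOM plausibility filters: integer non-negative DBE
(`C − H/2 + N/2 + 1`; integrality encodes the nitrogen rule), DBE ≤ 25,
H/C ∈ [0.3, 2.5], O/C ≤ 1.2 — all configurable, since the constraint set of
any given assignment tool is a convention, not physics. Candidates are
ordered by |ppm error|, then fewest heteroatoms (N+S), then fewest O; the
`strict` policy (default) assigns only unique candidates, `best` takes the
top of the order. Internally the enumeration binary-searches a precomputed
mass-sorted table of every valid composition; the tests verify it against
an independent exhaustive grid scan. Assignment feeds the QC metric
(fraction of total intensity carried by assigned peaks) and the pathway
screen; the PS indicator itself deliberately uses **all** S/N-passing m/z
values, assigned or not.

## Similarity and trend

Feature alignment pools all peaks, sorts by m/z, and breaks clusters where
the gap to the left neighbour exceeds 2 ppm or the cluster width would
exceed 4 ppm; each sample contributes at most one peak per feature (highest
intensity wins) and columns are renormalized — PS is therefore computed on
per-sample relative abundances that sum to one after alignment. PS against
the seepage reference set is averaged over references (mean, not median,
matching the averaging rule of the reporting convention). Two QC statistics
accompany the PS table: the standard deviation among pairwise PS values of
the seepage references themselves (surface heterogeneity), and a drift
report on the repeated reference standard (standard deviation plus a
Kendall test of PS against measurement order; drift is declared at
p ≤ 0.05, so the alarm fires at the nominal 5 % rate on a stable
instrument).

PS series are placed on a regular calendar-quarter grid (multiple samples
per well-quarter averaged, gaps left missing) and decomposed with
`statsmodels` STL using period 4, seasonal window 5, trend and seasonal
degree 1. Missing points are linearly interpolated for the decomposition
and their remainder set to NaN; the additive identity
trend + seasonal + remainder = observed holds exactly at observed points.
The drought breakpoint (July 2018 in the motivating campaign) is always a
parameter, never inferred or hard-coded; piecewise slopes are two
independent OLS fits on [start, break) and [break, end]. Kendall tau-b
(exact p for n ≤ 10 without ties) serves the variance-trend and drift
tests; Spearman is the default for the F¹⁴C–PS and pathway correlations
("rank correlation"), with Kendall selectable.

Intra-annual isotope variance is the unbiased sample variance
Σ(x − x̄)²/(n − 1) per well-year (well-years with n < 2 dropped), with a
per-well Kendall trend of variance against year.

## Pathway screen

Assigned formulas map to pathways through a compound table; a formula in
several compounds unions their pathway sets. Abundance accounting is
**multi-counting**: a formula's relative abundance is added in full to every
pathway it maps to. Isomer ambiguity makes any accounting a convention;
multi-counting is symmetric and monotone, and a split-abundance alternative
(divide by the number of pathways) is available by flag. Per-well MAG
pathway-presence profiles act as a hard constraint: a pathway absent from a
well's metagenomes is not counted for that well's samples. Pathways are
retained when ≥ 10 distinct formulas **or** ≥ 25 % of their theoretical
length are detected (both inclusive); "theoretical length" is the count of
distinct member formulas — counting reaction steps instead would need
reaction data the compound table does not carry. Retained pathways are
screened by Spearman correlation of per-sample summed abundance against
mean PS; significance requires rho > 0 and Bonferroni-corrected p < 0.01,
with the correction factor equal to the number of retained pathways. Two
ambiguity metrics are reported: the fraction of detected formulas mapping
to exactly one pathway, and the fraction of assigned formulas matching any
pathway.

## Synthetic campaign: what it emulates, and what it does not

The generator reproduces the *sampling design* of a multi-year monitoring
programme: quarterly groundwater duplicates per well over eight years
(matching the STL period of 4), recurring soil-seepage samples from a few
surface locations, procedural blanks, and an interspersed reference
standard measured twelve times.

Groundwater spectra are two-endmember mixtures
`α(t)·seepage + (1 − α(t))·deep` with α carrying a baseline (0.2), a linear
trend (0.0375 yr⁻¹, i.e. 0.2 → 0.5 over eight years), a quarterly sinusoid
(amplitude 0.03), and a step (0.05) at the 2018-07-01 breakpoint; an
optional post-break slope replaces the pre-break slope to express the
accelerated changeover after the drought. α is clipped to [0, 1] and the
seasonal phase is fixed per well at seed level.

Structural choices worth knowing:

- **Endmember intensities** are log-normal (σ = 1) — the heavy-tailed
  abundance profile of DOM spectra — over a library of ~500 plausible
  formulas partitioned into seepage-only (26 %), deep-groundwater-only
  (26 %), shared background (≈ 44 %) and blank contaminants (4 %).
- **Shared formulas carry the same intensity in both endmembers, and the
  seepage-only block is rescaled to the deep-only block total.** Mixing
  then preserves the TIC, so a feature's relative abundance is linear in α
  and background pathways have an exactly null abundance trend. Without
  this control, essentially every pathway whose members are imbalanced
  between endmembers acquires a deterministic monotone trend and the
  false-positive behaviour of the screen would be untestable.
- **Three CH₂-homologous CHO series** are planted in the shared background
  so every sample supports series-based recalibration, mirroring the
  homologous-series structure of real DOM.
- **The library avoids the Kendrick void band** (0.89–0.96), as real
  chemistry does; planted noise peaks (uniform m/z, none within 5 ppm of a
  library formula, intensities near the floor) populate it instead, which
  is what makes the noise estimator work on real spectra.
- **Noise model:** multiplicative log-normal intensity noise (CV 0.2,
  a typical DI-HR-MS replicate scatter), per-peak detection dropout
  (p = 0.05, exercising the replicate-intersection rule), per-spectrum
  linear calibration error (intercept ~ N(1.2, 0.4) ppm, slope
  ~ N(0, 3·10⁻⁴) ppm/Th, plus 0.03 ppm per-peak jitter), and location-level
  heterogeneity of the seepage endmember (log-normal, σ = 0.3).
- **Pathway database:** 30 pathways of 12–30 member formulas; 6 enriched
  pathways draw ≥ 80 % of members from the seepage-only subset (rest
  shared), background pathways draw 70 % shared / 30 % deep-only and never
  seepage-only; MAG profiles mark enriched pathways present in every well
  and others with probability 0.85.
- **Isotopes:** δ¹⁸O per well-year as a seasonal sinusoid (amplitude
  0.1 ‰) plus Gaussian noise whose variance grows linearly per year. The
  trend-power scenario uses base 0.04 ‰², growth 0.12 ‰² yr⁻¹ over ten
  years with monthly sampling — a variance ratio of ~30, chosen by power
  analysis (the log-variance step per year must clear the χ² sampling noise
  of an 11-df variance estimate) to sit clearly in the "strong growth"
  regime.

All randomness flows through `numpy` `SeedSequence`s keyed on
(seed, stream index), so regeneration from (config, seed) is bit-identical,
and the full ground truth (trajectories, library partition, endmember
vectors, per-spectrum calibration error, enriched pathway set) is stored as
JSON next to the generated peak lists.

What the generator does **not** emulate: instrument peak shapes (centroids
only), isotopologue patterns and ¹³C satellites, adducts and multiple
charging, compound-class-specific attenuation during soil passage (mixing
is linear per feature), correlated noise between co-eluting — here
co-infused — features, matrix and ionization-suppression effects, aquifer
hydraulics and isotope-fractionation physics. Passing recovery tests
therefore demonstrate that the *statistical chain* is correct and sensitive
at realistic noise levels, not that any particular field campaign will show
these effect sizes.

## Measurement protocols used by the acceptance checks

Two conventions in the recovery checks are part of the protocol, fixed
before measurement: PS values are pooled per quarter across the three
wells before trend fitting (the per-sample PS noise of ~1.3 pp would
otherwise dominate the slope estimates), and the post-drought slope ratio
is reported as the median over three replicate campaigns, since a ratio of
two OLS slopes is heavy-tailed when the denominator slope is small. The
slope-doubling scenario injects 0.04 → 0.08 yr⁻¹ so that each slope exceeds
roughly six times its standard error — the precision needed for a ratio to
be informative at all.

## Numerical and degenerate-input conventions

- Strict inequality at the S/N threshold; inclusive thresholds in the
  pathway filter; Bonferroni p capped at 1.
- All-tied Kendall input raises a degenerate-input error; the drift report
  maps a constant series to tau 0, "no drift".
- An all-zero spectrum cannot be normalized (error); an empty assignment
  set yields an explicitly undefined QC fraction rather than 0.
- Ratio of piecewise slopes is +inf when the pre-break slope is exactly 0.
- Feature alignment is deterministic and order-independent (pooled global
  sort; width-capped single-linkage).

## Known limitations

- The linear calibration model cannot remove strongly curved mass-error
  profiles; the residual-RMS and coverage fields of the calibration model
  are the guard rails.
- Single-linkage alignment can, in principle, chain distinct features
  under extreme peak density; the 2×tolerance width cap bounds the damage.
- The screen's pooled correlation ignores well identity; a per-well subset
  rerun is available, but a mixed-effects formulation is out of scope.
- STL edge behaviour differs slightly between LOESS implementations;
  recovery tolerances, not coefficient equality with any particular
  implementation, are the contract.
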