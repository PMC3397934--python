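# Methods

## The estimation problem

An iTRAQ 4-plex experiment compares two conditions (Treg, Teff) whose
tryptic peptides carry isobaric labels.  On fragmentation each label
releases a reporter ion (nominal m/z 114–117; monoisotopic 114.1112,
115.1083, 116.1116, 117.1150 Da), and the reporter intensity is
proportional to the peptide's abundance in the corresponding sample.
Each experiment uses two of the four channels; the condition→channel map
rotates across experiments (default design: Treg on 114/115/116/117
against Teff on 117/114/114/114) so that label-specific artifacts do not
align with condition.

The quantity of interest per protein is the regulation factor
RF = Treg/Teff, reported on the signed scale: ρ ≥ 1 ↦ ρ, ρ < 1 ↦ −1/ρ.
This leaves a hole in (−1, 1) by construction; wherever a mean or median
of signed values lands in that hole it is snapped to the nearer boundary
(+1 on ties at 0) and flagged rather than reported as an impossible
value.

## Preprocessing

**Reporter extraction.** Peak intensities within ±`reporter_tolerance_da`
of each canonical reporter m/z are summed; the default 0.05 Da suits
low-resolution Q-TOF profiles (0.02 Da is appropriate for Orbitrap-class
data).  Tolerances that would make adjacent reporter windows overlap
(≥ ~0.5 Da) are rejected as configuration errors.

**Isotope-impurity correction.** Label reagents carry isotope envelopes
that leak a few percent of each channel's signal into its ±1 Da
neighbours.  With purity matrix P (row = true label, column = observed
channel, rows summing to 1) the observed vector is Pᵀ·x; the correction
solves this 4×4 system exactly.  Negative solutions — possible when
noise makes observations slightly inconsistent — are clipped to zero and
flagged, because the downstream likelihood assumes non-negative signals.
The default matrix is the identity (pre-corrected data); a realistic
example matrix with 1–6% leakage ships in `kinoquant.constants`.

**Normalization.** Unequal loading of the two samples shifts every ratio
by a constant.  The default (`total`) rescales each active channel so
that the channel totals over contributing peptides (unique, score above
the identification threshold) equal their grand mean.  A `median` option
instead centers the median per-peptide log-ratio at zero, which is more
robust when a large fraction of the catalog is regulated; `none` skips
rescaling.  Only the experiment's two active channels participate.
Total-sum equalization is exactly idempotent and preserves within-peptide
ratios up to the global scalars.  Note its known bias: with an
asymmetric regulated fraction the scale factors absorb part of the real
signal; at the default study conditions (5% regulated) the shift is
below 2% and immaterial against the 1.5-fold calling threshold.

## Noise model and likelihood

Reporter noise is modelled as additive Gaussian with standard deviation
σ(I) = σ₀ + c·I — a floor σ₀ (intensity units) for detector/chemical
background and a dimensionless proportional coefficient c for ion
statistics.  This affine family is the simplest that captures both
regimes; instrument-specific parameters are free parameters of the
package, not reconstructions of any particular device.

For a peptide with corrected/normalized intensities (t, e) on the
(Treg, Teff) channels, the latent true Teff signal μ is a nuisance
parameter.  The package profiles rather than integrates it:

    ℓ(ρ) = max_{μ>0} [ log N(e; μ, σ(μ)) + log N(t; ρμ, σ(ρμ)) ]

For unimodal Gaussians profiling and marginalizing agree to within
normalization, and profiling keeps the computation a fast 1-D search.
The curve reported is exp(ℓ(ρ) − ℓ_max) on a 400-point log-spaced grid
over [1/50, 50] (configurable).  Implementation notes:

* For each grid ratio, μ is profiled on a per-ratio geometric grid
  spanning the two naive estimates (e and t/ρ) with ×0.3/×3 margins,
  sharpened by 3-point parabolic interpolation; the final maximum and
  the value at ρ = 1 are re-evaluated by exact bounded 1-D optimization
  (`scipy.optimize.minimize_scalar`), so the curve's maximum is exactly
  its value at the reported MLE.  Against a dense 2-D grid search the
  MLE agrees to well under 1% over the tested intensity/noise ranges.
* A peptide with one zero channel still yields a curve but is flagged
  `boundary`, as is any curve whose maximum touches the grid edge;
  both zero channels is an error (undefined ratio).
* "Separated from RF = 1" is operationalized as relative likelihood at
  ρ = 1 below α (default 0.05).  Under a correctly specified noise
  model the per-curve false-exclusion rate is ≈ P(χ²₁ > 2·log(1/α)) ≈
  1.5%, and the simulated null study measures ~2% at the protein level.

**Calibration.** When σ₀ and c are not fixed in the configuration they
are estimated from the data's unregulated bulk: peptides whose log-ratio
lies within three robust SDs of the median are rescaled onto a common
loading, and the per-intensity-bin standard deviation of
(t′ − e)/√2 is regressed linearly on bin mean intensity (intercept σ₀,
slope c, clipped at 0).  The slope is scale-invariant and recovered
within ~10% at 2000 peptides in simulation; the intercept is weakly
identified when c·I ≫ σ₀, which is harmless for the same reason.

## Protein rollup and differential calling

Within one experiment a protein's point estimate is the arithmetic mean
of its unique peptides' signed RFs (displayed to one decimal); its
significance comes from the product of the peptide curves (sum of log
relative likelihoods, renormalized, maximum located by parabolic
refinement).  The mean-of-signed-values estimator was chosen because it
reproduces the reference CDK6 worked example exactly (mean of the 12
printed peptide RFs is −3.69 → −3.7, where a geometric mean of ratios
gives ≈ −3.6).

Across experiments, each experiment receives a symbol: '−' if RF ≤ −1.5,
'+' if RF ≥ +1.5, else '0' — thresholds inclusive.  A protein is called
`down` iff at least `min_regulated_experiments` (default 2) experiments
carry '−' *and* the median signed RF over the experiments in which it
was quantified is ≤ −1.5 (symmetrically for `up`).  The median over an
even count is the mean of the two central signed values, snapped into
the convention if needed.  In the full pipeline a '−'/'+' symbol counts
toward the replication criterion only if that experiment's combined
curve also excludes unity; when calls are made from bare RF values (no
curves) the rule is purely threshold-based.  Missing experiments are
excluded from the median but still count against the absolute
replication requirement.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes: a
catalog of `n_proteins` = 200 enriched proteins, 40% kinases (8% of
those with non-protein substrates, the rest uniform over the ten Manning
groups), 5% of proteins truly regulated with |RF| drawn uniformly from
[2, 5] and random sign, regulation preferentially placed on kinases.
Each protein contributes 3–10 unique tryptic-like peptides per
experiment; base intensities are log-normal (log-mean 7, log-SD 1,
i.e. median ≈ 1100 counts) and shared by the two channels of a spectrum,
peptides of one protein being independent draws — matching the spread of
per-peptide RFs around a common protein RF seen in real tables.  True
channel vectors (Teff = base, Treg = base·ρ, unused channels 0) are
mixed through the configured purity matrix — so unused channels receive
leakage and exercise the correction path — and perturbed with
N(0, (σ₀ + c·I)²) noise truncated at zero, defaults σ₀ = 5, c = 0.05.
Identification scores are Gaussian (kinases 55 ± 18, others 35 ± 12,
floor 8), reproducing the enrichment-quality contrast between kinases
and background proteins and leaving some evidence below the score-20
cutoff; 5% of peptides are flagged non-unique.  Four experiments with
the rotating label design are the default; the study-level truth is
drawn from a child of the seed so all experiments share it, and
identical seeds give byte-identical MGF/TSV outputs.

What the generator does **not** emulate: chromatographic separation and
SCX fractionation, co-isolation interference, missed cleavages, PTMs,
decoy identifications, protein-level intensity correlations between
experiments, or heavy-tailed (non-Gaussian) outlier spectra.  Passing
parameter-recovery tests therefore demonstrates internal consistency of
the estimation chain under its own noise assumptions, not robustness to
every artifact of real LC-MS/MS data.

## Problem sizes and numerical choices

The simulation-based checks use a 4-experiment, 200-protein study
(≈ 5000 peptide spectra, ~15 s end to end) for parameter recovery and a
1-experiment, 500-protein unregulated study for null calibration —
sizes chosen so each check completes comfortably on one CPU while
leaving the binomial error of the measured rates well inside the stated
bounds.  Likelihood grids default to 400 points; determinism everywhere
derives from a single integer seed via `numpy` seed sequences.

## Known limitations

* The noise model is a stand-in for whichever device-specific model a
  given instrument warrants; no numeric equivalence with any published
  in-house tool is claimed.
* Only two-condition (one ratio) contrasts per experiment are supported;
  multi-condition 4-plex designs are out of scope.
* Normalization is global, not per-fraction; per-SCX-fraction loading
  drift is not modelled or corrected.
* Identification is taken as given input (scores and uniqueness flags);
  no database searching or FDR control is performed.
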