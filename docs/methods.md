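# Methods

## Isotope chemistry

Isotope masses and abundances are pinned to one published IUPAC/CIAAW table
shipped as package data (`data/isotopes.csv`; natural ¹³C = 0.0107).
Patterns are vectors over *nominal* mass offsets: the −3.8 mDa defect of a
²⁹Si isotopologue relative to a ¹³C isotopologue at the same nominal offset
is not resolved during correction, matching how MID correction is done in
practice. High-resolution mass defects matter only in the extraction
windows, where isotopologue centers follow the ¹³C series (spacing
1.00336 Da, ±0.005 Da tolerance) and near-lying ²⁹Si species are collected
and later removed by NIA correction. Patterns are tail-pruned below 1e−9
and renormalized; downstream identities therefore hold to ~1e−8 rather than
machine precision, which is far below every stated tolerance.

## Fragment registry

The registry is data (CSV), not code. Certified entries cover the aspartic
acid 3TMS ions m/z 350 [M+H]⁺, m/z 349 [M]⁺ (both {1,2,3,4}) and m/z 232
({2,3,4}). The m/z values and formulas of the two-carbon 3TMS fragments
({1,2}, {2,3}, {3,4}) and of the 2TMS alternatives (m/z 262/245/160) are
not publicly documented; they ship as `requires-user-input` placeholders,
and a companion file of **synthetic stand-in** formulas
(`data/synthetic_fragments.csv`, chemically plausible but not certified)
resolves them by default so the simulation-driven pipeline runs end to end.
Positional analysis takes the whole-backbone enrichment from m/z 349: the
[M+H]⁺ ion at m/z 350 is flagged because its MID is superimposed with the
[M]⁺ MID one ¹³C spacing below (the extraction windows genuinely collect
both, as the write→extract round trip demonstrates); correcting that
overlap is left as an external hook.

## NIA correction

The correction matrix column for tracer count j is
`natural(formula − n backbone C) ⊗ shift(j) ⊗ binomial(n−j, 0.0107)`.
The solver is non-negative least squares on the sum-normalized MID;
an unconstrained least-squares route (negative fractions clipped and
flagged) is retained as a cross-check. NNLS is the default because at low
abundance unconstrained solves produce negative fractions. Residuals above
5 % of the measured norm flag `poor_fit`. When the measured vector is
shorter than the matrix, trailing rows are dropped and columns renormalized
(flagged). Measured vectors default to n_tracer + 3 extra masses to capture
the Si-driven envelope tail.

Two conventions deserve note:

* **Certificates are total atom fractions.** A standard certified at atom
  fraction p comes back from correction with tracer enrichment
  (p − a)/(1 − a) where a is natural ¹³C — e.g. 98.99 % for a 99.0 %
  certificate — because the natural share of a labelled position is
  attributed to the unlabelled pool. Expected values for mixture validation
  use mole fraction × purity (the certificate convention); the ~0.01 pp
  convention gap is negligible against the 1 pp accuracy bound. Measured
  values are never purity-corrected; purity enters only the expectations.
* **Enrichment estimators are ratio estimators.** Normalizing the MID (and
  the recovered fractions) makes E¹³C biased at second order in the noise
  CV (~0.07 pp at CV 1 % for a highly enriched standard, first order if the
  non-negativity constraint becomes active at a boundary). The bias-free
  convergence test therefore runs at small CV on a mixture whose tracer
  fractions are interior.

## Positional algebra and error propagation

The four linear combinations invert the carbon-number-weighted averaging
exactly; their linearity implies mean(e₁..e₄) = E¹³C₁₂₃₄ identically. SDs
propagate under an independence assumption (weights 16+9, 9+4, 4+4+9, 9+4);
fragments share the ion source, so correlations are possible but unknown —
a documented limitation. Noise can push positions slightly negative; values
are reported as-is with a flag (never clipped) so accuracy statistics stay
unbiased. When the two-carbon fragments are unavailable (typical for
nominal-mass EI data), the dependent positions are NaN (undetermined), not
imputed. `cross_check` compares alternative calculations per position and
flags pairwise disagreements above a tolerance (default 0.02).

## Quantification

The quantifier is the sum of all isotopologue abundances, so the labelling
state does not bias concentration. Response = sum / ¹³C₆-sorbitol internal
standard (25 ng per injection in all fixtures); an ordinary least-squares
line over ≥3 calibration levels maps response to ng; split ratio and a
single configurable aliquot factor (default 1) scale to the sample;
133.103 g/mol converts to pmol, normalized by OD₇₅₀ × volume. Responses
outside the calibration range are flagged, negative inversions clip to 0
with a below-range flag.

## Sigmoidal kinetics

A three-parameter logistic with the baseline pinned at 0 (no label before
the pulse) is fitted by least squares over a deterministic multi-start grid
(k ∈ {0.01, 0.05, 0.2, 1} min⁻¹ × t_mid at the 25/50/75 % time quantiles,
y_max initialized at the series maximum; fixed order for reproducibility).
`max_slope = k·y_max/4` (pmol OD₇₅₀⁻¹ mL⁻¹ min⁻¹) and
`half_max_time = t_mid` hold exactly for every returned fit. A fit
classifies `sigmoidal` only if (i) fitted y(0)/y_max ≤ 0.05 (tolerance on
the zero-intensity constraint at t₀), (ii) the last observation reaches
75 % of the fitted plateau (threshold intensity ratio, interpreted as
plateau attainment), and (iii) the sigmoid beats a flat model by at least
10 AIC units (threshold −10). Series with nothing above a signal floor are
`no_signal`. A decaying (double-sigmoidal) branch is out of scope: no decay
occurs within the 90 min window modelled. Replicates are fitted
individually; a position/condition is reported only when at least half the
replicate fits classify sigmoidal (mean over those), else ND.

## Synthetic data generator

The generator defines the study conditions; its defaults are not tuning
knobs.

* **Labelling model**: each backbone position carries ¹³C independently at
  its own atom fraction (no isotopomer correlations — sufficient for every
  validation claim here since MIDs are position-symmetric), convolved with
  the natural pattern of the remaining atoms. Mixtures of certified
  standards are sums of population envelopes weighted by mole fraction —
  not averaged atom fractions, which would be a different (wrong) forward
  model.
* **Standards panel**: 36 mixtures reconstructed from the stated design
  (6 pure standards; each labelled standard at 5/10/50/90/95 mol-% in
  natural; the equal positional mix diluted to 100/50/20/10/4 %) × 4
  technical replicates at 25 ng injected. Certificate purities: 99.0 %
  ([U-¹³C]) and 99.6/99.7/99.6/99.3 % ([1-]..[4-¹³C]). The exact certified
  composition list is not publicly deposited; the reconstruction is flagged
  as such in the docstring.
* **Detector model**: response factors per fragment place m/z 232 near
  base-peak abundance (~1e7 counts at 25 ng splitless — hence acquired at
  split ratio 1:5, as is m/z 350) and minor fragments 1–2 orders lower;
  multiplicative noise CV 1 % per isotopologue (calibrated so the panel
  lands within the claimed accuracy/precision envelope, and held fixed);
  optional additive baseline; smooth saturation
  v/(1+(v/T)^m)^(1/m) with T = 1e7 counts and m = 6 (linear to <0.3 % at
  T/2, asymptoting to T). Measurements whose summed abundance exceeds the
  threshold are excluded from positional analysis and logged.
* **Time courses**: logistic tracer-excess trajectories on top of natural
  abundance (p = a + e·(1−a), so the corrected enrichment recovers the
  trajectory exactly). Light: all four positions with y_max = 0.35,
  k = 0.3 min⁻¹, t_mid = 25 min (first signal ≥1 % of plateau at the
  10 min sample; equal kinetics across positions, reflecting balanced
  carboxylation in the light). Dark: 4-C only, y_max = 0.2,
  k = 0.15 min⁻¹, t_mid = 45 min (onset at 15 min, lower and later than
  light). Constant aspartate pool 200 pmol OD₇₅₀⁻¹ mL⁻¹, OD 1.0, 10 mL,
  7 timepoints (0–90 min), 4 replicates; the EI-style quantifier and
  internal-standard responses are generated consistently with a noise-free
  calibration series so quantification inverts exactly.
* **mzML fixtures**: centroided Gaussian peaks (σ = 2.5 scans; the apex
  ±10 scan window spans 4σ, keeping round-trip loss below 0.01 %),
  uncompressed 64-bit arrays. True instrument noise magnitudes are not
  published; the CV default is a documented calibration choice.

What the generator does **not** emulate: isotopomer correlations, co-eluting
matrix compounds and isobaric contaminations, retention drift, baseline
structure, EI fragmentation spectra (the EI path ingests pre-integrated
tables), or detector physics beyond smooth clipping. Passing tests
demonstrate the correctness of the correction/algebra/fitting chain under
these idealized conditions, not robustness to real-matrix interferences —
the workflow's flags (saturation, poor fit, out-of-range, cross-check) are
the tools for judging real data.

## Numerical choices and degenerate inputs

All randomness flows from one seeded `numpy` generator per run; identical
config and seed give byte-identical CSV outputs. NNLS handles rank-adequate
matrices (every registry fragment yields a well-conditioned matrix);
all-zero MIDs, empty sample sets, missing t=0 samples, non-positive
calibration slopes, and sub-minimal coverage raise explicit errors rather
than propagating NaNs. Problem sizes in the shipped tests and examples
(36×4 panel, 4-replicate time courses, 100-replicate fit ensembles) were
chosen as the smallest that exercise the claimed statistics.

## Known limitations

* Positional results inherit the synthetic stand-in formulas for the
  {1,2}, {2,3}, {3,4} fragments until certified values are supplied.
* [M+H]⁺/[M]⁺ overlap is flagged, not corrected.
* Only ¹³C tracers are supported (no ²H/¹⁵N/¹⁸O tracer correction).
* Error propagation assumes independent fragment errors.
* The calibration model is a straight line; weighting is not implemented.
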