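# Methods

This note documents the models and numerical choices behind `mampep`: what
the pipeline computes, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## Digestion model

Trypsin specificity is cleavage C-terminal to K or R, suppressed before
proline; chain termini count as canonical termini. Peptides with `m` missed
cleavages are exactly the unions of `m+1` consecutive fully-cleaved
fragments; the default workbook cap is one missed cleavage. Coordinates are
1-based inclusive so residue labels used for antibody attributes (M255,
N300, K450) read naturally. Semi-specific peptides (exactly one canonical
terminus) are enumerated only to classify observations for the
non-specific-cleavage rate; fully non-specific species (neither terminus
canonical) are not enumerated — the reported rate is therefore a
semi-tryptic rate, the dominant class in practice. A length filter (default
≥2 residues for workbook building) drops free single residues, which are
unobservable in this LC setup.

## Masses and isotope envelopes

Residue elemental compositions, isotope masses/abundances, modification
deltas and glycan compositions live in versioned CSVs under `mampep/data`.
Peptide mass = Σ residue masses + H₂O; the proton mass is 1.007276 Da;
isotopologue spacing uses the ¹³C–¹²C difference (1.00335 Da), adequate for
CHNOS peptides. Envelopes are computed by per-element convolution with
binary exponentiation, truncated with guard bins so absolute abundances of
the first *n* isotopologues are exact; the monoisotopic share has the closed
form Π aᵢ₀^nᵢ, used for envelope correction (below).

Chemical modification deltas are elemental, so modified envelopes are
consistent: deamidation (−H −N +O, +0.98402 Da), succinimide from Asn
(−NH₃) or Asp (−H₂O), oxidation (+O), Trp oxolactone (+O −H₂), pyroglutamate
(−NH₃, peptide N-terminus only), C-terminal Lys clipping (−C₆H₁₂N₂O, chain
C-terminus only), and Asp isomerisation (Δm = 0, distinguishable only by
retention time). The glycan table covers the Fc glycoforms M5, A1G0F,
A2G0F, A1G1F, A2G1F, A2G2F and A2Ga1G1F; the last is the α-Gal positional
isomer of A2G2F with identical composition, separated chromatographically.
Ambiguous deamidation sites (e.g. two nearby asparagines on one tryptic
peptide) are modelled as a peptide-level site set and never split between
residues: MS1-only data cannot localise them.

## Synthetic data generator

The generator emulates a targeted MS1-only acquisition of a tryptic mAb
digest. What it models:

- **Ground truth**: per-site modified fractions, per-site glycoform
  profiles summing to 1, per-peptide loadings (arbitrary units, default 1),
  missed-cleavage forms at a configurable fraction of their parents' mean
  loading (default 0.15), optional semi-tryptic background. Presets
  reproduce published reference panels. Because a reported pairwise value is
  mod/(mod+unmodified), sites carrying several modified forms back-transform
  the printed values p through odds (r = p/(1−p), f = r/(1+Σr)) so every
  printed ratio is reproduced exactly by construction.
- **Signal**: for each workbook component, per listed charge and
  isotopologue (≥3), a Gaussian elution peak at the predicted RT sampled on
  the scan grid (default 1 s), amplitude = base intensity × loading ×
  fraction × charge weight × isotopologue abundance. Charge weights are
  normalised over the component's listed charges so each form carries total
  weight 1; charge lists come from a length rule (<15 residues → 1–2+, else
  2–3+) filtered to the 200–2000 m/z acquisition range.
- **Retention**: an additive per-residue hydrophobicity score mapped
  affinely onto [5, 100] min of the 105-min gradient, plus fixed
  modification offsets (deamidation +0.5 min, oxidation −1.0 min, isobaric
  species +0.8 min from their partner). Per-laboratory drift is a single
  affine shift (lab *i* shifts by *i*·drift or a per-lab list), matching the
  near-constant offsets seen between real installations (up to ~2 min).
- **Noise**: multiplicative log-normal noise of configurable CV per sampled
  point, mean 1 — the simplest heteroscedastic model consistent with
  area-RSD behaviour at the few-percent level. Replicates are independent
  digests only through this noise.
- **Determinism**: the RNG derives from (seed, lab, replicate); identical
  inputs give byte-identical peak lists and mzML files.

Elution sigma defaults to 0.15 min (FWHM ≈ 21 s, realistic for a 250-mm
column on a shallow 105-min gradient). This value is load-bearing: the
isobaric glycan pair differs ~7.6-fold in abundance at a 0.8-min offset, and
a resolvable pair requires the minor isomer to form its own local maximum —
at 0.25-min sigma it degenerates into a shoulder that no detector could
integrate separately, while at 0.15 min it is cleanly resolved.

Not modelled: profile-mode spectra, MS/MS, ion mobility, chimeric or
in-source artefacts (in-source oxidation is treated like any other
fraction), ionisation-efficiency differences between modified and
unmodified forms, retention non-linearity or warping, and column carryover.
Passing recovery tests therefore demonstrates correctness of the
computation, not robustness to every real-data pathology.

## Quantitation

XICs sum centroid intensities within ±5 ppm (on m/z) of the target per
scan; scans without a match contribute zero. The quantifier targets the
monoisotopic isotopologue per charge by default; a flag extracts and sums
the first *k* isotopologues instead. Each area is divided by the theoretical
abundance share of the targeted isotopologues ("envelope correction",
default on), so a form's reported area estimates its total envelope signal
regardless of elemental composition — without this, glycoforms differing by
hexoses would be biased by ~7% per Hex relative to each other in
monoisotopic-only mode.

Peak detection inside the RT window (default ±1.5 min after shift
correction; ±0.4 min for isobaric RT-resolved forms so the partner's peak
cannot be picked) is a documented stand-in for the vendor's unpublished
detector: 3-point moving-mean smoothing; baseline = median of the lowest
decile of the windowed trace; noise = MAD; candidate apexes are local maxima
above baseline + k·noise (k = 3); the candidate closest to the expected RT
wins (ties → taller). Bounds extend from the apex to the first baseline
crossing or to the valley preceding a persistent rise (> max(k·noise, 5% of
peak height) above the running minimum) — tolerating small upticks keeps
noisy single peaks integrated in full, while a genuine neighbouring peak
still terminates the bound at the valley. Areas are trapezoidal integrals
of the raw trace in intensity·seconds (RT is stored in minutes; the
integrator converts explicitly). A missing peak is a value (`found=False`,
area 0), never an exception, and never silently dropped.

Per-run RT drift is estimated as the median of (observed − expected) apex
times over landmark components (unmodified workbook peptides) searched with
a ±3-min window; at least three found landmarks are required, otherwise the
run is processed unshifted with a logged warning advising a manual workbook
RT update.

## Rollup and QC metrics

Pairwise attributes: 100·Σmod/(Σmod+Σunmod) over all charges and listed
peptide forms including missed-cleavage partners — adding a partner whose
forms sit at the same mod:unmod ratio provably leaves the value unchanged.
Glycoform profiles: member area over site total (members combine the
tryptic peptide and its missed-cleavage partner), summing to 100 ± 0.01.
Zero denominators propagate as flagged undefined values excluded from
statistics; silent zeros would bias precision estimates. Coverage maps mark
a residue covered iff a found peptide spans it; the recovery class bins the
residue's summed spanning area relative to the chain's most-covered residue
at thresholds >50, >20, >10, >5, >2, >1, ≤1% (the normalising reference is
a package choice; "recovery" has no standard numeric definition).
Missed-cleavage and non-specific rates are area-based fractions. Venn
membership matches peptides across 2–4 laboratories by (sequence,
modification) identity with observed masses within 5 ppm of the cross-lab
median, ignoring charge state.

## Precision statistics

RSD uses the sample (n−1) standard deviation — conventional for n = 3–4
analytical replicates. One-way ANOVA (laboratory factor) yields within/
between mean squares, F and p (descriptive only; no multiplicity
correction), the repeatability variance, and a between-lab component
max(0, (MS_b − MS_w)/n₀) with the standard unbalanced n₀. Inter-laboratory
RSD is reported in two labelled forms: pooled (√(σ²_w+σ²_b)/grand mean) and
means-based (RSD of the per-lab means); multi-site summaries are usually
quoted in the means-based form. Note the zero-floor engages whenever
MS_b ≤ MS_w, i.e. with probability ≈ P(F ≤ 1) under a null lab effect
(~0.57 for 4 labs × 3 replicates) — the floor guarantees non-negativity,
not a near-certain zero. Cells with fewer than two usable replicates are
excluded and listed. Degradation trends report per-cell mean, RSD, delta
versus the first time point, and a monotone-increase flag on cell means.

## Problem sizes and defaults used in checks

The bundled synthetic chain pair (heavy 173 aa, light 109 aa) is a
concatenation of the reference tryptic target peptides with realistic
filler, chosen so the ≤1-missed-cleavage workbook (79 components) covers
both chains completely. Recovery checks run 1–3 replicates per lab at noise
CV 0.02 on a 1-s scan grid over the full 105-min gradient (~6300 scans per
run); these sizes make the whole simulated-study suite run in seconds while
leaving every structural feature (envelopes, drift, partners, isobars)
exercised. Integration agrees with the analytic Gaussian area to <1%
per peak; noiseless end-to-end attribute recovery is exact to <0.2%
relative except the minor glycan isomer (~1.7% low from tail overlap with
its 7.6× larger isobar — flagged as a known limitation of valley-bounded
integration, not corrected by deconvolution, which is out of scope).

## Known limitations

- The peak detector is a documented reimplementation, not the vendor
  algorithm; absolute areas are not comparable to vendor output, only
  ratios are meaningful.
- Envelope correction assumes the targeted isotopologue is interference-
  free; co-eluting isobars within 5 ppm would be summed, not deconvolved.
- The semi-tryptic enumeration bounds peptide length (default 50) for
  tractability.
- The RT model is intentionally simple (additive, affine); it orders
  peptides plausibly but does not predict real retention times.
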