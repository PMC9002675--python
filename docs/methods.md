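# Methods

## The analysis

`whalehht` extracts energy characteristics of long tonal whale vocalizations —
blue whale B calls are the motivating case — from mono hydrophone recordings.
A B call is a frequency-modulated tonal with a fundamental near 10–16 Hz and a
harmonic stack; the analysis concentrates on the fundamental and one dominant
harmonic component near 40–50 Hz.  The chain has six stages, applied to short
fixed-duration analysis windows:

1. **Empirical mode decomposition (EMD).**  Each window x(t) is decomposed by
   sifting into intrinsic mode functions plus a residue,
   `x(t) = Σ_i IMF_i(t) + rf(t)`, ordered fastest to slowest.  Reconstruction
   is exact by construction.
2. **Energy analysis.**  Total energy is the *sum of component energies*
   `E_total = Σ_i Σ_t IMF_i(t)² + Σ_t rf(t)²` (cross terms deliberately
   ignored), so the per-component ratios `ENG_i = E_i / E_total × 100`
   always total exactly 100 %.
3. **Marginal frequency spectra (MF).**  The Hilbert transform gives each
   component's analytic amplitude a(t) and instantaneous frequency
   IF(t) = θ'(t)/2π; each sample deposits a(t)² into the 1 Hz bin nearest its
   IF.  The binned vector is rescaled to total the component's energy ratio,
   so spectra, ratios and thresholds share one percent scale.
4. **EDI feature extraction.**  For a threshold Δ (percent), bins with
   `R_i[x] ≥ Δ` are retained; the energy density intensity is their cumulative
   sum, `EDI_i = Σ R_i[x]`.  The *main frequency band* is the contiguous run
   of retained bins containing the global maximum; the full suprathreshold
   mask is kept alongside.  EDI is non-increasing in Δ and equals the energy
   ratio at Δ = 0.
5. **Classification.**  A window is Class I when its first IMF dominates
   (ENG_IMF1 strictly above 70 % by default) and MF1's argmax lies in the
   harmonic band (41–45 Hz inclusive by default); Class II when ENG_IMF2
   exceeds 30 % and MF2's argmax lies in 10–14 Hz.  Both bands and thresholds
   are configuration, because harmonic bands shift between recording sites.
   A window satisfying both is labelled Class I and flagged ambiguous (with
   the default thresholds this cannot happen, since ratios total 100 %).
6. **Hilbert spectra (HS).**  The analytic tracks of the *whole* window are
   sliced into six equal time bins (30 ms for a 180 ms window) and the MF
   binning applied per slice, giving a time–frequency–energy grid whose sum
   over time reproduces the MF exactly.  Sub-windows are *not* re-decomposed:
   a 12 Hz component has an 83 ms period, so 30 ms pieces cannot be
   independently sifted.

## Numerical choices

- **Sifting stop rule.**  Cauchy-type criterion
  `Σ(h_prev − h)² / Σ h_prev² < stop_sd` with `stop_sd = 0.2` and at most 100
  sifts per mode, at most 10 modes.  These are the conventional defaults; the
  IMF count of a given window depends on them, which is why the pipeline
  filters windows to a common decomposition depth before averaging.
- **Envelopes.**  Cubic splines through the extrema (plateaus count once, at
  their midpoint).  The two extrema nearest each end are mirrored across the
  end sample; additionally, an end sample that pokes beyond its nearest
  extremum is adopted as a knot first.  Without that clamp the envelope mean
  is badly wrong near the boundaries and sifting injects a spurious edge mode
  that can carry >10 % of window energy.
- **Instantaneous frequency.**  Central differences of the unwrapped analytic
  phase (one-sided at the ends).  Samples with IF outside [0, Nyquist] — a
  known Hilbert edge artifact — are excluded from binning, their fraction
  recorded, and the rescaling step restores mass conservation.
- **Binning.**  The bin at x Hz covers [x − res/2, x + res/2); assignment by
  rounding.  Argmax ties resolve to the lowest frequency; grid-extreme ties
  to the earlier time bin, then lower frequency.
- **Degenerate inputs.**  A constant (or extrema-poor) window is its own
  residue with zero IMFs; an all-zero component yields a flagged degenerate
  track and a zero spectrum; an all-zero decomposition has undefined ratios
  and raises.

## Synthetic data

`make_tones` sums sinusoids (optionally linearly swept and time-gated) with
seeded additive white Gaussian noise; `make_bcall` builds a B-call surrogate:
a fundamental (default 12 Hz) and a harmonic component (default 45 Hz) each
swept downward by 3 % of its centre frequency across the call, with a 4:1
harmonic:fundamental energy ratio and 20 dB broadband SNR by default, at the
7350 Hz rate and 180 ms windowing of the protocol.  Ground-truth component
tracks are returned so recovery can be scored by matching each track to its
best-correlated IMF (`match_ground_truth`).

What the generator does *not* emulate: ocean-coloured noise (white noise is
the conservative default in the absence of a stated noise model),
propagation/multipath, amplitude modulation within a call, or inter-call
variability.  Passing tests on this corpus therefore demonstrate the
correctness of the machinery and its behaviour on idealised tonal structure,
not detection performance on real PAM data.

Two measurement conventions are worth stating.  First, with broadband noise
the first extracted modes are low-energy noise, so "IMF1/IMF2" in the
classification sense are recovered either by ground-truth matching (synthetic
oracles) or by taking the two dominant-energy modes in extraction order
(`dominant_profile`).  Second, parameter-recovery statistics use 1 s analysis
windows at 1000 Hz so that both tones complete many cycles per window: a
12 Hz fundamental completes only ~2.2 cycles in a 180 ms window, and its
per-window argmax then scatters by a few Hz no matter how clean the
decomposition — the same physics that drives the heavy window attrition seen
in real B-call analyses.  The 180 ms protocol is kept for the
classification-oriented pipeline, where class-level averaging absorbs that
scatter.

## Problem sizes

The shipped checks run at desk scale by design: 100 random multi-tone
segments (0.375 s at 2000 Hz) for the conservation laws, 1000 random spectra
for EDI monotonicity, 30 one-second windows for two-tone recovery, and a
15-item constructed batch for classification.  The whole suite and the
acceptance script each complete in well under a minute on one CPU.

## Known limitations

- Plain EMD is used; noise-assisted variants (EEMD/CEEMDAN) that mitigate
  mode mixing are out of scope.  Occasional mixed modes on noisy input are
  expected and are the reason the recovery oracle matches components rather
  than trusting extraction order blindly.
- The IMF count of a window is sensitive to the stop rule; replicating any
  particular published kept-window count on an external recording is not
  guaranteed and not attempted.
- No automatic call detection: the valid-signal interval is caller-supplied.
- No resampling; frequency bins derive from the file's native rate.
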