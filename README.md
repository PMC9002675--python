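# whalehht

Energy-characteristic extraction for long tonal whale vocalizations, built on
empirical mode decomposition (EMD) and Hilbert spectral analysis.  The target
signal class is the blue whale B call — a frequency-modulated tonal with a
fundamental near 10–16 Hz plus a harmonic stack, recorded by passive acoustic
monitoring (PAM) hydrophones — but every stage is generic over tonal,
harmonic-stacked calls.

## What it computes

A mono WAV recording is windowed into fixed-duration analysis segments
(180 ms by default).  Each window x(t) is sifted into intrinsic mode
functions and a residue,

    x(t) = Σᵢ IMFᵢ(t) + rf(t),

and the chain then computes, per window and averaged per class:

- **Energy ratios** `ENG_IMFᵢ = Σₜ IMFᵢ(t)² / E_total × 100 %`, where
  `E_total` is the sum of all component energies (ratios always total 100 %).
- **Marginal frequency spectra (MF)**: squared analytic amplitude a(t)²
  binned at 1 Hz by instantaneous frequency `IF(t) = θ'(t)/2π`, scaled to
  percent of window energy.
- **Energy density intensity (EDI)**: for a threshold Δ, the cumulative mass
  of bins with `R[x] ≥ Δ`, with the main frequency band (the contiguous
  suprathreshold run containing the peak) and the maximum frequency.
- **Two-class labels**: Class I when IMF1 dominates (>70 %) with MF1 peaking
  in the harmonic band (41–45 Hz default); Class II when IMF2 is strong
  (>30 %) with MF2 peaking in the fundamental band (10–14 Hz default).
- **Hilbert spectra (HS)**: the same binning applied within six equal time
  bins per window, a time–frequency–energy grid whose time-sum reproduces
  the MF exactly.

A seeded synthetic-call generator (`make_bcall`, `make_tones`) emulates the
fundamental-plus-harmonic structure with additive white noise so the whole
chain is testable without any recordings.

## Worked example

Decompose one 1 s window of a synthetic two-tone call (45 Hz at amplitude
1.0, 12 Hz at amplitude 0.5, 20 dB SNR — an 80/20 energy split):

```python
import numpy as np
import whalehht as w
from whalehht.edi import edi_sweep

rec = w.make_tones(
    [w.ToneSpec(45.0, 1.0), w.ToneSpec(12.0, 0.5)],
    w.NoiseSpec(sd=0.079, seed=7),
    duration=30.0, rate=1000.0,
)
seg = w.window_segments(rec, duration=1.0)[0]
d = w.sift(seg)
prof = w.energy_profile(d)
print("IMF count:", d.n_imfs)
print("energy ratios (%):", np.round(prof.ratios, 2), "residue:", round(prof.rf_ratio, 2))
for i in w.dominant_components(d, 2):
    track = w.analytic_track(d.imfs[i], seg.rate)
    mf = w.marginal_spectrum(d.imfs[i], track, prof.e_total, imf_index=i)
    print(f"IMF{i+1}: argmax {mf.argmax_freq:g} Hz, mass {mf.energy_ratio:.2f}%")
    for f in edi_sweep(mf, [1.0, 3.0, 5.0]):
        band = f"{f.main_band[0]:g}-{f.main_band[1]:g} Hz" if f.main_band else "-"
        print(f"  Delta={f.threshold:g}%: EDI {f.edi:.2f}%, band {band}")
```

prints

```
IMF count: 4
energy ratios (%): [ 0.74 79.35 19.37  0.31] residue: 0.22
IMF2: argmax 44 Hz, mass 79.35%
  Delta=1%: EDI 76.87%, band 38-52 Hz
  Delta=3%: EDI 68.05%, band 41-50 Hz
  Delta=5%: EDI 57.28%, band 42-48 Hz
IMF3: argmax 12 Hz, mass 19.37%
  Delta=1%: EDI 18.25%, band 11-13 Hz
  Delta=3%: EDI 16.46%, band 11-12 Hz
  Delta=5%: EDI 13.42%, band 12-12 Hz
```

The first extracted mode (IMF1, 0.74 %) is broadband noise; the two dominant
modes carry the 45 Hz harmonic (79.35 % ≈ 80 %) and the 12 Hz fundamental
(19.37 % ≈ 20 %), and raising the EDI threshold narrows each main band onto
its tone.  As the threshold rises from 1 % to 5 % the harmonic's band
tightens from 38–52 Hz toward 42–48 Hz — the concentration behaviour the EDI
feature is designed to expose.

## Command line

```
whalehht synth call.wav --seed 1          # synthetic B-call WAV + truth sidecar
whalehht run call.wav outdir/             # full pipeline -> CSV/JSON bundle
whalehht decompose call.wav imfs.csv      # one window's IMFs
whalehht features call.wav profiles.csv   # per-window energy ratios
whalehht spectrum call.wav mf.csv --imf 1 # averaged MF + EDI sweep
whalehht classify call.wav labels.csv     # Class I / II / unclassified
```

`whalehht run` writes per-segment energy profiles, classification results,
per-class averaged marginal spectra, EDI threshold sweeps, Hilbert-spectrum
grids restricted to each component's main band, and a `manifest.json`
sufficient to reproduce the run byte-identically.

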