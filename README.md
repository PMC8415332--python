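# dropsfx

Analysis pipeline for **drop-on-demand serial femtosecond crystallography
(SFX)**, exercised end to end on synthetic diffraction data with known
ground truth.

In drop-on-demand SFX an acoustic dispenser ejects ~80 µm droplets of
crystal slurry into the X-ray focus of a free-electron laser running at
10 Hz. Each detector frame is one probed drop: it may be blank (the drop
missed), carry one crystal, or — at dense slurries — several crystals at
once. The questions a beamtime team asks of such data are the ones this
package answers:

* **Which frames are hits?** Bragg-peak finding on masked frames: a peak is
  a connected component of ≥2 pixels above 100 ADU with signal-to-noise
  ratio ≥ 7; a frame with ≥15 peaks is a crystal hit.
* **How well does indexing work, and is there cross-contamination?**
  Hit rates, crystal-level indexing rates (indexed crystals of the correct
  unit cell per hit, tolerances 5% / 1.5°), time-binned rate series across
  wash gaps, and a misindexing audit that scores every event against every
  sample's cell.
* **Does dispensing damage the crystals?** Radially averaged Bragg-peak
  intensity profiles: per-image shell averages, closed-form L2 scaling to
  the first hit's reference (s\* = Σpᵢrᵢ/Σpᵢ²), run averaging, and
  normalization to mean 1 — two undamaged runs agree up to ~2 Å.
* **How much sample does it cost?** Drop-volume arithmetic
  (V = π/6·d³; 250 pl at 60 Hz → 0.9 µl min⁻¹) and a Poisson occupancy
  model P(hit) = 1 − e^(−cV) linking slurry concentration to hit rate.

Because no public data exist for this kind of experiment, the package
includes a first-class simulator: Poisson crystal counts per drop, uniform
random orientations, Ewald-sphere reflection prediction (excitation error
‖|q + k₀| − |k₀|‖ ≤ tol), Debye–Waller-like intensity falloff
e^(−B/2d²), Cu powder rings at 2.09/1.81 Å, Poisson photon noise, missed
drops, and end-of-run buffer depletion — all deterministic per seed, with
per-event ground truth.

## Worked example

```bash
python examples/01_simulate_and_find_peaks.py
```

```
frames simulated : 50
crystals dispensed: 108
hits (>=15 peaks) : 40  (hit rate 80.0%)
mean peaks / frame with peaks: 211.0
```

Fifty 10 Hz frames of a dense (400 crystals nl⁻¹) slurry; with a Poisson
occupancy mean of ~2.1 crystals per probed volume, 1 − e^(−2.1) ≈ 88% of
drops carry a crystal, and the realized 80% hit rate tracks that. The
damage check (`examples/03_radial_damage_check.py`) prints

```
hits per run: 103, 109, 112
profile means (normalized): 1.000000000000
max relative shell difference, identical sample : 0.049
max relative shell difference, degraded crystals: 0.747
```

— identical-sample runs differ only by sampling noise, while a 50% larger
B factor depresses the high-resolution shells far beyond it. The other
examples cover the published-table rate arithmetic (`02`), consumption and
occupancy (`04`), and the cross-contamination audit (`05`). A thin CLI
(`dropsfx simulate|findpeaks|rates|radial|audit|budget|report`) wraps the
same library calls.

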