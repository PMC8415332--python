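# Methods

## The experiment being emulated

A drop-on-demand dispenser ejects spherical droplets (~80 µm, ~268 pl) of
protein crystal slurry at 60 Hz into the focus of a 10 Hz FEL beam at
9.28 keV, so every sixth drop is probed; only probed drops are simulated
as events. Dense slurries (thaumatin, xylanase, ~400 crystals nl⁻¹)
produce frequent multi-crystal patterns; dilute ones (proteinase K,
alcohol dehydrogenase, 40–50 nl⁻¹) produce low hit rates. The analysis
chain — peak finding, hit classification, indexing-rate bookkeeping,
radial quality profiles, consumption arithmetic — is the package's
subject; auto-indexing itself (orientation search) is delegated to
established programs in practice and is deliberately out of scope, with
simulator ground-truth orientations (or an external solutions table)
standing in where a solution is needed.

## Detector geometry

A single flat panel at normal incidence. λ = hc/E with hc = 12.398419
keV·Å; ρ = pitch·|pos − center|, 2θ = arctan(ρ/D), d = λ/(2 sin θ), and
inversely r = D·tan(2 arcsin(λ/2d))/pitch. The beam-center pixel maps to
an infinite-d sentinel that shell binning treats as out of range; d-values
at or below λ/2 (and 2θ ≥ 90°) are unreachable and raise.

The emulated beamline fixes only the photon energy (9.28 keV) and frame
rate (10 Hz). Detector distance, pixel pitch, frame size and beam center
are **synthetic configuration**: the default 512×512 panel at 45 mm with
177 µm pixels reaches ~1.7 Å at the edge midpoint and places the Cu
powder rings (2.09, 1.81 Å) inside the frame; a 256×256 panel at 20 mm
(`demo_config`) is used where speed matters more than peak-density
realism.

## Simulator

* **Occupancy.** Crystals per probed event ~ Poisson(λ) with
  λ = concentration × probed volume, probed volume = interaction_fraction
  × drop volume. The beam focus is much smaller than an 80 µm drop, so
  only a fraction of the drop is probed; the default
  interaction_fraction = 0.02 gives λ ≈ 2.1 at 400 nl⁻¹ (hit probability
  ≈ 0.88, multi-crystal patterns common) and λ ≈ 0.24 at 45 nl⁻¹ —
  matching the qualitative regimes of dense and dilute slurries. It is a
  free parameter with no measured counterpart.
* **Diffraction.** Reflections are reciprocal-lattice points q = R·B·h
  with |q| ≤ 1/d_min whose excitation error ||q+k₀| − |k₀|| is at most
  `excitation_tol` (default 2×10⁻⁴ Å⁻¹). Partiality, mosaicity and
  bandwidth are collapsed into this single tolerance; the default yields
  ~160 reflections per thaumatin-like crystal to 2 Å, in line with the
  tens-to-hundreds of peaks per hit a real run shows. The per-cell lattice
  ball is enumerated once and cached; orientations are uniform via
  normalized Gaussian quaternions.
* **Intensities.** Integrated photon count I₀·e^(−B/2d²) (defaults
  I₀ = 400 photons, B = 15 Å²), stamped as an isotropic 2-D Gaussian
  (σ = 1 px); frames add a flat background (1 photon/px), Gaussian
  annular powder rings at 2.09/1.81 Å, Poisson photon noise, and a gain
  of 10 ADU/photon. With these values found-peak intensities average
  1–3 kADU and high-resolution peaks fade below the detection threshold,
  giving realistic per-run averages. In the noise-free mode pixel values
  are rounded to integers rather than Poisson-sampled.
* **Run structure.** ⌊duration × 10 Hz⌋ events; misses (blank frames) with
  `miss_probability`, optionally ramped linearly across the run to mimic
  nozzle drift; on a miss the trailing fluid tail may still be hit
  (`tail_hit_probability`, treated as a normal event); after
  `depletion_time_s` the stream switches to buffer-only frames, as when
  the aspirated slurry runs out. Everything is drawn from one seeded
  generator, so a seed reproduces a run bit for bit.

What the simulator does **not** model: detector point-spread and
saturation, polarization/solid-angle corrections, jet/tail scatter
streaks, crystal size distributions (a single intensity scale), real
mosaicity or bandwidth profiles, and fluid dynamics. Passing tests
therefore show that the *analysis* is correct on data with this
statistical structure, not that the generator reproduces any particular
detector's systematics.

## Peak finding and hits

Connected components (8-connectivity by default — the minimum pixel count
of 2 makes diagonal-touching pairs matter) of unmasked pixels ≥ 100 ADU;
components with ≥ 2 px are candidates. The local background is the median
and 1.4826×MAD of an annulus (inner 3, outer 6 px) around the component;
candidates keep intensity = Σ(pixel − median) and pass if
intensity/(σ·√n) ≥ 7. The SNR estimator is a documented stand-in: the
production peak finder being emulated publishes only the threshold, not
the estimator. Centroids are intensity-weighted; output order (descending
intensity, ties by (slow, fast)) is fixed so outputs are byte-stable. A
frame with ≥ 15 peaks is a hit. The four thresholds (100, 2, 7, 15) are
the standard criteria for these data and are the package defaults.

## Indexing validation and the contamination audit

Cells are equivalent within 5% on lengths (relative) and 1.5° on angles
(absolute). Spot integration uses disc/annulus radii 3/4/5 px. Prediction
matching is greedy one-to-one nearest-neighbour within 3 px, predictions
visited low-resolution-first for determinism; an indexing solution is
*supported* when ≥ 50% of its predictions land on observed peaks
(`support_fraction` — our operationalization of "the predicted spots do
not contain actual Bragg peaks"; both it and the 3 px position tolerance
are free parameters). The audit scores every event against every sample
cell — ground-truth orientation for the own cell, random orientation for
foreign cells — and counts events supported only by a foreign cell; zero
such events is the no-cross-contamination outcome.

## Rates

Hit rate = 100·hits/patterns. Crystal-level indexing rate =
100·(indexed crystals of the correct cell)/hits; multi-crystal patterns
count each crystal, so the rate can exceed 100. Event-level (time-binned)
indexing rate counts multi-crystal hits once. Rates over an empty
denominator are flagged, not silently zero: summary tables print 0 for
zero-hit runs while keeping a machine-readable validity flag. Display
rounding is one decimal, half away from zero (271/1083 → 25.0); full
precision is kept internally. Binned series lay uniform bins over the
concatenated wall-clock timeline anchored at the first event, so
wash/reload gaps appear as flagged empty bins; total pattern counts are
treated as data, never derived from run duration × frame rate.

## Radial profiles

Shells are uniform in q = 1/d by default (equal reciprocal-space
thickness, the crystallographic norm; uniform-in-d is selectable), 30
shells over d ∈ (2, 20] Å. Per-image profile: mean found-peak intensity
per shell, half-open bins, empty shells unoccupied. Each hit's profile is
scaled to the run's first hit by the closed-form L2 minimizer
s\* = Σpᵢrᵢ/Σpᵢ² over co-occupied shells (a shell-wise median reference is
offered for sparse first hits, with a warning below 1/3 shell coverage);
the run profile is the shell-wise mean of scaled profiles, divided by its
mean over occupied shells so that mean is exactly 1 (occupied shells only
— unoccupied shells have no value to include). Run comparison reports
|a−b|/((a+b)/2) per co-occupied shell with center d ≥ 2 Å and its
maximum.

The dispensing-damage surrogate (no beamline data exist to re-analyze):
two 60 s runs of identical sample on the 512² geometry (~515 hits each)
give a maximum relative shell difference of ~0.02–0.05, while raising B by
50% gives ~0.7. The less-crowded 512² panel matters here: on the 256²
demo panel peak overlap between crystals merges components often enough
to push identical-sample noise above 0.1.

## Consumption and occupancy

V = π/6·d³ (80 µm → 268.08 pl; 78.16 µm → 250 pl); volumetric rate
V·f·60/10⁶ µl min⁻¹ (250 pl at 60 Hz → 0.9). P(hit) = 1 − e^(−cV);
P(≥2|≥1) = (1 − e^(−λ) − λe^(−λ))/(1 − e^(−λ)). The concentration
estimator inverts the hit model, c = −ln(1 − rate/100)/V, optionally
dividing out a known miss probability first; it is undefined at 0 and
100% rates. Across 50 seeded runs of 1000 events at λ = 1 the median
estimate falls within two standard errors of the truth (delta-method
standard error, median efficiency factor 1.2533).

## Numerical and design choices

* Rounding half away from zero for displayed rates; banker's rounding
  would turn 92.05 into 92.0 vs 92.1 inconsistently with printed tables.
* Unit-cell algebra (orthogonalization, volume) comes from gemmi; the
  Ewald enumeration, excitation test and projection are implemented here
  and checked against a scalar brute-force oracle in the tests.
* Connected components come from scipy.ndimage; HDF5 via h5py
  (`/entry_1/data_1/data`, `/entry_1/event_id`, `/entry_1/timestamp_s`,
  masks at `/entry_1/mask`); CSVs carry a `# dropsfx-csv <major.minor>
  <kind>` header and readers reject unknown major versions.
* All simulation sizes in tests are desk-scale by choice: 256²/512²
  panels, runs of 25–600 events, so the full suite exercises every
  contract in minutes on one core.
* Degenerate inputs fail loudly: zero-event rates, unscalable profiles,
  fully-masked annuli, unreachable d-spacings and overlapping run
  intervals each raise a dedicated error rather than returning NaN.

## Known limitations

Indexing is validated, not performed; multi-lattice disentanglement,
detector-geometry refinement and structure solution/merging are out of
scope. The interaction fraction is unidentifiable from hit rates alone
(only the product cV enters); concentration estimates inherit that
degeneracy. Unit cells for the four named samples are literature-typical
synthetic defaults, not measured values.
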