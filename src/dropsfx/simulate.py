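"""Synthetic drop-on-demand SFX data with known ground truth.

Emulates the statistical structure of a 10 Hz FEL run fed by an acoustic
drop dispenser: each probed drop carries a Poisson-distributed number of
crystals, each crystal diffracts according to a forward Ewald-sphere model,
and frames additionally carry powder rings from Cu shielding, a flat
background, and Poisson photon noise. Missed drops give blank frames, and
an optional depletion time switches the stream to buffer-only frames, as
happens when the aspirated slurry runs out near the end of a run.

The generator is deterministic for a fixed seed and records per-event
ground truth (crystal count, orientations, true peak positions) so that
peak finding, hit classification, indexing validation and rate statistics
can all be scored against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd

from .geometry import BeamlineGeometry


# ---------------------------------------------------------------------------
# unit cells and samples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell (a, b, c in Å; angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0°, 180°)")
        if not math.isfinite(self.volume) or self.volume <= 0:
            raise ValueError("degenerate unit cell (non-positive volume)")

    def _gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c,
                              self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        """Cell volume in Å³."""
        try:
            return float(self._gemmi().volume)
        except Exception:
            return float("nan")

    def reciprocal_basis(self) -> np.ndarray:
        """3×3 matrix whose columns are a*, b*, c* in Cartesian Å⁻¹.

        q = B·h gives the scattering vector (|q| = 1/d) of reflection h.
        """
        frac = np.array(self._gemmi().frac.mat.tolist(), dtype=float)
        return frac.T

    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class SampleModel:
    """A crystal slurry as loaded into the dispenser.

    ``concentration`` is the crystal number density in crystals nl⁻¹
    (≈400 nl⁻¹ for dense thaumatin/xylanase slurries, 40–50 nl⁻¹ for
    proteinase K / alcohol dehydrogenase). ``peak_scale_i0`` is the
    integrated photon count of a Bragg reflection at infinite d before the
    Debye–Waller-like falloff exp(−B/(2d²)); ``b_factor`` controls how fast
    reflections fade with resolution.
    """

    name: str
    cell: UnitCell
    concentration: float = 400.0     # crystals / nl
    peak_scale_i0: float = 400.0     # photons
    b_factor: float = 15.0           # Å²
    is_buffer_only: bool = False

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not self.is_buffer_only and self.peak_scale_i0 <= 0:
            raise ValueError("peak_scale_i0 must be > 0 for crystal samples")


@dataclass(frozen=True)
class DropModel:
    """Dispensed drop geometry and delivery statistics.

    An 80 µm drop at 60 Hz with the beam probing only a small interaction
    fraction of its volume. ``miss_probability`` is the chance a drop is
    mistimed/misaligned and the pulse probes nothing; on a miss,
    ``tail_hit_probability`` is the chance the pulse still intercepts the
    fluid tail trailing the drop (treated as a normal crystal-bearing
    event). The 1.5 m s⁻¹ drop speed is metadata only.
    """

    diameter_um: float = 80.0
    speed_m_s: float = 1.5
    dispense_rate_hz: float = 60.0
    miss_probability: float = 0.0
    tail_hit_probability: float = 0.0
    interaction_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be > 0")
        for p in (self.miss_probability, self.tail_hit_probability,
                  self.interaction_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities/fractions must lie in [0, 1]")

    @property
    def volume_pl(self) -> float:
        """Spherical drop volume in pl (π/6·d³)."""
        return math.pi / 6.0 * self.diameter_um ** 3 * 1e-3

    @property
    def probed_volume_nl(self) -> float:
        """Beam-probed sub-volume in nl: interaction_fraction × drop volume."""
        return self.volume_pl * 1e-3 * self.interaction_fraction


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to simulate one run deterministically."""

    geometry: BeamlineGeometry
    sample: SampleModel
    drop: DropModel = field(default_factory=DropModel)
    duration_s: float = 30.0
    seed: int = 0
    excitation_tol: float = 2e-4     # Å⁻¹, half-thickness of the Ewald shell
    d_min: float = 2.0               # Å, resolution cutoff of predictions
    ring_bands: tuple = ((2.09, 2.0, 6.0), (1.81, 2.0, 4.0))
    # each band: (d_center Å, radial sigma px, peak photons/pixel)
    background_level: float = 1.0    # photons / pixel
    noise_model: bool = True         # Poisson photon noise on/off
    gain: float = 10.0               # ADU / photon
    peak_sigma_px: float = 1.0       # isotropic Gaussian peak width
    depletion_time_s: float | None = None
    miss_probability_end: float | None = None  # optional linear drift ramp

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.excitation_tol < 0:
            raise ValueError("excitation_tol must be >= 0")
        if self.d_min <= self.geometry.wavelength / 2.0:
            raise ValueError("d_min must exceed λ/2")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# elementary draws
# ---------------------------------------------------------------------------

def draw_crystal_count(concentration: float, probed_volume_nl: float,
                       rng: np.random.Generator) -> int:
    """Poisson crystal occupancy with mean λ = concentration × probed volume."""
    if concentration < 0 or probed_volume_nl < 0:
        raise ValueError("concentration and probed volume must be >= 0")
    return int(rng.poisson(concentration * probed_volume_nl))


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via unit-quaternion sampling."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# reflection prediction (forward Ewald model)
# ---------------------------------------------------------------------------

@dataclass
class ReflectionSet:
    """Predicted in-frame reflections of one crystal orientation."""

    fast: np.ndarray    # fractional pixel
    slow: np.ndarray
    d: np.ndarray       # Å
    hkl: np.ndarray     # (n, 3) int

    def __len__(self) -> int:
        return self.fast.size

    def positions(self) -> np.ndarray:
        """(n, 2) array of (fast, slow) positions."""
        return np.column_stack([self.fast, self.slow])


# cache of (H, q0) lattice enumerations keyed by (cell, d_min): the set of
# reciprocal-lattice points inside the |q| <= 1/d_min ball is orientation-
# independent, so it is enumerated once per cell
_LATTICE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _lattice_ball(cell: UnitCell, d_min: float) -> tuple[np.ndarray, np.ndarray]:
    key = (cell, round(d_min, 12))
    hit = _LATTICE_CACHE.get(key)
    if hit is not None:
        return hit
    B = cell.reciprocal_basis()
    # index bounds: |h_i| <= length_i / d_min since B⁻¹ rows are the real
    # basis vectors
    hmax = [int(math.ceil(length / d_min)) for length in cell.lengths()]
    ranges = [np.arange(-m, m + 1) for m in hmax]
    H = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    H = H[np.any(H != 0, axis=1)]
    q0 = H @ B.T
    qn = np.linalg.norm(q0, axis=1)
    keep = (qn > 0) & (qn <= 1.0 / d_min)
    out = (H[keep], q0[keep])
    if len(_LATTICE_CACHE) > 32:
        _LATTICE_CACHE.clear()
    _LATTICE_CACHE[key] = out
    return out


def predict_reflections(cell: UnitCell, orientation: np.ndarray,
                        geom: BeamlineGeometry, excitation_tol: float,
                        d_min: float) -> ReflectionSet:
    """Reflections excited by a monochromatic beam for one crystal orientation.

    Enumerates reciprocal-lattice vectors q = R·B·h with |q| ≤ 1/d_min,
    keeps those whose excitation error ||q + k₀| − |k₀|| (distance from the
    Ewald sphere, |k₀| = 1/λ, beam along +z) is at most ``excitation_tol``,
    and projects the scattered ray k₀ + q onto the flat detector. Only
    positions landing inside the frame are returned.
    """
    if d_min <= geom.wavelength / 2.0:
        raise ValueError("d_min must exceed λ/2")
    R = np.asarray(orientation, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("orientation must be a 3x3 rotation matrix")

    H, q0 = _lattice_ball(cell, d_min)
    q = q0 @ R.T                         # (n, 3) scattering vectors
    qn = np.linalg.norm(q, axis=1)

    k0 = 1.0 / geom.wavelength
    kout = q + np.array([0.0, 0.0, k0])
    exc = np.abs(np.linalg.norm(kout, axis=1) - k0)
    keep = exc <= excitation_tol
    H, q, qn, kout = H[keep], q[keep], qn[keep], kout[keep]

    kz = kout[:, 2]
    keep = kz > 0                        # forward-scattered only
    H, q, qn, kout, kz = H[keep], q[keep], qn[keep], kout[keep], kz[keep]

    pitch_mm = geom.pixel_pitch_um * 1e-3
    fast = geom.beam_center[0] + kout[:, 0] / kz * geom.detector_distance_mm / pitch_mm
    slow = geom.beam_center[1] + kout[:, 1] / kz * geom.detector_distance_mm / pitch_mm
    n_slow, n_fast = geom.frame_shape
    inside = (fast >= 0) & (fast <= n_fast - 1) & (slow >= 0) & (slow <= n_slow - 1)
    return ReflectionSet(fast=fast[inside], slow=slow[inside],
                         d=1.0 / qn[inside], hkl=H[inside])


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------

class FrameRenderer:
    """Composes background + powder rings + Bragg peaks and applies noise.

    Caches the static (background + ring) photon map for a geometry so that
    per-event rendering only stamps the Gaussian peaks and draws noise.
    """

    def __init__(self, config: SimConfig):
        self.config = config
        geom = config.geometry
        r = geom.radius_map()
        static = np.full(geom.frame_shape, float(config.background_level))
        for d_center, sigma_px, amplitude in config.ring_bands:
            rc = geom.d_to_ring_radius(d_center)
            static += amplitude * np.exp(-0.5 * ((r - rc) / sigma_px) ** 2)
        self._static_photons = static

    def render(self, reflections: Sequence[ReflectionSet],
               rng: np.random.Generator) -> np.ndarray:
        """Render one frame (ADU, uint32) from per-crystal reflection lists."""
        cfg = self.config
        photons = self._static_photons.copy()
        sig = cfg.peak_sigma_px
        half = max(2, int(math.ceil(4 * sig)))
        n_slow, n_fast = cfg.geometry.frame_shape
        i0 = cfg.sample.peak_scale_i0
        b = cfg.sample.b_factor
        nonempty = [r for r in reflections if len(r)]
        if nonempty:
            fast = np.concatenate([r.fast for r in nonempty])
            slow = np.concatenate([r.slow for r in nonempty])
            d = np.concatenate([r.d for r in nonempty])
            counts = i0 * np.exp(-b / (2.0 * d * d))
            off = np.arange(-half, half + 1)
            ds, df = np.meshgrid(off, off, indexing="ij")
            ds, df = ds.ravel(), df.ravel()
            S = np.floor(slow).astype(int)[:, None] + ds[None, :]
            F = np.floor(fast).astype(int)[:, None] + df[None, :]
            g = np.exp(-((S - slow[:, None]) ** 2 + (F - fast[:, None]) ** 2)
                       / (2.0 * sig * sig))
            vals = counts[:, None] * g / (2.0 * math.pi * sig * sig)
            ok = (S >= 0) & (S < n_slow) & (F >= 0) & (F < n_fast)
            np.add.at(photons, (S[ok], F[ok]), vals[ok])
        if cfg.noise_model:
            adu = rng.poisson(photons) * cfg.gain
        else:
            adu = np.rint(photons * cfg.gain)
        return np.asarray(np.clip(adu, 0, None), dtype=np.uint32)


def render_frame(reflections: Sequence[ReflectionSet], config: SimConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """One-shot frame rendering (see :class:`FrameRenderer`)."""
    return FrameRenderer(config).render(reflections, rng)


# ---------------------------------------------------------------------------
# runs
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthEvent:
    """Per-event simulator ground truth."""

    event_id: int
    time_s: float
    n_crystals: int
    is_blank: bool
    orientations: list  # list of 3x3 rotation matrices
    reflections: list   # list of ReflectionSet, one per crystal

    @property
    def n_true_peaks(self) -> int:
        return sum(len(r) for r in self.reflections)

    def true_positions(self) -> np.ndarray:
        """(n, 2) stacked (fast, slow) true peak positions over all crystals."""
        mats = [r.positions() for r in self.reflections if len(r)]
        return np.vstack(mats) if mats else np.empty((0, 2))


class GroundTruthTable:
    """Ordered collection of :class:`GroundTruthEvent` with CSV export."""

    def __init__(self, events: list[GroundTruthEvent]):
        self.events = events

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[GroundTruthEvent]:
        return iter(self.events)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ev in self.events:
            pos = ev.true_positions()
            rows.append({
                "event_id": ev.event_id,
                "time_s": ev.time_s,
                "n_crystals": ev.n_crystals,
                "is_blank": ev.is_blank,
                "n_true_peaks": ev.n_true_peaks,
                "true_fast_px": ";".join(f"{v:.3f}" for v in pos[:, 0]),
                "true_slow_px": ";".join(f"{v:.3f}" for v in pos[:, 1]),
            })
        return pd.DataFrame(rows, columns=[
            "event_id", "time_s", "n_crystals", "is_blank", "n_true_peaks",
            "true_fast_px", "true_slow_px"])


@dataclass
class FrameStack:
    """In-memory stack of detector frames with event metadata."""

    frames: np.ndarray       # (n, slow, fast) uint
    event_ids: np.ndarray    # (n,) int
    timestamps: np.ndarray   # (n,) float seconds
    geometry: BeamlineGeometry

    def __len__(self) -> int:
        return self.frames.shape[0]


def _event_miss_probability(config: SimConfig, t: float) -> float:
    p0 = config.drop.miss_probability
    if config.miss_probability_end is None:
        return p0
    frac = min(max(t / config.duration_s, 0.0), 1.0)
    return p0 + (config.miss_probability_end - p0) * frac


def stream_events(config: SimConfig) -> Iterator[tuple[GroundTruthEvent, np.ndarray]]:
    """Yield (ground-truth event, rendered frame) pairs one at a time.

    Frames are emitted at the FEL rate (⌊duration × fel_rate⌋ events). The
    dispenser runs faster than the FEL, so only beam-synchronous drops are
    emitted. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    renderer = FrameRenderer(config)
    geom = config.geometry
    n_frames = int(math.floor(config.duration_s * geom.fel_rate_hz))
    probed_nl = config.drop.probed_volume_nl
    for i in range(n_frames):
        t = i / geom.fel_rate_hz
        blank = False
        if rng.random() < _event_miss_probability(config, t):
            # missed drop; the tail may still carry sample through the beam
            if not (config.drop.tail_hit_probability > 0
                    and rng.random() < config.drop.tail_hit_probability):
                blank = True
        depleted = (config.depletion_time_s is not None
                    and t >= config.depletion_time_s)
        if blank or depleted or config.sample.is_buffer_only:
            n_crystals = 0
        else:
            n_crystals = draw_crystal_count(config.sample.concentration,
                                            probed_nl, rng)
        orientations, refls = [], []
        for _ in range(n_crystals):
            R = random_orientation(rng)
            orientations.append(R)
            refls.append(predict_reflections(config.sample.cell, R, geom,
                                             config.excitation_tol,
                                             config.d_min))
        frame = renderer.render(refls, rng)
        yield (GroundTruthEvent(event_id=i, time_s=t, n_crystals=n_crystals,
                                is_blank=blank, orientations=orientations,
                                reflections=refls),
               frame)


def simulate_run(config: SimConfig) -> tuple[FrameStack, GroundTruthTable]:
    """Simulate a full run and return the frame stack plus ground truth."""
    events, frames = [], []
    for ev, frame in stream_events(config):
        events.append(ev)
        frames.append(frame)
    geom = config.geometry
    stack = FrameStack(
        frames=np.stack(frames) if frames else
        np.empty((0,) + geom.frame_shape, dtype=np.uint32),
        event_ids=np.array([e.event_id for e in events], dtype=np.int64),
        timestamps=np.array([e.time_s for e in events], dtype=float),
        geometry=geom,
    )
    return stack, GroundTruthTable(events)
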