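"""Flat-detector beamline geometry and Bragg-law conversions.

A single flat detector panel at normal beam incidence, described by the
photon energy, sample-to-detector distance, pixel pitch and beam center.
Conversions go pixel position -> radial distance -> scattering angle 2θ ->
d-spacing via Bragg's law, and back.

Pixel coordinates are 0-based in (fast, slow) order with pixel centers at
integer coordinates; the beam center may be fractional.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

#: hc in keV·Å, used to convert photon energy to wavelength.
HC_KEV_ANGSTROM = 12.398419


class UnreachableResolutionError(ValueError):
    """Requested d-spacing cannot be scattered onto a flat detector."""


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength in Å for a photon energy in keV (λ = hc/E)."""
    if energy_kev <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_KEV_ANGSTROM / energy_kev


@dataclass(frozen=True)
class BeamlineGeometry:
    """Flat detector normal to the beam.

    Parameters
    ----------
    photon_energy_kev
        FEL photon energy in keV. 9.28 keV matches a standard MFX
        crystallography configuration.
    detector_distance_mm
        Sample-to-detector distance in mm.
    pixel_pitch_um
        Square pixel edge length in µm.
    beam_center
        (fast, slow) position of the direct beam in fractional pixels.
    frame_shape
        (n_slow, n_fast) detector size in pixels.
    fel_rate_hz
        Pulse repetition rate in frames per second (10 Hz for the Rayonix
        configuration emulated here).

    Notes
    -----
    The distance, pitch and frame size defaults are synthetic desk-scale
    choices (no specific detector is reproduced); only the photon energy
    and repetition rate mirror the emulated beamline configuration.
    """

    photon_energy_kev: float = 9.28
    detector_distance_mm: float = 45.0
    pixel_pitch_um: float = 177.0
    beam_center: tuple[float, float] = (255.5, 255.5)
    frame_shape: tuple[int, int] = (512, 512)
    fel_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.photon_energy_kev <= 0:
            raise ValueError("photon_energy_kev must be > 0")
        if self.detector_distance_mm <= 0:
            raise ValueError("detector_distance_mm must be > 0")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be > 0")
        if len(self.frame_shape) != 2 or any(s < 1 for s in self.frame_shape):
            raise ValueError("frame_shape must be two positive integers")

    @property
    def wavelength(self) -> float:
        """Wavelength in Å derived from the photon energy."""
        return wavelength_from_energy(self.photon_energy_kev)

    # -- pixel <-> d-spacing ------------------------------------------------

    def pixel_to_d(self, pos) -> float | np.ndarray:
        """d-spacing in Å scattering onto pixel position ``pos`` = (fast, slow).

        At the beam center (2θ = 0) the d-spacing diverges; ``inf`` is
        returned as an out-of-range sentinel that shell binning ignores.
        Accepts a single (fast, slow) pair or arrays of fast/slow coordinates.
        """
        pos = np.asarray(pos, dtype=float)
        if pos.shape[-1] != 2:
            raise ValueError("pos must have a trailing dimension of 2 (fast, slow)")
        fast = pos[..., 0]
        slow = pos[..., 1]
        return self.radius_to_d(np.hypot(fast - self.beam_center[0],
                                         slow - self.beam_center[1]))

    def radius_to_d(self, radius_px) -> float | np.ndarray:
        """d-spacing for a radial distance from the beam center in pixels."""
        r = np.asarray(radius_px, dtype=float)
        rho_mm = r * self.pixel_pitch_um * 1e-3
        theta = 0.5 * np.arctan2(rho_mm, self.detector_distance_mm)
        with np.errstate(divide="ignore"):
            d = self.wavelength / (2.0 * np.sin(theta))
        d = np.where(r == 0, np.inf, d)
        return float(d) if d.ndim == 0 else d

    def d_to_ring_radius(self, d: float) -> float:
        """Radius in pixels of the diffraction ring at d-spacing ``d`` (Å).

        radius = D·tan(2·arcsin(λ/2d)) / pitch. Raises
        :class:`UnreachableResolutionError` when d ≤ λ/2 (Bragg's law has no
        solution) or 2θ ≥ 90° (never intersects a flat forward detector).
        """
        lam = self.wavelength
        if d <= lam / 2.0:
            raise UnreachableResolutionError(
                f"d = {d} Å unreachable at λ = {lam:.5f} Å (requires d > λ/2)")
        two_theta = 2.0 * math.asin(lam / (2.0 * d))
        if two_theta >= math.pi / 2.0:
            raise UnreachableResolutionError(
                f"d = {d} Å scatters at 2θ = {math.degrees(two_theta):.1f}° "
                "which never intersects a flat forward detector")
        rho_mm = self.detector_distance_mm * math.tan(two_theta)
        return rho_mm / (self.pixel_pitch_um * 1e-3)

    # -- per-pixel maps -----------------------------------------------------

    def radius_map(self) -> np.ndarray:
        """(n_slow, n_fast) map of radial pixel distance from the beam center."""
        n_slow, n_fast = self.frame_shape
        slow = np.arange(n_slow, dtype=float)[:, None]
        fast = np.arange(n_fast, dtype=float)[None, :]
        return np.hypot(fast - self.beam_center[0], slow - self.beam_center[1])

    def d_map(self) -> np.ndarray:
        """(n_slow, n_fast) map of d-spacing per pixel (inf at the beam center)."""
        return self.radius_to_d(self.radius_map())

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "photon_energy_kev": self.photon_energy_kev,
            "detector_distance_mm": self.detector_distance_mm,
            "pixel_pitch_um": self.pixel_pitch_um,
            "beam_center_fast_px": self.beam_center[0],
            "beam_center_slow_px": self.beam_center[1],
            "frame_n_slow": self.frame_shape[0],
            "frame_n_fast": self.frame_shape[1],
            "fel_rate_hz": self.fel_rate_hz,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "BeamlineGeometry":
        return cls(
            photon_energy_kev=doc["photon_energy_kev"],
            detector_distance_mm=doc["detector_distance_mm"],
            pixel_pitch_um=doc["pixel_pitch_um"],
            beam_center=(doc["beam_center_fast_px"], doc["beam_center_slow_px"]),
            frame_shape=(int(doc["frame_n_slow"]), int(doc["frame_n_fast"])),
            fel_rate_hz=doc.get("fel_rate_hz", 10.0),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BeamlineGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def with_(self, **kwargs) -> "BeamlineGeometry":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
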