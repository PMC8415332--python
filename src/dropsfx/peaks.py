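"""Bragg-peak finding and hit classification on masked detector frames.

A peak is a connected component of unmasked pixels above an ADU threshold,
with at least a minimum pixel count and a minimum signal-to-noise ratio;
a frame with at least ``min_peaks_per_hit`` peaks is a crystal hit. The
defaults (threshold 100 ADU, ≥2 pixels, SNR ≥ 7, ≥15 peaks per hit) are
the standard hit-finding criteria for this kind of drop-delivery SFX data.

The SNR estimator is not part of the hit definition itself and is a
documented choice here: integrated background-subtracted intensity over a
robust (median/MAD) noise estimate from a local annulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import BeamlineGeometry


class BackgroundEstimationError(ValueError):
    """Local background annulus has too few usable pixels."""


@dataclass(frozen=True)
class PeakFindParams:
    """Peak finding and hit classification thresholds."""

    adu_threshold: float = 100.0
    min_pixel_count: int = 2
    min_snr: float = 7.0
    min_peaks_per_hit: int = 15
    connectivity: int = 8
    bg_annulus: tuple[int, int] = (3, 6)   # (inner, outer) radius in px

    def __post_init__(self) -> None:
        if self.adu_threshold <= 0 or self.min_snr <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_pixel_count < 1:
            raise ValueError("min_pixel_count must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        inner, outer = self.bg_annulus
        if not 0 < inner < outer:
            raise ValueError("bg_annulus must satisfy outer > inner > 0")


@dataclass(frozen=True)
class Peak:
    """A found Bragg peak."""

    fast: float          # intensity-weighted centroid, fractional px
    slow: float
    n_pixels: int
    intensity: float     # background-subtracted ADU sum over the component
    snr: float
    d: float             # Å at the centroid


class PeakList:
    """Peaks of one frame, ordered by descending intensity."""

    def __init__(self, peaks: list[Peak]):
        self.peaks = peaks

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    def positions(self) -> np.ndarray:
        """(n, 2) array of (fast, slow) centroids."""
        return np.array([[p.fast, p.slow] for p in self.peaks]).reshape(-1, 2)

    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    def d_spacings(self) -> np.ndarray:
        return np.array([p.d for p in self.peaks])

    def to_dataframe(self, event_id: int | None = None) -> pd.DataFrame:
        rows = [{
            "peak_index": i, "fast": p.fast, "slow": p.slow,
            "n_pixels": p.n_pixels, "intensity_adu": p.intensity,
            "snr": p.snr, "d_angstrom": p.d,
        } for i, p in enumerate(self.peaks)]
        df = pd.DataFrame(rows, columns=["peak_index", "fast", "slow",
                                         "n_pixels", "intensity_adu", "snr",
                                         "d_angstrom"])
        if event_id is not None:
            df.insert(0, "event_id", event_id)
        return df


# ---------------------------------------------------------------------------

def make_ring_mask(geom: BeamlineGeometry,
                   bands: list[tuple[float, float]]) -> np.ndarray:
    """Boolean mask (True = excluded) covering powder-ring annuli.

    ``bands`` is a list of (d_center Å, half_width px); a pixel is excluded
    iff its radial distance from the beam center lies within half_width of
    the ring radius of any band. Used to remove the Cu-shielding rings at
    2.09 Å and 1.81 Å before peak finding.
    """
    r = geom.radius_map()
    mask = np.zeros(geom.frame_shape, dtype=bool)
    for d_center, half_width in bands:
        rc = geom.d_to_ring_radius(d_center)   # raises if unreachable
        mask |= np.abs(r - rc) <= half_width
    return mask


def local_background(frame: np.ndarray, center: tuple[float, float],
                     bg_annulus: tuple[int, int],
                     mask: np.ndarray | None = None) -> tuple[float, float]:
    """Robust local background (median, 1.4826·MAD) from an annulus.

    ``center`` is (fast, slow). Pixels with inner < r ≤ outer from the
    center, unmasked and in-frame, enter the estimate; fewer than 10 such
    pixels raises :class:`BackgroundEstimationError`.
    """
    inner, outer = bg_annulus
    cf, cs = center
    n_slow, n_fast = frame.shape
    s0, s1 = max(0, int(math.floor(cs)) - outer), min(n_slow, int(math.ceil(cs)) + outer + 1)
    f0, f1 = max(0, int(math.floor(cf)) - outer), min(n_fast, int(math.ceil(cf)) + outer + 1)
    ss = np.arange(s0, s1)[:, None]
    ff = np.arange(f0, f1)[None, :]
    r = np.hypot(ff - cf, ss - cs)
    sel = (r > inner) & (r <= outer)
    if mask is not None:
        sel &= ~mask[s0:s1, f0:f1]
    vals = np.asarray(frame[s0:s1, f0:f1], dtype=float)[sel]
    if vals.size < 10:
        raise BackgroundEstimationError(
            f"only {vals.size} usable annulus pixels at ({cf:.1f}, {cs:.1f})")
    med = float(np.median(vals))
    sigma = 1.4826 * float(np.median(np.abs(vals - med)))
    return med, sigma


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def find_peaks(frame: np.ndarray, mask: np.ndarray | None,
               params: PeakFindParams, geom: BeamlineGeometry) -> PeakList:
    """Find Bragg peaks on a masked frame.

    Connected components (4- or 8-connectivity) of unmasked pixels at or
    above ``adu_threshold`` are candidate peaks; those with enough pixels
    and an integrated SNR of at least ``min_snr`` are kept. The component
    intensity is the background-subtracted ADU sum, the centroid is
    intensity-weighted, and each peak gets a d-spacing from the geometry.
    Peaks whose local background annulus is unusable are dropped. Returned
    sorted by descending intensity, ties broken by (slow, fast) ascending.
    """
    frame = np.asarray(frame)
    if mask is None:
        mask = np.zeros(frame.shape, dtype=bool)
    if mask.shape != frame.shape:
        raise ValueError("frame and mask shapes differ")
    above = (frame >= params.adu_threshold) & ~mask
    labels, n_comp = ndimage.label(above, structure=_STRUCTURES[params.connectivity])
    found: list[Peak] = []
    if n_comp == 0:
        return PeakList(found)
    objects = ndimage.find_objects(labels)
    for idx, sl in enumerate(objects, start=1):
        comp = labels[sl] == idx
        n_pix = int(comp.sum())
        if n_pix < params.min_pixel_count:
            continue
        ss, ff = np.nonzero(comp)
        ss = ss + sl[0].start
        ff = ff + sl[1].start
        vals = np.asarray(frame[ss, ff], dtype=float)
        # rough centroid to place the background annulus
        cf0, cs0 = float(ff.mean()), float(ss.mean())
        try:
            bg_med, bg_sigma = local_background(frame, (cf0, cs0),
                                               params.bg_annulus, mask)
        except BackgroundEstimationError:
            continue
        sub = vals - bg_med
        intensity = float(sub.sum())
        if intensity <= 0:
            continue
        if bg_sigma > 0:
            snr = intensity / (bg_sigma * math.sqrt(n_pix))
        else:
            snr = math.inf
        if snr < params.min_snr:
            continue
        w = np.clip(sub, 0, None)
        wsum = w.sum()
        if wsum <= 0:
            continue
        cf = float((w * ff).sum() / wsum)
        cs = float((w * ss).sum() / wsum)
        d = float(geom.pixel_to_d((cf, cs)))
        found.append(Peak(fast=cf, slow=cs, n_pixels=n_pix,
                          intensity=intensity, snr=snr, d=d))
    found.sort(key=lambda p: (-p.intensity, p.slow, p.fast))
    return PeakList(found)


def classify_hit(peak_list: PeakList, params: PeakFindParams) -> bool:
    """True iff the frame has at least ``min_peaks_per_hit`` peaks."""
    return len(peak_list) >= params.min_peaks_per_hit
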