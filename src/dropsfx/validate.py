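"""Indexing validation: cell matching, spot integration, misindexing audit.

Auto-indexing itself is out of scope (it is delegated to established
indexing programs in practice); what is validated here is the step that
makes an indexing solution trustworthy: do the predicted reflection
positions of a candidate (cell, orientation) coincide with Bragg peaks
actually observed on the frame? A solution supported only by a foreign
sample's cell whose predictions do NOT land on real peaks is a
misindexing, and a run in which no event is supported exclusively by a
foreign cell shows no cross-contamination between samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import BeamlineGeometry
from .peaks import PeakList
from .simulate import GroundTruthTable, ReflectionSet, UnitCell, predict_reflections


class UndefinedIntensityError(ValueError):
    """Spot integration impossible (e.g. background annulus fully masked)."""


@dataclass(frozen=True)
class MatchParams:
    """Tolerances for cell equivalence and prediction/peak matching.

    The 5% length and 1.5° angle tolerances are the standard indexing
    tolerances used for these data; ``position_tolerance`` (px) and
    ``support_fraction`` (minimum matched fraction for an indexing to count
    as supported by the image) are free parameters of the audit.
    """

    length_tolerance: float = 0.05
    angle_tolerance: float = 1.5
    position_tolerance: float = 3.0
    support_fraction: float = 0.5

    def __post_init__(self) -> None:
        if min(self.length_tolerance, self.angle_tolerance,
               self.position_tolerance) <= 0:
            raise ValueError("tolerances must be positive")
        if not 0.0 < self.support_fraction <= 1.0:
            raise ValueError("support_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class IntegrationRadii:
    """Spot integration disc and background annulus radii in pixels (3, 4, 5)."""

    r_int: float = 3.0
    r_bg_inner: float = 4.0
    r_bg_outer: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.r_int < self.r_bg_inner < self.r_bg_outer:
            raise ValueError("radii must satisfy 0 < r_int < r_bg_inner < r_bg_outer")


def cells_equivalent(cell_a: UnitCell, cell_b: UnitCell,
                     params: MatchParams = MatchParams()) -> bool:
    """True iff lengths agree within the relative length tolerance and
    angles within the absolute angle tolerance."""
    for la, lb in zip(cell_a.lengths(), cell_b.lengths()):
        if abs(la - lb) > params.length_tolerance * la:
            return False
    for aa, ab in zip(cell_a.angles(), cell_b.angles()):
        if abs(aa - ab) > params.angle_tolerance:
            return False
    return True


def integrate_spot(frame: np.ndarray, position: tuple[float, float],
                   radii: IntegrationRadii = IntegrationRadii(),
                   mask: np.ndarray | None = None) -> float:
    """Background-subtracted spot intensity at a predicted position.

    Sums unmasked pixels within ``r_int`` of ``position`` = (fast, slow) and
    subtracts n_int times the mean of the unmasked annulus
    r_bg_inner ≤ r ≤ r_bg_outer. The position must sit far enough inside
    the frame for the full outer annulus.
    """
    frame = np.asarray(frame, dtype=float)
    n_slow, n_fast = frame.shape
    cf, cs = position
    ro = radii.r_bg_outer
    if not (ro <= cf <= n_fast - 1 - ro and ro <= cs <= n_slow - 1 - ro):
        raise ValueError(f"position ({cf:.1f}, {cs:.1f}) lacks a full outer annulus")
    s0, s1 = int(math.floor(cs - ro)), int(math.ceil(cs + ro)) + 1
    f0, f1 = int(math.floor(cf - ro)), int(math.ceil(cf + ro)) + 1
    ss = np.arange(s0, s1)[:, None]
    ff = np.arange(f0, f1)[None, :]
    r = np.hypot(ff - cf, ss - cs)
    patch = frame[s0:s1, f0:f1]
    unmasked = np.ones(patch.shape, dtype=bool) if mask is None \
        else ~mask[s0:s1, f0:f1]
    disc = (r <= radii.r_int) & unmasked
    ann = (r >= radii.r_bg_inner) & (r <= ro) & unmasked
    if not ann.any():
        raise UndefinedIntensityError("background annulus fully masked")
    n_int = int(disc.sum())
    return float(patch[disc].sum() - n_int * patch[ann].mean())


def match_predictions(predicted: ReflectionSet | np.ndarray, observed: PeakList,
                      position_tolerance: float = 3.0) -> np.ndarray:
    """Boolean matched-mask over predicted positions (input order).

    Greedy one-to-one nearest matching: predictions are visited in order of
    descending d (low resolution first; a deterministic order), each taking
    its nearest unconsumed observed peak within ``position_tolerance`` px.
    """
    if isinstance(predicted, ReflectionSet):
        pos = predicted.positions()
        order = np.argsort(-predicted.d, kind="stable")
    else:
        pos = np.asarray(predicted, dtype=float).reshape(-1, 2)
        order = np.arange(pos.shape[0])
    n_pred = pos.shape[0]
    matched = np.zeros(n_pred, dtype=bool)
    obs = observed.positions()
    if n_pred == 0 or obs.shape[0] == 0:
        return matched
    consumed = np.zeros(obs.shape[0], dtype=bool)
    for i in order:
        p = pos[i]
        dist = np.hypot(obs[:, 0] - p[0], obs[:, 1] - p[1])
        dist[consumed] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= position_tolerance:
            consumed[j] = True
            matched[i] = True
    return matched


def match_fraction(predicted: ReflectionSet | np.ndarray, observed: PeakList,
                   position_tolerance: float = 3.0) -> float:
    """Fraction of predicted positions matched by observed peak centroids.

    See :func:`match_predictions` for the matching rule. An empty
    prediction list scores 0 by convention.
    """
    matched = match_predictions(predicted, observed, position_tolerance)
    if matched.size == 0:
        return 0.0
    return float(matched.sum()) / matched.size


def contamination_audit(truth: GroundTruthTable,
                        peak_lists: dict[int, PeakList],
                        cells: dict[str, UnitCell],
                        true_label: str | dict[int, str],
                        geom: BeamlineGeometry,
                        params: MatchParams = MatchParams(),
                        excitation_tol: float = 0.0015,
                        d_min: float = 2.0,
                        seed: int = 0) -> pd.DataFrame:
    """Score every event against every candidate sample cell.

    For the event's own sample the candidate solutions are the simulator's
    ground-truth orientations; for foreign cells a random orientation is
    drawn (a stand-in for what a misindexing would propose — its predicted
    spots should not coincide with real peaks). Events without peaks are
    scored 0 against every cell. ``true_label`` is one label for the whole
    run, or an event_id → label map for mixed tables.

    Returns a table with one row per (event, cell): event_id, cell_label,
    n_predicted, n_matched, match_fraction, supported. A run free of
    cross-contamination has no event supported *only* by a foreign cell
    (see :func:`foreign_only_supported`).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ev in truth:
        observed = peak_lists.get(ev.event_id, PeakList([]))
        own_label = true_label.get(ev.event_id) \
            if isinstance(true_label, dict) else true_label
        for label, cell in sorted(cells.items()):
            if label == own_label and ev.orientations:
                refl_sets = [predict_reflections(cell, R, geom, excitation_tol,
                                                 d_min)
                             for R in ev.orientations]
            else:
                from .simulate import random_orientation
                refl_sets = [predict_reflections(cell, random_orientation(rng),
                                                 geom, excitation_tol, d_min)]
            scored = [(match_fraction(r, observed, params.position_tolerance),
                       len(r)) for r in refl_sets]
            best, n_pred = max(scored, default=(0.0, 0))
            rows.append({
                "event_id": ev.event_id,
                "cell_label": label,
                "n_predicted": n_pred,
                "n_matched": int(round(best * n_pred)),
                "match_fraction": best,
                "supported": bool(best >= params.support_fraction and n_pred > 0),
            })
    return pd.DataFrame(rows, columns=["event_id", "cell_label", "n_predicted",
                                       "n_matched", "match_fraction",
                                       "supported"])


def foreign_only_supported(audit: pd.DataFrame,
                           true_label: str | dict[int, str]) -> int:
    """Number of events supported by some foreign cell but not their own."""
    if audit.empty:
        return 0
    count = 0
    for event_id, grp in audit.groupby("event_id"):
        own_label = true_label.get(event_id) \
            if isinstance(true_label, dict) else true_label
        own = grp.loc[grp.cell_label == own_label, "supported"].any()
        foreign = grp.loc[grp.cell_label != own_label, "supported"].any()
        if foreign and not own:
            count += 1
    return count
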