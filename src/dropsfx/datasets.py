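"""Reference data: published per-run beamtime statistics and default samples.

``BEAMTIME_RUN_STATS`` reproduces the per-run hit-finding and indexing
statistics of a drop-on-demand SFX beamtime at a 10 Hz FEL beamline
(thaumatin, proteinase K, xylanase and alcohol-dehydrogenase runs). It is
used as a regression fixture for the rate arithmetic: every printed
indexing-rate cell must be recoverable from the printed (indexed, hits)
pairs. The "Number of indexed" columns count crystals (a multi-crystal
pattern contributes several), and the indexing rate is indexed crystals of
the run's own sample divided by the number of hits.

The unit cells in ``DEFAULT_CELLS`` are literature-typical synthetic
defaults for the four samples — configuration, not measured ground truth.
"""

from __future__ import annotations

import pandas as pd

from .simulate import SampleModel, UnitCell

_RUN_ROWS = [
    # run, sample, run_time_s, n_hits, hit_rate_pct,
    # indexed_Th, indexed_PK, indexed_Xy, indexed_AD,
    # indexing_rate_pct, avg_dlimit_A, avg_n_peaks, avg_intensity_adu
    (31, "Th", 357, 1083, 30.4, 271, 0, 0, 1, 25.0, 3.1, 82.0, 970.0),
    (32, "Th", 640, 2454, 38.3, 1094, 0, 0, 8, 44.6, 3.2, 56.0, 947.0),
    (33, "Th", 617, 5604, 90.9, 963, 0, 0, 4, 17.2, 3.0, 91.0, 920.0),
    (34, "Th", 556, 3756, 67.6, 770, 0, 0, 3, 20.5, 3.1, 84.0, 897.0),
    (35, "Th", 557, 2480, 44.5, 726, 1, 0, 4, 29.3, 3.2, 64.0, 906.0),
    (36, "Th", 660, 363, 5.5, 266, 0, 0, 0, 73.3, 3.4, 27.0, 926.0),
    (37, "PK", 733, 683, 9.3, 0, 569, 0, 5, 83.3, 2.7, 52.0, 2149.0),
    (38, "PK", 729, 771, 10.6, 0, 709, 0, 11, 92.0, 2.7, 67.0, 2483.0),
    (39, "Th", 438, 1109, 25.3, 434, 0, 0, 3, 39.1, 3.1, 98.0, 1117.0),
    (40, "Th", 309, 2732, 88.5, 145, 0, 0, 1, 5.3, 2.9, 256.0, 1107.0),
    (42, "Xy", 129, 670, 51.9, 1, 0, 41, 2, 6.1, 2.6, 90.0, 1848.0),
    (43, "AD", 58, 0, 0.0, 0, 0, 0, 0, 0.0, None, None, None),
    (44, "AD", 84, 0, 0.0, 0, 0, 0, 0, 0.0, None, None, None),
    (45, "AD", 74, 1, 0.1, 0, 0, 0, 0, 0.0, None, 17.0, 1710.0),
]

#: Published per-run statistics (see module docstring).
BEAMTIME_RUN_STATS = pd.DataFrame(_RUN_ROWS, columns=[
    "run", "sample", "run_time_s", "n_hits", "hit_rate_pct",
    "indexed_Th", "indexed_PK", "indexed_Xy", "indexed_AD",
    "indexing_rate_pct", "avg_dlimit_A", "avg_n_peaks", "avg_intensity_adu",
])

#: crystals indexed with the run's own sample cell, keyed by run number
OWN_CELL_COLUMN = {"Th": "indexed_Th", "PK": "indexed_PK",
                   "Xy": "indexed_Xy", "AD": "indexed_AD"}

#: Literature-typical unit cells (synthetic defaults; not measured here).
DEFAULT_CELLS = {
    "Th": UnitCell(57.8, 57.8, 150.1, 90, 90, 90, label="Th"),
    "PK": UnitCell(68.3, 68.3, 108.5, 90, 90, 90, label="PK"),
    "Xy": UnitCell(49.0, 77.2, 38.1, 90, 90, 90, label="Xy"),
    "AD": UnitCell(44.5, 180.4, 86.8, 90, 90, 90, label="AD"),
}

#: Estimated slurry number densities (crystals / nl).
DEFAULT_CONCENTRATIONS = {"Th": 400.0, "Xy": 400.0, "PK": 45.0, "AD": 45.0}


def default_sample(label: str) -> SampleModel:
    """A :class:`SampleModel` with the default cell and concentration."""
    return SampleModel(name=label, cell=DEFAULT_CELLS[label],
                       concentration=DEFAULT_CONCENTRATIONS[label])
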