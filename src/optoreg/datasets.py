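"""Bundled reference data: group-averaged optode coordinates (MNI, mm).

Two registration methods — a photogrammetric optode registration (POR,
averaged over pre- and post-MRI photo sessions) and an MRI-based
registration — measured the same 18-optode left-hemisphere cap in an adult
and a child cohort. The group-averaged MNI coordinates per optode are kept
here as machine-readable fixtures for worked examples and regression tests
of the comparison metrics.
"""

from __future__ import annotations

import numpy as np

from .geometry_io import MNI, PointTable

# optode id: ((POR x, y, z), (MRI x, y, z))
ADULT_OPTODES = {
    "1":  ((-61, 34, -7),   (-59, 39, -5)),
    "2":  ((-67, 1, -1),    (-66, 6, 1)),
    "3":  ((-62, -32, 5),   (-65, -25, 7)),
    "4":  ((-46, -58, 6),   (-51, -51, 9)),
    "5":  ((-65, -31, -29), (-64, -31, -32)),
    "6":  ((-48, -61, -23), (-49, -59, -28)),
    "7":  ((-53, 60, -27),  (-53, 60, -29)),
    "8":  ((-48, 54, 4),    (-47, 59, 4)),
    "9":  ((-63, 19, -21),  (-64, 18, -23)),
    "10": ((-61, 16, 13),   (-58, 27, 14)),
    "11": ((-68, -15, -17), (-69, -13, -19)),
    "12": ((-62, -19, 19),  (-62, -7, 21)),
    "13": ((-58, -45, -12), (-61, -40, -13)),
    "14": ((-51, -45, 20),  (-55, -34, 24)),
    "15": ((-37, -70, -8),  (-41, -66, -7)),
    "16": ((-33, -63, 18),  (-38, -55, 20)),
    "17": ((-56, -46, -39), (-52, -49, -47)),
    "18": ((-37, -71, -34), (-38, -69, -39)),
}

CHILD_OPTODES = {
    "1":  ((-59, 41, -9),   (-59, 39, -9)),
    "2":  ((-66, 4, -2),    (-66, 6, -5)),
    "3":  ((-63, -31, 3),   (-65, -27, -4)),
    "4":  ((-47, -58, 4),   (-50, -55, -6)),
    "5":  ((-65, -28, -32), (-62, -30, -41)),
    "6":  ((-49, -60, -28), (-46, -58, -44)),
    "7":  ((-50, 66, -30),  (-52, 61, -30)),
    "8":  ((-48, 59, 2),    (-47, 57, 6)),
    "9":  ((-62, 24, -24),  (-63, 19, -27)),
    "10": ((-60, 21, 12),   (-59, 24, 13)),
    "11": ((-68, -12, -21), (-68, -12, -25)),
    "12": ((-63, -17, 18),  (-64, -10, 16)),
    "13": ((-56, -45, -15), (-59, -42, -24)),
    "14": ((-52, -46, 18),  (-55, -40, 14)),
    "15": ((-38, -70, -12), (-39, -69, -22)),
    "16": ((-34, -64, 15),  (-36, -63, 12)),
    "17": ((-56, -43, -45), (-51, -47, -57)),
    "18": ((-37, -69, -40), (-35, -67, -52)),
}

# group-averaged frontal channel positions (channels 1-4), same methods
ADULT_CHANNELS = {
    "CH1": ((-57, 47, -17), (-56, 50, -17)),
    "CH2": ((-55, 44, -2),  (-53, 49, -1)),
    "CH3": ((-62, 27, -14), (-62, 29, -14)),
    "CH4": ((-61, 25, 3),   (-59, 33, 5)),
}

CHILD_CHANNELS = {
    "CH1": ((-55, 54, -20), (-56, 50, -20)),
    "CH2": ((-54, 50, -4),  (-53, 48, -2)),
    "CH3": ((-61, 33, -17), (-61, 29, -18)),
    "CH4": ((-60, 31, 2),   (-59, 32, 2)),
}


def _tables(mapping: dict) -> tuple[PointTable, PointTable]:
    ids = list(mapping)
    por = np.array([mapping[i][0] for i in ids], dtype=float)
    mri = np.array([mapping[i][1] for i in ids], dtype=float)
    return PointTable(ids, por, MNI), PointTable(ids, mri, MNI)


def load_reference_optodes(group: str = "adult") -> tuple[PointTable, PointTable]:
    """(POR, MRI) group-averaged optode tables for ``group`` in {adult, child}."""
    if group not in ("adult", "child"):
        raise ValueError(f"unknown group {group!r}")
    return _tables(ADULT_OPTODES if group == "adult" else CHILD_OPTODES)


def load_reference_channels(group: str = "adult") -> tuple[PointTable, PointTable]:
    """(POR, MRI) frontal channel position tables for ``group``."""
    if group not in ("adult", "child"):
        raise ValueError(f"unknown group {group!r}")
    return _tables(ADULT_CHANNELS if group == "adult" else CHILD_CHANNELS)
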