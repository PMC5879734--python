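"""Reference cohort statistics from a 20-patient free-breathing liver study.

These constants summarise the displacement of nine representative points
(one per Couinaud segment: 1, 2, 3, 4a, 4b, 5, 6, 7, 8) measured between a
helical CT snapshot and the two extreme phases of a 10-phase-gated 4DCT
(phase 0 = end-inspiration, phase 50 = end-expiration) in a cohort of 20
patients scanned under free breathing.

Sign convention (fixed for the whole package): positive displacements point
left / posterior / superior; negative point right / anterior / inferior.
All distances are millimetres, printed to 0.1 mm.

The per-segment expiration amplitudes (phase 0 -> phase 50) parameterise the
default synthetic cohort generator; the helical -> phase statistics and the
published ITV margins serve as inputs and cross-checks for the margin
derivation.
"""

from __future__ import annotations

SEGMENTS: tuple[str, ...] = ("S1", "S2", "S3", "S4a", "S4b", "S5", "S6", "S7", "S8")
AXES: tuple[str, ...] = ("lr", "ap", "si")

# Expiration amplitude (phase 0 -> phase 50), per segment: axis -> (mean, sd) mm.
EXPIRATION_AMPLITUDE_MM: dict[str, dict[str, tuple[float, float]]] = {
    "S1":  {"lr": (-2.0, 2.6), "ap": (1.0, 1.3), "si": (5.5, 2.6)},
    "S2":  {"lr": (0.3, 2.2),  "ap": (1.2, 3.5), "si": (6.3, 4.2)},
    "S3":  {"lr": (-0.3, 1.9), "ap": (2.4, 1.4), "si": (5.8, 2.8)},
    "S4a": {"lr": (-1.4, 3.3), "ap": (1.5, 2.4), "si": (3.0, 2.6)},
    "S4b": {"lr": (-1.2, 1.6), "ap": (2.0, 1.9), "si": (5.3, 3.4)},
    "S5":  {"lr": (-0.2, 2.1), "ap": (3.2, 2.0), "si": (5.5, 2.4)},
    "S6":  {"lr": (-0.1, 4.6), "ap": (2.2, 2.3), "si": (6.5, 3.5)},
    "S7":  {"lr": (-1.4, 3.8), "ap": (3.5, 2.5), "si": (8.6, 3.4)},
    "S8":  {"lr": (1.0, 2.6),  "ap": (3.3, 2.3), "si": (5.0, 3.3)},
}

# Overall row of the expiration-amplitude table (pooled over 9 segments x 20
# patients): axis -> (mean, sd) mm.
EXPIRATION_AMPLITUDE_OVERALL_MM: dict[str, tuple[float, float]] = {
    "lr": (-0.6, 3.0),
    "ap": (2.3, 2.4),
    "si": (5.7, 3.4),
}

# Helical -> phase 0 displacement, per segment: axis -> (mean, sd) mm.
HELICAL_TO_PHASE0_MM: dict[str, dict[str, tuple[float, float]]] = {
    "S1":  {"lr": (0.8, 3.1),  "ap": (0.4, 1.6),  "si": (-2.5, 3.9)},
    "S2":  {"lr": (-1.1, 2.5), "ap": (-0.6, 3.7), "si": (-2.4, 4.9)},
    "S3":  {"lr": (-0.3, 2.9), "ap": (-1.8, 3.1), "si": (-2.9, 3.5)},
    "S4a": {"lr": (0.4, 2.8),  "ap": (-1.4, 2.1), "si": (-0.6, 3.9)},
    "S4b": {"lr": (-0.5, 1.5), "ap": (-1.7, 2.2), "si": (-2.4, 3.5)},
    "S5":  {"lr": (-2.2, 1.7), "ap": (-1.4, 2.1), "si": (-1.9, 2.2)},
    "S6":  {"lr": (0.2, 4.3),  "ap": (-1.2, 2.3), "si": (-3.2, 2.9)},
    "S7":  {"lr": (0.3, 4.2),  "ap": (-1.7, 2.8), "si": (-3.6, 4.4)},
    "S8":  {"lr": (-2.2, 2.5), "ap": (-1.5, 2.6), "si": (-1.9, 3.4)},
}

# Helical -> phase 50 displacement, per segment: axis -> (mean, sd) mm.
HELICAL_TO_PHASE50_MM: dict[str, dict[str, tuple[float, float]]] = {
    "S1":  {"lr": (-1.1, 2.2), "ap": (1.4, 1.8), "si": (3.0, 3.5)},
    "S2":  {"lr": (-0.8, 2.6), "ap": (0.6, 2.1), "si": (3.9, 4.1)},
    "S3":  {"lr": (-0.7, 3.1), "ap": (0.6, 3.0), "si": (2.9, 2.5)},
    "S4a": {"lr": (-1.0, 1.7), "ap": (0.1, 2.4), "si": (2.4, 3.4)},
    "S4b": {"lr": (-1.8, 1.6), "ap": (0.3, 2.2), "si": (2.9, 3.3)},
    "S5":  {"lr": (-2.3, 1.3), "ap": (1.7, 2.4), "si": (3.7, 2.1)},
    "S6":  {"lr": (0.1, 4.1),  "ap": (1.0, 2.3), "si": (3.3, 3.7)},
    "S7":  {"lr": (-1.1, 2.6), "ap": (1.8, 2.1), "si": (5.0, 4.8)},
    "S8":  {"lr": (-1.3, 1.5), "ap": (1.8, 2.5), "si": (3.2, 3.1)},
}

HELICAL_TO_PHASE0_OVERALL_MM: dict[str, tuple[float, float]] = {
    "lr": (-0.5, 3.1),
    "ap": (-1.2, 2.6),
    "si": (-2.4, 3.7),
}

HELICAL_TO_PHASE50_OVERALL_MM: dict[str, tuple[float, float]] = {
    "lr": (-1.1, 2.5),
    "ap": (1.0, 2.4),
    "si": (3.4, 3.5),
}

# Published asymmetric ITV expansion margins, per segment: axis -> (neg, pos)
# mm.  neg <= 0 expands toward right/anterior/inferior, pos >= 0 toward
# left/posterior/superior.
PUBLISHED_ITV_MARGIN_MM: dict[str, dict[str, tuple[float, float]]] = {
    "S1":  {"lr": (-2.2, 2.3), "ap": (-0.4, 2.3), "si": (-4.4, 4.7)},
    "S2":  {"lr": (-2.3, 0.5), "ap": (-2.4, 1.6), "si": (-4.7, 5.9)},
    "S3":  {"lr": (-2.2, 1.1), "ap": (-3.3, 2.1), "si": (-4.6, 4.1)},
    "S4a": {"lr": (-1.8, 1.8), "ap": (-2.4, 1.3), "si": (-2.4, 4.0)},
    "S4b": {"lr": (-2.6, 0.3), "ap": (-2.8, 1.4), "si": (-4.1, 4.5)},
    "S5":  {"lr": (-3.0, 0.0), "ap": (-2.4, 2.9), "si": (-3.0, 4.7)},
    "S6":  {"lr": (-1.9, 2.3), "ap": (-2.3, 2.1), "si": (-4.6, 5.1)},
    "S7":  {"lr": (-2.4, 2.3), "ap": (-3.1, 2.8), "si": (-5.7, 7.3)},
    "S8":  {"lr": (-3.4, 0.0), "ap": (-2.8, 3.0), "si": (-3.5, 4.7)},
}

PUBLISHED_ITV_MARGIN_OVERALL_MM: dict[str, tuple[float, float]] = {
    "lr": (-2.5, 1.2),
    "ap": (-2.5, 2.2),
    "si": (-4.2, 5.0),
}

# Cohort-mean lung volumes (ml) per imaging state, left and right lungs.
# The total is left + right by construction.
LUNG_VOLUME_MEAN_ML: dict[str, dict[str, float]] = {
    "helical": {"left": 1104.6, "right": 1444.7},
    "phase0":  {"left": 1167.0, "right": 1529.8},
    "phase50": {"left": 1034.3, "right": 1336.1},
}

# t multiplier of the margin formula at the study's cohort size: the
# two-sided 95% Student-t quantile at 19 degrees of freedom.
STUDY_N_PATIENTS: int = 20
STUDY_T_MULTIPLIER: float = 2.093
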