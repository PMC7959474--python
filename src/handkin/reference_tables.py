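"""Published reference values from a representative validation study of a
markerless hand tracker (LMC) against a marker-based system (QTM).

These printed group-level tables serve as inputs for arithmetic
cross-checks and as the default population for the simulator; they are not
raw capture data.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import pandas as pd

#: (task, joint, LMC ROM deg, QTM ROM deg, printed QTM-LMC difference deg)
ROM_COMPARISON_ROWS: List[Tuple[str, str, float, float, float]] = [
    ("thumb_abduction", "thumb_ip", 31.26, 37.75, 6.49),
    ("thumb_abduction", "thumb_mcp", 41.38, 49.65, 8.27),
    ("thumb_abduction", "thumb_cmc", 54.10, 42.44, -11.66),
    ("thumb_flexion", "thumb_ip", 43.86, 72.15, 28.29),
    ("thumb_flexion", "thumb_mcp", 43.16, 62.47, 19.31),
    ("thumb_flexion", "thumb_cmc", 53.66, 45.73, -7.93),
    ("index_flexion", "index_dip", 68.78, 68.31, -0.47),
    ("index_flexion", "index_pip", 81.09, 81.34, 0.25),
    ("index_flexion", "index_mcp", 107.86, 86.66, -21.20),
    ("middle_flexion", "middle_dip", 33.80, 21.38, -12.42),
    ("middle_flexion", "middle_pip", 43.59, 105.10, 61.51),
    ("middle_flexion", "middle_mcp", 72.36, 92.64, 20.28),
    ("ring_flexion", "ring_dip", 47.49, 19.86, -27.63),
    ("ring_flexion", "ring_pip", 69.55, 103.94, 34.39),
    ("ring_flexion", "ring_mcp", 78.89, 83.39, 4.50),
    ("pinky_flexion", "pinky_dip", 41.16, 50.32, 9.16),
    ("pinky_flexion", "pinky_pip", 57.35, 94.68, 37.33),
    ("pinky_flexion", "pinky_mcp", 78.08, 95.61, 17.53),
]


def rom_comparison_table() -> pd.DataFrame:
    return pd.DataFrame(ROM_COMPARISON_ROWS,
                        columns=["task", "joint", "lmc_rom", "qtm_rom", "printed_difference"])


#: worked flexion-extrema example (index finger, one trial): per-joint
#: (system, max deg, min deg)
FLEXION_EXTREMA_EXAMPLE: Dict[str, Dict[str, Tuple[float, float]]] = {
    "index_mcp": {"qtm": (78.01, 9.62), "lmc": (80.85, 9.69)},
    "index_pip": {"qtm": (73.80, 2.33), "lmc": (83.40, 2.62)},
    "index_dip": {"qtm": (17.88, 1.63), "lmc": (70.12, 1.68)},
}

#: group mean +/- sd segment lengths (mm) per system: finger -> segment ->
#: {"lmc": (mean, sd), "qtm": (mean, sd)}; non-thumb metacarpals were not
#: reported for the marker-based system
SEGMENT_LENGTH_REFERENCE: Dict[str, Dict[str, Dict[str, Tuple[float, float]]]] = {
    "thumb": {
        "distal": {"lmc": (22.68, 10.61), "qtm": (19.27, 10.52)},
        "proximal": {"lmc": (33.06, 10.70), "qtm": (32.32, 11.65)},
        "metacarpal": {"lmc": (48.40, 12.41), "qtm": (38.12, 11.15)},
    },
    "index": {
        "distal": {"lmc": (18.99, 10.25), "qtm": (17.08, 9.72)},
        "intermediate": {"lmc": (23.42, 10.69), "qtm": (25.73, 12.14)},
        "proximal": {"lmc": (39.17, 12.86), "qtm": (44.89, 13.19)},
    },
    "middle": {
        "distal": {"lmc": (18.21, 12.08), "qtm": (17.71, 11.57)},
        "intermediate": {"lmc": (27.58, 11.51), "qtm": (30.21, 12.07)},
        "proximal": {"lmc": (46.46, 13.24), "qtm": (50.59, 13.07)},
    },
    "ring": {
        "distal": {"lmc": (18.10, 10.84), "qtm": (17.40, 10.75)},
        "intermediate": {"lmc": (26.87, 10.56), "qtm": (28.95, 10.94)},
        "proximal": {"lmc": (43.33, 11.59), "qtm": (44.90, 10.90)},
    },
    "pinky": {
        "distal": {"lmc": (16.67, 8.50), "qtm": (16.69, 8.65)},
        "intermediate": {"lmc": (18.96, 8.41), "qtm": (19.58, 7.96)},
        "proximal": {"lmc": (34.28, 2.76), "qtm": (36.31, 3.58)},
    },
}
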