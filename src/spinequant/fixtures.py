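"""Published per-vertebra cohort measurements shipped as a fixture.

Seven patients (three with diffuse osteoblastic metastases of L1-L4, four
with osteoporosis), four lumbar levels each, three measures per vertebra:
PDFF (%), FEA failure displacement (mm) and FEA failure load (N). Fracture
flags mark previously fractured / vertebroplastied vertebrae (patient 4:
L2+L3 vertebroplasty, patient 5: L4 endplate fracture, patient 6: L2
compression fracture and L4 endplate fracture); fractured vertebrae are
excluded from all averaging and statistics.

``PRINTED_PATIENT_SUMMARY`` and ``PRINTED_POOLED`` hold the published
per-patient and pooled "median [Q1-Q3]" values used by the regression
harness (:func:`spinequant.stats.reproduce_table1`).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "table1_fixture",
    "PRINTED_PATIENT_SUMMARY",
    "PRINTED_POOLED",
    "MEASURES",
    "MEASURE_DECIMALS",
]

LEVELS = ("L1", "L2", "L3", "L4")
MEASURES = ("pdff_percent", "failure_displacement_mm", "failure_load_N")
MEASURE_DECIMALS = {"pdff_percent": 1, "failure_displacement_mm": 3,
                    "failure_load_N": 0}

# patient id -> (group, pdff x4, displacement x4, load x4, fractured levels)
_TABLE1 = {
    1: ("metastasis", (24.1, 26.2, 27.8, 31.8),
        (1.027, 0.775, 0.911, 0.724), (19735, 13240, 39470, 27447), ()),
    2: ("metastasis", (14.4, 10.3, 9.4, 5.6),
        (1.050, 0.708, 0.804, 0.979), (29731, 29447, 22665, 50760), ()),
    3: ("metastasis", (7.7, 13.4, 8.8, 9.8),
        (0.884, 0.841, 0.942, 0.864), (45616, 53618, 53510, 27663), ()),
    4: ("osteoporosis", (46.0, 41.4, 35.8, 49.4),
        (0.325, 0.978, 0.769, 0.526), (4161, 3173, 10248, 3095), ("L2", "L3")),
    5: ("osteoporosis", (33.4, 38.0, 41.6, 26.3),
        (0.296, 0.369, 0.348, 0.315), (3744, 4108, 4303, 5995), ("L4",)),
    6: ("osteoporosis", (41.0, 8.1, 43.8, 38.5),
        (0.221, 0.224, 0.311, 0.257), (3235, 6275, 2728, 6024), ("L2", "L4")),
    7: ("osteoporosis", (43.9, 43.0, 48.6, 45.5),
        (0.301, 0.502, 0.605, 0.504), (2188, 2797, 2611, 2558), ()),
}

# patient id -> measure -> (median, q1, q3) as printed
PRINTED_PATIENT_SUMMARY = {
    1: {"pdff_percent": (27.0, 25.7, 28.8),
        "failure_displacement_mm": (0.843, 0.762, 0.940),
        "failure_load_N": (23591, 18111, 30453)},
    2: {"pdff_percent": (9.9, 8.5, 11.3),
        "failure_displacement_mm": (0.892, 0.780, 0.997),
        "failure_load_N": (29589, 27752, 34988)},
    3: {"pdff_percent": (9.3, 8.5, 10.7),
        "failure_displacement_mm": (0.874, 0.858, 0.899),
        "failure_load_N": (49563, 41128, 53537)},
    4: {"pdff_percent": (47.7, 46.9, 48.6),
        "failure_displacement_mm": (0.426, 0.375, 0.476),
        "failure_load_N": (3628, 3361, 3895)},
    5: {"pdff_percent": (38.0, 35.7, 39.8),
        "failure_displacement_mm": (0.348, 0.322, 0.359),
        "failure_load_N": (4108, 3926, 4205)},
    6: {"pdff_percent": (42.4, 41.7, 43.1),
        "failure_displacement_mm": (0.266, 0.244, 0.289),
        "failure_load_N": (2981, 2854, 3108)},
    7: {"pdff_percent": (44.7, 43.7, 46.2),
        "failure_displacement_mm": (0.503, 0.451, 0.529),
        "failure_load_N": (2584, 2465, 2658)},
}

# group -> measure -> (median, q1, q3) pooled over non-fractured vertebrae
PRINTED_POOLED = {
    "metastasis": {"pdff_percent": (11.9, 9.3, 24.7),
                   "failure_displacement_mm": (0.874, 0.797, 0.951),
                   "failure_load_N": (29589, 26252, 46902)},
    "osteoporosis": {"pdff_percent": (43.8, 41.3, 45.7),
                     "failure_displacement_mm": (0.348, 0.306, 0.503),
                     "failure_load_N": (3095, 2669, 3926)},
}


def table1_fixture() -> pd.DataFrame:
    """The cohort table: 7 patients x 4 levels, with fracture flags.

    Columns: patient_id, group, level, fractured, pdff_percent,
    failure_displacement_mm, failure_load_N. 28 rows, 5 flagged fractured.
    """
    rows = []
    for pid, (group, pdff, disp, load, fractured) in _TABLE1.items():
        for i, lev in enumerate(LEVELS):
            rows.append({
                "patient_id": pid,
                "group": group,
                "level": lev,
                "fractured": lev in fractured,
                "pdff_percent": pdff[i],
                "failure_displacement_mm": disp[i],
                "failure_load_N": float(load[i]),
            })
    return pd.DataFrame(rows)
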