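"""Bundled small tables.

``load_demographics`` returns the 32-row clinical summary table of the
primary retrospective cohort (sex, age, Karnofsky performance status,
resection type, chemoradiotherapy flag) used by the cohort-summary
operation and by examples.
"""

from __future__ import annotations

import pandas as pd

# (case, sex, age, kps, resection, chemoradiotherapy)
_DEMOGRAPHICS = [
    (1, "M", 56, 90, "total", "N"),
    (2, "F", 42, 90, "total", "N"),
    (3, "M", 73, 90, "subtotal", "Y"),
    (4, "F", 48, 90, "total", "N"),
    (5, "F", 54, 90, "total", "Y"),
    (6, "M", 62, 80, "total", "N"),
    (7, "M", 41, 80, "total", "Y"),
    (8, "F", 44, 90, "total", "N"),
    (9, "F", 27, 90, "total", "N"),
    (10, "M", 51, 90, "total", "Y"),
    (11, "M", 72, 90, "total", "Y"),
    (12, "M", 54, 80, "total", "N"),
    (13, "M", 42, 80, "subtotal", "Y"),
    (14, "M", 66, 80, "total", "N"),
    (15, "M", 33, 90, "total", "Y"),
    (16, "F", 25, 80, "total", "N"),
    (17, "F", 52, 80, "total", "Y"),
    (18, "F", 70, 80, "total", "Y"),
    (19, "M", 33, 80, "total", "N"),
    (20, "F", 76, 70, "total", "Y"),
    (21, "F", 46, 80, "total", "N"),
    (22, "M", 37, 80, "total", "N"),
    (23, "F", 52, 90, "total", "Y"),
    (24, "M", 26, 80, "subtotal", "Y"),
    (25, "M", 34, 60, "total", "Y"),
    (26, "F", 49, 70, "total", "N"),
    (27, "M", 52, 60, "subtotal", "Y"),
    (28, "F", 73, 80, "total", "Y"),
    (29, "M", 64, 80, "total", "Y"),
    (30, "F", 67, 60, "total", "Y"),
    (31, "F", 46, 70, "total", "Y"),
    (32, "F", 51, 65, "total", "Y"),
]


def load_demographics() -> pd.DataFrame:
    """Clinical summary of the 32-case primary cohort."""
    return pd.DataFrame(
        _DEMOGRAPHICS,
        columns=["case", "sex", "age", "kps", "resection", "chemoradiotherapy"])
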