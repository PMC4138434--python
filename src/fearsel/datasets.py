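"""Reference datasets for the vocalization-incidence analyses.

``VOCALIZER_INCIDENCE`` holds the published first-generation incidence of
ultrasonic-vocalizer status (vocalizers / subjects tested) by affect band,
breeding line, and sex: 18-32 kHz long "negative affect" calls and 32-96 kHz
short "positive affect" calls, for the low-extinguisher (LE), random-bred
(RB) and high-extinguisher (HE) lines (231 subjects in total).  The helper
functions assemble the vocalizer/non-vocalizer contingency tables whose
Pearson chi-squares quantify line and sex differences in call incidence.
"""

from __future__ import annotations

import pandas as pd

from fearsel.usv import NEGATIVE_BAND, POSITIVE_BAND

#: (vocalizers, n_tested) per (band, line, sex)
VOCALIZER_INCIDENCE: dict[str, dict[tuple[str, str], tuple[int, int]]] = {
    NEGATIVE_BAND: {
        ("LE", "M"): (11, 48), ("LE", "F"): (4, 50),
        ("RB", "M"): (6, 20), ("RB", "F"): (2, 19),
        ("HE", "M"): (2, 39), ("HE", "F"): (2, 55),
    },
    POSITIVE_BAND: {
        ("LE", "M"): (11, 48), ("LE", "F"): (16, 50),
        ("RB", "M"): (10, 20), ("RB", "F"): (8, 19),
        ("HE", "M"): (11, 39), ("HE", "F"): (12, 55),
    },
}

LINE_ORDER = ("LE", "RB", "HE")


def incidence_by_line(band: str, sex: str | None = None) -> pd.DataFrame:
    """Vocalizer / non-vocalizer counts by breeding line (optionally one sex)."""
    cells = VOCALIZER_INCIDENCE[band]
    rows = {}
    for line in LINE_ORDER:
        voc = tot = 0
        for s in ("M", "F"):
            if sex is not None and s != sex:
                continue
            v, n = cells[(line, s)]
            voc, tot = voc + v, tot + n
        rows[line] = {"vocalizer": voc, "non_vocalizer": tot - voc}
    return pd.DataFrame.from_dict(rows, orient="index")


def incidence_by_sex(band: str) -> pd.DataFrame:
    """Vocalizer / non-vocalizer counts by sex, lines pooled."""
    cells = VOCALIZER_INCIDENCE[band]
    rows = {}
    for s in ("M", "F"):
        voc = sum(cells[(line, s)][0] for line in LINE_ORDER)
        tot = sum(cells[(line, s)][1] for line in LINE_ORDER)
        rows[s] = {"vocalizer": voc, "non_vocalizer": tot - voc}
    return pd.DataFrame.from_dict(rows, orient="index")
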