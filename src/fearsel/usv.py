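"""Ultrasonic-vocalization classification and shock-reactivity metrics.

Detected calls (onset, duration, peak frequency, peak amplitude) are sorted
into two affect bands — long 18-32 kHz calls indexing negative affect and
short 32-96 kHz calls indexing positive affect — and into windows relative to
the tone CS schedule (20 s before, during, and 20 s after each tone).  A
subject is a vocalizer for a band if it emitted at least one band-qualifying
call during the acquisition or extinction session.  Shock reactivity is the
change in broadband sound level from the second before to the second after
foot-shock onset.

The 32 kHz boundary belongs to the upper band ([18, 32) vs [32, 96) kHz) so
the two bands partition the frequency axis; duration gates are inclusive at
both ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NEGATIVE_BAND = "negative_18_32"
POSITIVE_BAND = "positive_32_96"
REJECTED = "rejected"

#: (freq_lo_khz, freq_hi_khz, dur_lo_ms, dur_hi_ms); frequency intervals are
#: half-open at the upper edge, duration gates closed at both ends
BAND_GATES = {
    NEGATIVE_BAND: (18.0, 32.0, 300.0, 4000.0),
    POSITIVE_BAND: (32.0, 96.0, 30.0, 50.0),
}

#: sessions that count toward vocalizer status
VOCALIZER_SESSIONS = ("acquisition", "extinction")


class MissingDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Band classification
# ---------------------------------------------------------------------------


def classify_call(peak_freq_khz: float, duration_ms: float) -> str:
    """Assign one call to an affect band, or reject it.

    Negative band: peak frequency in [18, 32) kHz and duration in
    [300, 4000] ms.  Positive band: [32, 96) kHz and [30, 50] ms.  Calls
    outside both gates (including 18-32 kHz calls shorter than 300 ms) are
    rejected.
    """
    for band, (flo, fhi, dlo, dhi) in BAND_GATES.items():
        if flo <= peak_freq_khz < fhi and dlo <= duration_ms <= dhi:
            return band
    return REJECTED


def classify_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Vectorized band classification; returns a copy with a ``band`` column."""
    out = calls.copy()
    band = np.full(len(out), REJECTED, dtype=object)
    f = out["peak_freq_khz"].to_numpy(float)
    d = out["duration_ms"].to_numpy(float)
    for name, (flo, fhi, dlo, dhi) in BAND_GATES.items():
        band[(f >= flo) & (f < fhi) & (d >= dlo) & (d <= dhi)] = name
    out["band"] = band
    return out


# ---------------------------------------------------------------------------
# CS windows
# ---------------------------------------------------------------------------


@dataclass
class CSSchedule:
    """Tone-CS presentation times within one session.

    ``onsets`` are tone onsets in seconds from session start; every tone has
    the same duration (20 s by default) and is flanked by a 20-s pre-CS and
    post-CS analysis window.
    """

    onsets: np.ndarray
    tone_s: float = 20.0
    margin_s: float = 20.0

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, float)
        if self.onsets.ndim != 1 or len(self.onsets) == 0:
            raise ValueError("schedule requires at least one tone onset")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("tone onsets must be strictly increasing")
        gaps = np.diff(self.onsets)
        if np.any(gaps < self.tone_s + 2 * self.margin_s):
            warnings.warn(
                "adjacent CS analysis windows overlap; earlier tone wins",
                stacklevel=2,
            )


def window_call(onset_s: float, schedule: CSSchedule) -> str:
    """Label a call onset as pre_cs / cs / post_cs / outside.

    Windows are half-open: pre_cs = [t-20, t), cs = [t, t+tone), post_cs =
    [t+tone, t+tone+20).  When windows from adjacent tones overlap, the
    earlier tone's window takes the call.
    """
    for t in schedule.onsets:
        if onset_s < t - schedule.margin_s:
            break  # onsets sorted; no later tone can claim it
        if t - schedule.margin_s <= onset_s < t:
            return "pre_cs"
        if t <= onset_s < t + schedule.tone_s:
            return "cs"
        if t + schedule.tone_s <= onset_s < t + schedule.tone_s + schedule.margin_s:
            return "post_cs"
    return "outside"


def window_calls(calls: pd.DataFrame, schedules: dict[str, CSSchedule]) -> pd.DataFrame:
    """Window every call against its session's schedule (``window`` column).

    ``schedules`` maps session name to :class:`CSSchedule`; calls from
    sessions without a schedule are labeled ``outside``.
    """
    out = calls.copy()
    win = []
    for sess, onset in zip(out["session"], out["onset_s"]):
        sched = schedules.get(sess)
        win.append("outside" if sched is None else window_call(float(onset), sched))
    out["window"] = win
    return out


# ---------------------------------------------------------------------------
# Vocalizer status and incidence
# ---------------------------------------------------------------------------


def classify_vocalizer(
    calls: pd.DataFrame,
    band: str,
    sessions: tuple[str, ...] = VOCALIZER_SESSIONS,
) -> bool:
    """True if one subject's calls include a band call in a counted session.

    Every band-classified call already meets the band's minimum duration, so
    a single qualifying call makes the subject a vocalizer.  Calls restricted
    to the recall session do not count.
    """
    if len(calls) == 0:
        return False
    if "band" not in calls.columns:
        calls = classify_calls(calls)
    mask = (calls["band"] == band) & calls["session"].isin(sessions)
    return bool(mask.any())


def vocalizer_flags(
    calls: pd.DataFrame,
    subjects: pd.DataFrame,
    bands: tuple[str, ...] = (NEGATIVE_BAND, POSITIVE_BAND),
) -> pd.DataFrame:
    """Per-subject vocalizer flags for each band.

    Returns ``subjects`` (id, sex, line) with one boolean column per band;
    subjects absent from the call table are non-vocalizers.
    """
    if "band" not in calls.columns:
        calls = classify_calls(calls)
    counted = calls[calls["session"].isin(VOCALIZER_SESSIONS)]
    out = subjects[["id", "sex", "line"]].copy()
    for band in bands:
        ids = set(counted.loc[counted["band"] == band, "subject_id"])
        out[band] = out["id"].isin(ids)
    return out


def incidence_table(
    flags: pd.DataFrame,
    band: str,
    group_by: list[str] | str = "line",
) -> pd.DataFrame:
    """Vocalizer / non-vocalizer counts per stratum, ready for a chi-square.

    Rows are strata (e.g. breeding lines), columns ``vocalizer`` and
    ``non_vocalizer``.  Empty strata present in the data are retained with
    zero counts (a degenerate margin is then the chi-square's problem, with a
    warning here).
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    g = flags.groupby(group_by, observed=True)[band]
    tab = pd.DataFrame({"vocalizer": g.sum().astype(int), "non_vocalizer": (~flags[band]).groupby(
        [flags[c] for c in group_by], observed=True).sum().astype(int)})
    if (tab.sum(axis=1) == 0).any():
        warnings.warn("incidence table contains an empty stratum", stacklevel=2)
    return tab


# ---------------------------------------------------------------------------
# Shock reactivity
# ---------------------------------------------------------------------------


@dataclass
class ShockReactivity:
    subject_id: str
    db_before: float
    db_after: float
    delta_db: float = field(init=False)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.db_before) and np.isfinite(self.db_after)):
            raise MissingDataError(
                f"subject {self.subject_id}: non-finite shock-window sound level"
            )
        self.delta_db = self.db_after - self.db_before


def shock_reactivity(
    subject_id: str,
    levels_before,
    levels_after,
    aggregate: str = "first",
) -> ShockReactivity:
    """Shock-evoked sound-energy change (dB) for one subject.

    ``levels_before`` / ``levels_after`` hold the sound level in the 1 s
    before and after each foot-shock onset (typically 3 shocks).  The
    per-subject value uses the first shock by default; ``aggregate`` may also
    be ``mean`` or ``max`` over shocks (applied to the per-shock deltas).
    """
    before = np.atleast_1d(np.asarray(levels_before, float))
    after = np.atleast_1d(np.asarray(levels_after, float))
    if before.shape != after.shape or before.size == 0:
        raise MissingDataError(f"subject {subject_id}: mismatched or empty shock windows")
    if not (np.all(np.isfinite(before)) and np.all(np.isfinite(after))):
        raise MissingDataError(f"subject {subject_id}: non-finite shock-window sound level")
    deltas = after - before
    if aggregate == "first":
        i = 0
        return ShockReactivity(subject_id, float(before[i]), float(after[i]))
    if aggregate == "mean":
        return ShockReactivity(subject_id, float(before.mean()), float(before.mean() + deltas.mean()))
    if aggregate == "max":
        i = int(np.argmax(deltas))
        return ShockReactivity(subject_id, float(before[i]), float(after[i]))
    raise ValueError(f"unknown aggregate: {aggregate!r}")
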