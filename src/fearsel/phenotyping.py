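"""Phenotype scores and discrete extinguisher types from trial-level freezing.

Two summary scores per subject, both medians of three trials:

* **post-acquisition freezing** — median of the first 3 trials of the
  extinction session, which double as the 24-h fear-recall measure (there is
  no separate recall session between conditioning and extinction);
* **post-extinction freezing** — median of the 3 recall trials run 24 h
  after extinction.

Discrete types use 2-of-3 trial rules with inclusive thresholds ("75 % or
more", "25 % or less"): robust acquisition requires at least 2 of extinction
trials 1-3 at or above the high threshold; robust extinction at least 2 of
the 3 recall trials at or below the low threshold; negligible extinction at
least 2 recall trials at or above the high threshold.  A high extinguisher
(HE) shows robust acquisition and robust extinction; a low extinguisher (LE)
robust acquisition and negligible extinction; subjects with robust
acquisition but neither recall pattern are ``intermediate`` (a residual
class), and subjects without robust acquisition are ``non_robust``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

HE_TYPE = "HE_type"
LE_TYPE = "LE_type"
INTERMEDIATE = "intermediate"
NON_ROBUST = "non_robust"
PHENOTYPE_TYPES = (HE_TYPE, LE_TYPE, INTERMEDIATE, NON_ROBUST)

DEFAULT_HIGH = 75.0
DEFAULT_LOW = 25.0


class MissingDataError(ValueError):
    pass


def _first3_and_recall(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    ext = trials[trials["session"] == "extinction"].sort_values("trial_index")
    rec = trials[trials["session"] == "recall"].sort_values("trial_index")
    subject = trials["subject_id"].iloc[0] if len(trials) else "<unknown>"
    if len(ext) == 0 or len(rec) == 0:
        raise MissingDataError(
            f"subject {subject}: needs at least one extinction and one recall trial"
        )
    first3 = ext["freezing_pct"].to_numpy(float)[:3]
    recall = rec["freezing_pct"].to_numpy(float)[:3]
    if len(first3) < 3 or len(recall) < 3:
        warnings.warn(
            f"subject {subject}: fewer than 3 extinction or recall trials; "
            "using the median of what exists",
            stacklevel=3,
        )
    return first3, recall


def summarize_freezing(trials: pd.DataFrame) -> tuple[float, float]:
    """(post_acq_pct, post_ext_pct) for one subject's trials.

    The median of an even number of values is the mean of the two central
    values.  Raises :class:`MissingDataError` if the subject has no
    extinction or no recall trials.
    """
    first3, recall = _first3_and_recall(trials)
    return float(np.median(first3)), float(np.median(recall))


def classify_from_scores(
    first3,
    recall,
    high_thresh: float = DEFAULT_HIGH,
    low_thresh: float = DEFAULT_LOW,
) -> str:
    """Type from the raw trial vectors (first 3 extinction trials, 3 recall).

    The array-level core of :func:`classify_phenotype`, usable without a
    trials table.  Thresholds are inclusive on both sides.
    """
    first3 = np.asarray(first3, float)
    recall = np.asarray(recall, float)
    robust_acq = int(np.sum(first3 >= high_thresh)) >= 2
    robust_ext = int(np.sum(recall <= low_thresh)) >= 2
    negligible_ext = int(np.sum(recall >= high_thresh)) >= 2
    if not robust_acq:
        return NON_ROBUST
    if robust_ext:
        return HE_TYPE
    if negligible_ext:
        return LE_TYPE
    return INTERMEDIATE


def classify_phenotype(
    trials: pd.DataFrame,
    high_thresh: float = DEFAULT_HIGH,
    low_thresh: float = DEFAULT_LOW,
) -> str:
    """Discrete extinguisher type for one subject's trials."""
    first3, recall = _first3_and_recall(trials)
    return classify_from_scores(first3, recall, high_thresh, low_thresh)


def score_subjects(
    trials: pd.DataFrame,
    subjects: pd.DataFrame | None = None,
    high_thresh: float = DEFAULT_HIGH,
    low_thresh: float = DEFAULT_LOW,
) -> pd.DataFrame:
    """Per-subject scores and types from a full trials table.

    Returns one row per subject with ``post_acq_pct``, ``post_ext_pct`` and
    ``phenotype_type``; if ``subjects`` is given, the columns are appended to
    it (matched on ``id``), keeping only subjects that have trials.
    """
    recs = []
    for sid, sub in trials.groupby("subject_id", sort=False):
        post_acq, post_ext = summarize_freezing(sub)
        recs.append({
            "subject_id": sid,
            "post_acq_pct": post_acq,
            "post_ext_pct": post_ext,
            "phenotype_type": classify_phenotype(sub, high_thresh, low_thresh),
        })
    scored = pd.DataFrame(recs)
    if subjects is None:
        return scored
    stale = [c for c in ("post_acq_pct", "post_ext_pct", "phenotype_type")
             if c in subjects.columns]
    out = subjects.drop(columns=stale).merge(
        scored, left_on="id", right_on="subject_id", how="inner")
    return out.drop(columns=["subject_id"])


def phenotype_census(
    subjects: pd.DataFrame,
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Counts and proportions of each phenotype type, by stratum.

    ``by`` defaults to ``["line", "sex"]`` (restricted to columns actually
    present).  Within each stratum the four type proportions sum to 1 and the
    counts sum to the stratum size.
    """
    if "phenotype_type" not in subjects.columns:
        raise ValueError("subjects must carry a phenotype_type column; run score_subjects")
    if by is None:
        by = [c for c in ("line", "sex") if c in subjects.columns]
    ptype = pd.Categorical(subjects["phenotype_type"], categories=PHENOTYPE_TYPES)
    frame = subjects.assign(phenotype_type=ptype)
    if by:
        counts = (frame.groupby(by, observed=True)["phenotype_type"]
                  .value_counts().unstack(fill_value=0))
    else:
        counts = subjects["phenotype_type"].value_counts().reindex(
            PHENOTYPE_TYPES, fill_value=0).to_frame().T
        counts.index = ["all"]
    counts = counts.reindex(columns=PHENOTYPE_TYPES, fill_value=0)
    n = counts.sum(axis=1)
    out = counts.copy()
    out.columns = [f"n_{c}" for c in counts.columns]
    out["n_total"] = n
    for c in PHENOTYPE_TYPES:
        out[f"prop_{c}"] = counts[c] / n
    return out.reset_index()
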