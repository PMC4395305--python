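"""Scoring of letter 2-back sessions: trial classification, d', RT controls.

A trial log has one row per presented letter with the participant's
response ("match", "nonmatch", or "none" for an omission) and RT in ms.
Trials 1 and 2 are never scoreable (there is no letter two back).  From
trial 3 on, signal-detection counts are accumulated:

    target + "match"              -> hit
    target + "nonmatch"/"none"    -> miss
    non-target + "match"          -> false alarm
    non-target + "nonmatch"/"none"-> correct rejection

Sensitivity is d' = z(H) - z(FA) with H the hit rate and FA the
false-alarm rate; rates of exactly 0 or 1 are adjusted by the 1/(2N) rule
by default so the normal quantile is finite.  The speed control is the
mean RT on correct responded trials after a single-pass exclusion of RTs
beyond 3 SD from their mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SdtCounts",
    "classify_trials",
    "dprime",
    "mean_correct_rt",
    "score_session",
]

REQUIRED_COLUMNS = ("letter", "is_target", "response")
VALID_RESPONSES = ("match", "nonmatch", "none")


@dataclass
class SdtCounts:
    """Signal-detection counts over the scoreable trials of one session."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_targets(self) -> int:
        return self.hits + self.misses

    @property
    def n_nontargets(self) -> int:
        return self.false_alarms + self.correct_rejections


def _validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    if len(trials) < 3:
        raise ValueError("need at least 3 trials (first two are unscoreable)")
    bad = set(trials["response"]) - set(VALID_RESPONSES)
    if bad:
        raise ValueError(f"unknown response values: {sorted(bad)}")
    letters = trials["letter"].to_numpy()
    flagged = trials["is_target"].to_numpy(dtype=bool)
    expected = np.zeros(len(trials), dtype=bool)
    expected[2:] = letters[2:] == letters[:-2]
    if not np.array_equal(flagged, expected):
        rows = np.flatnonzero(flagged != expected) + 1
        raise ValueError(
            f"is_target inconsistent with the letter sequence at trial(s) "
            f"{rows.tolist()} (1-based)"
        )
    return trials


def classify_trials(trials: pd.DataFrame) -> SdtCounts:
    """Accumulate hits/misses/false alarms/correct rejections (trials >= 3)."""
    trials = _validate_trials(trials)
    scoreable = trials.iloc[2:]
    target = scoreable["is_target"].to_numpy(dtype=bool)
    match = scoreable["response"].to_numpy() == "match"
    return SdtCounts(
        hits=int(np.sum(target & match)),
        misses=int(np.sum(target & ~match)),
        false_alarms=int(np.sum(~target & match)),
        correct_rejections=int(np.sum(~target & ~match)),
    )


def dprime(counts: SdtCounts, correction: str = "half_count") -> float:
    """Signal-detection sensitivity d' = z(H) - z(FA).

    ``correction`` handles rates of exactly 0 or 1 (which have infinite
    normal quantiles):

    * ``"half_count"`` (default): 0 -> 1/(2N), 1 -> 1 - 1/(2N), with N
      the number of trials of that type.
    * ``"none"``: no adjustment; extreme rates yield +-inf.
    """
    if counts.n_targets < 1 or counts.n_nontargets < 1:
        raise ValueError("need at least one target and one non-target trial")
    h = counts.hits / counts.n_targets
    fa = counts.false_alarms / counts.n_nontargets
    if correction == "half_count":
        h = min(max(h, 1.0 / (2 * counts.n_targets)), 1.0 - 1.0 / (2 * counts.n_targets))
        fa = min(
            max(fa, 1.0 / (2 * counts.n_nontargets)),
            1.0 - 1.0 / (2 * counts.n_nontargets),
        )
    elif correction != "none":
        raise ValueError(f"unknown rate-correction policy {correction!r}")
    return float(norm.ppf(h) - norm.ppf(fa))


def _correct_responded(trials: pd.DataFrame) -> pd.DataFrame:
    """Scoreable trials answered correctly with an explicit response."""
    scoreable = trials.iloc[2:]
    target = scoreable["is_target"].to_numpy(dtype=bool)
    resp = scoreable["response"].to_numpy()
    correct = (target & (resp == "match")) | (~target & (resp == "nonmatch"))
    out = scoreable[correct]
    return out[out["rt_ms"].notna()] if "rt_ms" in out.columns else out.iloc[0:0]


def mean_correct_rt(trials: pd.DataFrame) -> float:
    """Mean RT (ms) on correct trials after one-pass +-3 SD exclusion."""
    trials = _validate_trials(trials)
    rts = _correct_responded(trials)["rt_ms"].to_numpy(dtype=float)
    if rts.size == 0:
        raise ValueError("no correct responded trials with an RT")
    m = rts.mean()
    sd = rts.std(ddof=1) if rts.size > 1 else 0.0
    keep = np.abs(rts - m) <= 3.0 * sd if sd > 0 else np.ones(rts.size, dtype=bool)
    return float(rts[keep].mean())


def score_session(trials: pd.DataFrame, correction: str = "half_count") -> dict:
    """Full per-session summary: SDT counts, d', RT control.

    Returns a JSON-ready dict with keys ``hits``, ``misses``, ``fa``,
    ``cr``, ``dprime``, ``mean_rt``, ``n_excluded_rt``.
    """
    counts = classify_trials(trials)
    rts = _correct_responded(trials)["rt_ms"].to_numpy(dtype=float)
    mean_rt = mean_correct_rt(trials)
    if rts.size > 1 and rts.std(ddof=1) > 0:
        n_excl = int(np.sum(np.abs(rts - rts.mean()) > 3.0 * rts.std(ddof=1)))
    else:
        n_excl = 0
    return {
        "hits": counts.hits,
        "misses": counts.misses,
        "fa": counts.false_alarms,
        "cr": counts.correct_rejections,
        "dprime": dprime(counts, correction=correction),
        "mean_rt": mean_rt,
        "n_excluded_rt": n_excl,
    }
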