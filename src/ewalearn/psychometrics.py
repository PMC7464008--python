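"""Interoception and questionnaire scoring.

Covers the three participant-level measurement channels:

* heartbeat counting (Schandry task) — interoceptive *awareness*, the
  accuracy of counting one's own heartbeats over timed intervals;
* probe detection — interoceptive *attention*, the reaction-time advantage
  for an internal (vibrotactile) probe over an external (visual) probe,
  computed after iterative Smirnov-Grubbs outlier removal;
* self-report questionnaires (CES-D, DAMS-D, PANAS) — totals with
  reverse-keying, plus Cronbach's alpha internal-consistency reliability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HeartbeatTrial",
    "ProbeTrial",
    "ParticipantProfile",
    "heartbeat_score",
    "arcsine_transform",
    "grubbs_critical_value",
    "grubbs_filter",
    "interoceptive_attention",
    "score_questionnaire",
    "cronbach_alpha",
]


@dataclass(frozen=True)
class HeartbeatTrial:
    """One heartbeat-counting trial: timed interval, actual and reported counts."""

    duration: float
    actual_beats: int
    reported_beats: int

    def __post_init__(self) -> None:
        if self.actual_beats <= 0:
            raise ValueError("actual_beats must be positive")
        if self.reported_beats < 0:
            raise ValueError("reported_beats must be non-negative")


@dataclass(frozen=True)
class ProbeTrial:
    """One probe-detection trial."""

    probe_type: str  # 'internal' or 'external'
    rt: float  # reaction time, seconds
    emotion_block: str = "neutrality"
    soa: float = 3.0  # probe onset asynchrony, seconds

    def __post_init__(self) -> None:
        if self.probe_type not in ("internal", "external"):
            raise ValueError(f"unknown probe type {self.probe_type!r}")
        if self.rt <= 0:
            raise ValueError("reaction time must be positive")


@dataclass
class ParticipantProfile:
    """Questionnaire totals, interoception scores and group label."""

    participant_id: str
    group: str  # 'experimental' or 'control'
    ces_d: int
    dams_d: int
    panas_pa: int
    panas_na: int
    awareness: float
    attention: float
    age: float = float("nan")
    gender: str = "unknown"


def heartbeat_score(trials: Sequence[HeartbeatTrial], raw: bool = False) -> float:
    """Heartbeat-counting accuracy index.

    Default is the Schandry accuracy score, the mean over trials of
    ``1 - |actual - reported| / actual``: 1 for perfect counting, lower as
    the miscount grows, and possibly negative when the report overshoots
    past twice the actual count (not clipped here). ``raw=True`` instead
    returns the plain summed signed relative gap
    ``sum((actual - reported) / actual)``.
    """
    if not trials:
        raise ValueError("heartbeat_score requires at least one trial")
    if raw:
        return float(sum((t.actual_beats - t.reported_beats) / t.actual_beats for t in trials))
    return float(
        np.mean(
            [1.0 - abs(t.actual_beats - t.reported_beats) / t.actual_beats for t in trials]
        )
    )


def arcsine_transform(p: float) -> float:
    """Variance-stabilising arcsine-square-root transform for proportions.

    Values outside [0, 1] are clipped with a warning before transforming.
    """
    if p < 0.0 or p > 1.0:
        warnings.warn(
            f"proportion {p} outside [0, 1]; clipping before arcsine transform",
            stacklevel=2,
        )
        p = min(max(p, 0.0), 1.0)
    return math.asin(math.sqrt(p))


def grubbs_critical_value(n: int, significance: float = 0.05) -> float:
    """Two-sided critical value of the Grubbs statistic for sample size n."""
    if n < 3:
        return math.inf
    t_crit = stats.t.ppf(1.0 - significance / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t_crit**2 / (n - 2 + t_crit**2))


def grubbs_filter(
    values: Iterable[float], significance: float = 0.05
) -> list[float]:
    """Iterative two-sided Smirnov-Grubbs outlier removal.

    Repeatedly removes the single most extreme value while the Grubbs
    statistic ``G = max|x - mean| / sd`` exceeds its critical value at the
    given significance level. The surviving values keep their input order.
    Samples with fewer than 3 values, or zero standard deviation, are
    returned unchanged.
    """
    vals = list(values)
    keep = list(range(len(vals)))
    while len(keep) >= 3:
        x = np.array([vals[i] for i in keep])
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - x.mean())
        g = dev.max() / sd
        if g <= grubbs_critical_value(len(keep), significance):
            break
        keep.pop(int(dev.argmax()))
    return [vals[i] for i in keep]


def interoceptive_attention(
    trials: Sequence[ProbeTrial], significance: float = 0.05
) -> float:
    """Interoceptive attention score in seconds.

    Grubbs-filters reaction times within each probe type, then returns
    mean(external RT) - mean(internal RT); positive values mean faster
    responses to the internal probe.
    """
    internal = [t.rt for t in trials if t.probe_type == "internal"]
    external = [t.rt for t in trials if t.probe_type == "external"]
    if not internal or not external:
        raise ValueError("need at least one trial of each probe type")
    internal = grubbs_filter(internal, significance)
    external = grubbs_filter(external, significance)
    if not internal or not external:
        raise ValueError("a probe type was emptied by outlier filtering")
    return float(np.mean(external) - np.mean(internal))


def score_questionnaire(
    items: Sequence[int],
    reverse_keys: Iterable[int] = (),
    item_range: tuple[int, int] = (1, 7),
) -> int:
    """Questionnaire total with reverse-keying.

    Reverse-keyed items (0-based indices) are mapped ``x -> min + max - x``
    before summation. Out-of-range responses raise with the item index.
    """
    lo, hi = item_range
    reverse = set(reverse_keys)
    total = 0
    for i, x in enumerate(items):
        if not lo <= x <= hi:
            raise ValueError(f"item {i}: response {x} outside range [{lo}, {hi}]")
        total += (lo + hi - x) if i in reverse else x
    return total


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha internal-consistency reliability.

    ``item_matrix`` is participants x items. Uses the standard
    ``(k/(k-1)) * (1 - sum(item variances) / variance(totals))`` form via
    pingouin; raises on degenerate (zero total-variance) input.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 participants and 2 items")
    if x.sum(axis=1).var(ddof=1) == 0:
        raise ValueError("zero variance of totals: alpha undefined")
    import pingouin  # deferred: heavy import

    alpha, _ = pingouin.cronbach_alpha(data=pd.DataFrame(x))
    return float(alpha)
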