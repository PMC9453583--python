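"""Social-contact features from smartphone call logs.

Five per-window features: total number of calls (numCalls), summed call
duration (durCalls) and its SD (durCalls_std), summed call-free time
(durNoCalls) and the SD of the call-free gaps (durNoCalls_std). Call-free
time is edge-inclusive: the gap from the window start to the first call and
from the last call's end to the window end are part of the gap list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SOCIAL_FEATURE_NAMES = ("numCalls", "durCalls", "durCalls_std", "durNoCalls", "durNoCalls_std")

CALL_DIRECTIONS = ("incoming", "outgoing")


@dataclass
class SocialFeatures:
    numCalls: float
    durCalls: float
    durCalls_std: float
    durNoCalls: float
    durNoCalls_std: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in SOCIAL_FEATURE_NAMES}


def _sample_sd(x: np.ndarray) -> float:
    # sample (n-1) SD; a single element (or none) has SD 0 by convention
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def social_features(calls: pd.DataFrame, start_s: float, end_s: float) -> SocialFeatures:
    """Compute the call features for one window.

    ``calls`` needs columns ``start`` (s) and ``duration_s``. A call belongs to
    the window iff its start lies in [start_s, end_s); durations are not
    truncated at the boundary. Overlapping calls (call waiting) produce
    negative inter-call gaps, floored at 0.
    """
    if end_s <= start_s:
        raise ValueError("window must have positive length")
    window_len = end_s - start_s
    if len(calls) == 0:
        return SocialFeatures(0.0, 0.0, 0.0, window_len, 0.0)
    starts = np.asarray(calls["start"], dtype=float)
    durations = np.asarray(calls["duration_s"], dtype=float)
    order = np.argsort(starts, kind="stable")
    starts, durations = starts[order], durations[order]
    in_win = (starts >= start_s) & (starts < end_s)
    starts, durations = starts[in_win], durations[in_win]
    if starts.size == 0:
        return SocialFeatures(0.0, 0.0, 0.0, window_len, 0.0)

    ends = starts + durations
    gaps = np.empty(starts.size + 1)
    gaps[0] = starts[0] - start_s
    gaps[1:-1] = starts[1:] - ends[:-1]
    gaps[-1] = end_s - ends[-1]
    gaps = np.maximum(gaps, 0.0)

    return SocialFeatures(
        numCalls=float(starts.size),
        durCalls=float(durations.sum()),
        durCalls_std=_sample_sd(durations),
        durNoCalls=float(gaps.sum()),
        durNoCalls_std=_sample_sd(gaps),
    )
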