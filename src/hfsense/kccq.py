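"""KCCQ-12 scoring and windowed active features.

The KCCQ-12 has four domains (physical limitation, symptom frequency,
quality of life, social limitation), each scored 0-100, lower = worse; the
summary score is the mean of the available domains (a summary <= 25
corresponds to NYHA class IV). Per analysis window the feature block is
either the summary score (KCCQ12_sum) or the four domain scores
(KCCQ12_all), aggregated as the mean of all in-window surveys or the most
recent in-window survey.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

KCCQ_DOMAINS = ("phys", "symp", "qol", "social")

AGGREGATION_MODES = ("mean_of_window", "most_recent")
FEATURE_SETS = ("sum", "all")


def summary_score(domains) -> float:
    """Mean of the available (non-NaN) domain scores."""
    values = np.asarray(domains, dtype=float)
    if np.all(np.isnan(values)):
        raise ValueError("cannot score a response with all domains missing")
    if np.nanmin(values) < 0 or np.nanmax(values) > 100:
        raise ValueError("domain scores must lie in [0, 100]")
    return float(np.nanmean(values))


def kccq_features(
    responses: pd.DataFrame,
    start_s: float,
    end_s: float,
    mode: str = "most_recent",
    feature_set: str = "sum",
) -> dict[str, float] | None:
    """Windowed KCCQ feature block; None when no in-window response exists.

    ``responses`` needs column ``t`` (s) plus the four domain columns with NaN
    for missing domains. In ``mean_of_window`` mode the summary (or each
    domain) is averaged over all in-window responses; ``most_recent`` uses
    only the latest in-window response.
    """
    if end_s <= start_s:
        raise ValueError("window must have positive length")
    if mode not in AGGREGATION_MODES:
        raise ValueError(f"mode must be one of {AGGREGATION_MODES}")
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    t = np.asarray(responses["t"], dtype=float)
    mask = (t >= start_s) & (t < end_s)
    if not np.any(mask):
        return None
    window = responses.loc[mask]
    domain_matrix = window[list(KCCQ_DOMAINS)].to_numpy(dtype=float)
    scorable = ~np.all(np.isnan(domain_matrix), axis=1)
    if not np.any(scorable):
        return None
    window = window.loc[scorable]
    domain_matrix = domain_matrix[scorable]

    if mode == "most_recent":
        idx = int(np.argmax(window["t"].to_numpy(dtype=float)))
        row = domain_matrix[idx]
        if feature_set == "sum":
            return {"KCCQ12_sum": summary_score(row)}
        return {d: float(row[i]) for i, d in enumerate(KCCQ_DOMAINS)}

    if feature_set == "sum":
        summaries = [summary_score(r) for r in domain_matrix]
        return {"KCCQ12_sum": float(np.mean(summaries))}
    with np.errstate(invalid="ignore"):
        means = np.nanmean(domain_matrix, axis=0)
    return {d: float(means[i]) for i, d in enumerate(KCCQ_DOMAINS)}


def kccq_feature_names(feature_set: str = "sum") -> tuple[str, ...]:
    return ("KCCQ12_sum",) if feature_set == "sum" else KCCQ_DOMAINS
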