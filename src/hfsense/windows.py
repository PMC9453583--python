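"""Labeled pre-event windows and the multimodality feature table.

Each clinical encounter (compensated = 0, decompensated = 1) yields one
N-day window ending ``lead_days`` before the event's local midnight; the
four modality blocks (motion, social, location, kccq) are extracted per
window, with per-modality missing-data rules applied, and fused analyses
keep only complete cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import actigraphy, geolocation, kccq, social
from .actigraphy import SECONDS_PER_DAY

MODALITIES = ("motion", "social", "location", "kccq")

LABEL_NAMES = {0: "comp", 1: "decomp"}
LABEL_CODES = {"comp": 0, "decomp": 1}


@dataclass
class EventWindow:
    """An N-day analysis window preceding one clinical event.

    ``end_s`` sits ``lead_days`` whole days before the event's midnight;
    ``start_s`` is ``n_days`` before that (possibly truncated at enrollment).
    """

    participant_id: str
    event_day: int
    label: int
    n_days: int
    lead_days: int
    start_s: float
    end_s: float


def build_windows(
    events: pd.DataFrame,
    n_days: int = 14,
    lead_days: int = 0,
    enroll_start_s: float = 0.0,
) -> list[EventWindow]:
    """One window per event row (columns participant_id, day, label).

    Windows that would extend before enrollment are truncated with a warning.
    Overlapping windows from closely spaced events are allowed.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if lead_days < 0:
        raise ValueError("lead_days must be >= 0")
    out: list[EventWindow] = []
    truncated = 0
    for row in events.itertuples(index=False):
        end_s = (int(row.day) - lead_days) * float(SECONDS_PER_DAY)
        start_s = end_s - n_days * float(SECONDS_PER_DAY)
        if start_s < enroll_start_s:
            start_s = enroll_start_s
            truncated += 1
        if end_s <= start_s:
            continue
        out.append(
            EventWindow(str(row.participant_id), int(row.day), int(row.label), n_days, lead_days, start_s, end_s)
        )
    if truncated:
        warnings.warn(f"{truncated} window(s) truncated at enrollment start", stacklevel=2)
    return out


def modality_columns(
    modalities=MODALITIES, kccq_feature_set: str = "sum"
) -> dict[str, list[str]]:
    """Prefixed feature-column names per modality (e.g. ``social.numCalls``)."""
    names = {
        "motion": actigraphy.MOTION_FEATURE_NAMES,
        "social": social.SOCIAL_FEATURE_NAMES,
        "location": geolocation.LOCATION_FEATURE_NAMES,
        "kccq": kccq.kccq_feature_names(kccq_feature_set),
    }
    return {m: [f"{m}.{n}" for n in names[m]] for m in modalities}


def assemble_dataset(
    cohort,
    windows: list[EventWindow],
    modalities=MODALITIES,
    kccq_mode: str = "most_recent",
    kccq_feature_set: str = "sum",
) -> pd.DataFrame:
    """Feature table with one row per window.

    ``cohort`` must expose ``motion_counts`` (participant -> EpochCountSeries),
    and DataFrames ``calls``, ``locations``, ``kccq`` with a participant_id
    column. Missing modality blocks are NaN with the matching ``has_<m>``
    flag False (motion follows the 0.1% completeness rule; the other blocks
    are missing when the window holds no record).
    """
    modalities = tuple(modalities)
    unknown = set(modalities) - set(MODALITIES)
    if unknown:
        raise ValueError(f"unknown modalities: {sorted(unknown)}")
    cols = modality_columns(modalities, kccq_feature_set)

    by_pid: dict[str, dict[str, pd.DataFrame]] = {}

    def _per_pid(df: pd.DataFrame, pid: str) -> pd.DataFrame:
        return df.loc[df["participant_id"] == pid]

    homes: dict[str, geolocation.HomeLocation | None] = {}
    rows = []
    for w in windows:
        pid = w.participant_id
        if pid not in by_pid:
            by_pid[pid] = {
                "calls": _per_pid(cohort.calls, pid) if "social" in modalities else None,
                "locations": _per_pid(cohort.locations, pid) if "location" in modalities else None,
                "kccq": _per_pid(cohort.kccq, pid) if "kccq" in modalities else None,
            }
        row: dict[str, object] = {
            "participant_id": pid,
            "event_day": w.event_day,
            "label": w.label,
            "n_days": w.n_days,
            "lead_days": w.lead_days,
        }
        if "motion" in modalities:
            series = cohort.motion_counts.get(pid)
            feats = (
                actigraphy.motion_features(series, w.start_s, w.end_s) if series is not None and len(series) else None
            )
            _write_block(row, cols["motion"], feats.as_dict() if feats else None, "motion")
        if "social" in modalities:
            calls = by_pid[pid]["calls"]
            in_win = calls.loc[(calls["start"] >= w.start_s) & (calls["start"] < w.end_s)]
            feats = social.social_features(in_win, w.start_s, w.end_s) if len(in_win) else None
            _write_block(row, cols["social"], feats.as_dict() if feats else None, "social")
        if "location" in modalities:
            fixes = by_pid[pid]["locations"]
            if pid not in homes:
                homes[pid] = geolocation.infer_home(fixes) if len(fixes) else None
            home = homes[pid]
            feats = geolocation.location_features(fixes, home, w.start_s, w.end_s) if home else None
            _write_block(row, cols["location"], feats.as_dict() if feats else None, "location")
        if "kccq" in modalities:
            responses = by_pid[pid]["kccq"]
            feats = (
                kccq.kccq_features(responses, w.start_s, w.end_s, kccq_mode, kccq_feature_set)
                if len(responses)
                else None
            )
            _write_block(row, cols["kccq"], feats, "kccq")
        rows.append(row)
    return pd.DataFrame(rows)


def _write_block(row: dict, columns: list[str], values: dict[str, float] | None, modality: str) -> None:
    row[f"has_{modality}"] = values is not None
    for col in columns:
        bare = col.split(".", 1)[1]
        row[col] = float(values[bare]) if values is not None else np.nan


def filter_complete_cases(
    rows: pd.DataFrame, modalities=MODALITIES
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep rows with every requested modality present.

    Returns the filtered table and the per-modality attrition (rows dropped
    solely for lacking that modality).
    """
    modalities = tuple(modalities)
    keep = np.ones(len(rows), dtype=bool)
    attrition: dict[str, int] = {}
    for m in modalities:
        present = rows[f"has_{m}"].to_numpy(dtype=bool)
        attrition[m] = int(np.sum(~present))
        keep &= present
    return rows.loc[keep].reset_index(drop=True), attrition
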