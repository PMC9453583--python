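"""CSV stream schemas, cohort round-tripping, and the pipeline runner.

All on-disk formats are UTF-8 CSV with a header row and ISO-8601 timestamps
carrying a zone offset; internally, times are seconds since the study start
(midnight UTC), which a ``meta.json`` sidecar records per cohort directory.
Motion is persisted as 30-s epoch counts (the cached product of the
band-pass -> count conversion) rather than raw 5-Hz samples.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import explain as explain_mod
from . import models, synthetic, windows
from .actigraphy import EpochCountSeries

SCHEMAS: dict[str, dict] = {
    "accel": {"columns": ["participant_id", "timestamp_iso", "x_g", "y_g", "z_g"], "time": "timestamp_iso"},
    "epoch_counts": {"columns": ["participant_id", "epoch_start_iso", "count", "present"], "time": "epoch_start_iso"},
    "calls": {"columns": ["participant_id", "contact_hash", "direction", "start_iso", "duration_s"],
              "time": "start_iso"},
    "locations": {"columns": ["participant_id", "timestamp_iso", "lat", "lon"], "time": "timestamp_iso"},
    "kccq": {"columns": ["participant_id", "date_iso", "phys", "symp", "qol", "social"], "time": "date_iso"},
    "events": {"columns": ["participant_id", "date_iso", "label"], "time": "date_iso"},
}

LABEL_TO_CODE = {"comp": 0, "decomp": 1}
CODE_TO_LABEL = {0: "comp", 1: "decomp"}


def _to_iso(t_seconds: np.ndarray, study_start: str) -> pd.Series:
    start = pd.Timestamp(study_start)
    return (start + pd.to_timedelta(np.asarray(t_seconds, dtype=float), unit="s")).map(
        lambda ts: ts.isoformat()
    )


def _from_iso(values: pd.Series, study_start: str, path: str, on_error: str) -> np.ndarray:
    start = pd.Timestamp(study_start)
    parsed = pd.to_datetime(values, utc=True, format="ISO8601", errors="coerce")
    bad = parsed.isna() & values.notna()
    if bad.any():
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())][:5]
        msg = f"{path}: unparseable timestamp(s) at line(s) {lines}"
        if on_error == "raise":
            raise ValueError(msg)
        warnings.warn(msg + " (rows skipped)", stacklevel=3)
    return (parsed - start).dt.total_seconds().to_numpy()


def read_stream(path, schema: str, study_start: str = synthetic.DEFAULT_STUDY_START,
                on_error: str = "raise") -> pd.DataFrame:
    """Read and validate one stream CSV.

    Returns participant-grouped, time-sorted records with the timestamp
    column converted to seconds since ``study_start`` (column ``t``; events
    additionally gain integer ``day`` and binary ``label``). Malformed rows
    raise (or are skipped, per ``on_error``) with their line numbers.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    layout = SCHEMAS[schema]
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(layout["columns"]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    t = _from_iso(df[layout["time"]], study_start, str(path), on_error)
    df = df.assign(t=t)
    bad = df["t"].isna()
    if bad.any():
        df = df.loc[~bad]

    def _lines(mask) -> list[int]:
        return [int(i) + 2 for i in np.flatnonzero(np.asarray(mask))][:5]

    if schema == "locations":
        invalid = (df["lat"].abs() > 90) | (df["lon"].abs() > 180)
        if invalid.any():
            msg = f"{path}: coordinate out of range at line(s) {_lines(invalid)}"
            if on_error == "raise":
                raise ValueError(msg)
            warnings.warn(msg + " (rows skipped)", stacklevel=2)
            df = df.loc[~invalid]
    if schema == "calls" and (df["duration_s"] < 0).any():
        raise ValueError(f"{path}: negative duration at line(s) {_lines(df['duration_s'] < 0)}")
    if schema == "events":
        unknown = ~df["label"].isin(LABEL_TO_CODE)
        if unknown.any():
            raise ValueError(f"{path}: label must be comp/decomp at line(s) {_lines(unknown)}")
        df = df.assign(label=df["label"].map(LABEL_TO_CODE), day=(df["t"] // 86400).astype(int))
    if schema == "kccq":
        for c in ("phys", "symp", "qol", "social"):
            out_of_range = df[c].notna() & ((df[c] < 0) | (df[c] > 100))
            if out_of_range.any():
                raise ValueError(f"{path}: {c} outside [0,100] at line(s) {_lines(out_of_range)}")

    by = ["participant_id", "t"]
    if not df.sort_values(by, kind="stable")["t"].equals(df["t"]):
        grouped = df.groupby("participant_id", sort=False)["t"]
        if (grouped.diff().dropna() < 0).any():
            warnings.warn(f"{path}: out-of-order timestamps; records sorted", stacklevel=2)
    return df.sort_values(by, kind="stable").reset_index(drop=True)


def write_epoch_counts(series_by_pid: dict[str, EpochCountSeries], path,
                       study_start: str = synthetic.DEFAULT_STUDY_START) -> None:
    frames = []
    for pid, s in series_by_pid.items():
        frames.append(pd.DataFrame({
            "participant_id": pid,
            "epoch_start_iso": _to_iso(s.epoch_start, study_start),
            "count": s.count,
            "present": s.present.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_epoch_counts(path, study_start: str = synthetic.DEFAULT_STUDY_START) -> dict[str, EpochCountSeries]:
    df = read_stream(path, "epoch_counts", study_start)
    out = {}
    for pid, g in df.groupby("participant_id", sort=True):
        out[pid] = EpochCountSeries(
            pid, g["t"].to_numpy(), g["count"].to_numpy(dtype=float), g["present"].to_numpy(dtype=bool)
        )
    return out


def write_cohort(cohort: synthetic.Cohort, out_dir) -> Path:
    """Persist every stream of a cohort as CSV plus a meta.json sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    start = cohort.study_start
    write_epoch_counts(cohort.motion_counts, out / "epoch_counts.csv", start)
    calls = cohort.calls.copy()
    calls["start_iso"] = _to_iso(calls.pop("start"), start)
    calls[SCHEMAS["calls"]["columns"]].to_csv(out / "calls.csv", index=False)
    locs = cohort.locations.copy()
    locs["timestamp_iso"] = _to_iso(locs.pop("t"), start)
    locs[SCHEMAS["locations"]["columns"]].to_csv(out / "locations.csv", index=False)
    kccq = cohort.kccq.copy()
    kccq["date_iso"] = _to_iso(kccq.pop("t"), start)
    kccq[SCHEMAS["kccq"]["columns"]].to_csv(out / "kccq.csv", index=False)
    events = cohort.events.copy()
    events["date_iso"] = _to_iso(events.pop("day").to_numpy() * 86400.0, start)
    events["label"] = events["label"].map(CODE_TO_LABEL)
    events[SCHEMAS["events"]["columns"]].to_csv(out / "events.csv", index=False)
    meta = {"study_start": start, "participants": cohort.participants,
            "config": dataclasses.asdict(cohort.config)}
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


def read_cohort(cohort_dir) -> synthetic.Cohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    d = Path(cohort_dir)
    meta = json.loads((d / "meta.json").read_text())
    start = meta["study_start"]
    cfg_dict = dict(meta["config"])
    cfg_dict["effect_sizes"] = synthetic.EffectSizes(**cfg_dict["effect_sizes"])
    config = synthetic.CohortConfig(**cfg_dict)
    calls = read_stream(d / "calls.csv", "calls", start).rename(columns={"t": "start"})
    return synthetic.Cohort(
        config=config,
        participants=list(meta["participants"]),
        events=read_stream(d / "events.csv", "events", start)[["participant_id", "day", "label"]],
        motion_counts=read_epoch_counts(d / "epoch_counts.csv", start),
        calls=calls[["participant_id", "contact_hash", "direction", "start", "duration_s"]],
        locations=read_stream(d / "locations.csv", "locations", start)[["participant_id", "t", "lat", "lon"]],
        kccq=read_stream(d / "kccq.csv", "kccq", start)[["participant_id", "t", "phys", "symp", "qol", "social"]],
        study_start=start,
    )


# ---------------------------------------------------------------------------
# configuration and the full pipeline


def cohort_config_from_dict(d: dict, seed: int | None = None) -> synthetic.CohortConfig:
    d = dict(d or {})
    if "effect_sizes" in d and isinstance(d["effect_sizes"], dict):
        d["effect_sizes"] = synthetic.EffectSizes(**d["effect_sizes"])
    if seed is not None:
        d["seed"] = seed
    return synthetic.CohortConfig(**d)


def model_config_from_dict(d: dict, seed: int | None = None) -> models.ModelConfig:
    d = dict(d or {})
    if "modalities" in d:
        d["modalities"] = tuple(d["modalities"])
    if seed is not None:
        d["base_seed"] = seed
    return models.ModelConfig(**d)


def run_pipeline(config: dict, out_dir, seed: int = 0) -> Path:
    """simulate -> featurize -> train (-> horizon) (-> explain), writing all
    artifacts plus a manifest under ``out_dir``.

    ``config`` holds optional sections ``cohort`` (CohortConfig fields),
    ``models`` (a mapping of run name to ModelConfig fields), ``horizon``
    (leads / mode / model fields) and ``explain`` (bool or field mapping).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = cohort_config_from_dict(config.get("cohort", {}), seed=seed)
    cohort = synthetic.generate_cohort(cohort_cfg)
    write_cohort(cohort, out / "cohort")

    model_sections = config.get("models") or {
        "late_fusion": {"modalities": ["kccq", "motion", "social"], "fusion": "late"}
    }
    metric_rows = []
    feature_tables: dict[tuple[int, int], pd.DataFrame] = {}
    for name, section in model_sections.items():
        mcfg = model_config_from_dict(section, seed=seed)
        key = (mcfg.n_days, mcfg.lead_days)
        if key not in feature_tables:
            wlist = windows.build_windows(cohort.events, *key)
            feature_tables[key] = windows.assemble_dataset(
                cohort, wlist, windows.MODALITIES, mcfg.kccq_mode, mcfg.kccq_feature_set
            )
        complete, _ = windows.filter_complete_cases(feature_tables[key], mcfg.modalities)
        summary = models.repeat_experiment(complete, mcfg)
        for _, row in summary.to_frame().iterrows():
            metric_rows.append({"setting": name, **row.to_dict()})
    if feature_tables:
        next(iter(feature_tables.values())).to_csv(out / "features.csv", index=False)
    pd.DataFrame(metric_rows).to_csv(out / "metrics.csv", index=False)

    if "horizon" in config:
        h = dict(config["horizon"])
        leads = [int(x) for x in h.pop("leads", [1, 2, 4, 6])]
        mode = h.pop("mode", "time_to_event")
        hcfg = model_config_from_dict(h.pop("model", {"modalities": ["social"], "fusion": "single"}), seed=seed)
        rows = []
        for lead, summary in models.horizon_analysis(cohort, hcfg, leads, mode).items():
            for _, row in summary.to_frame().iterrows():
                rows.append({"setting": f"{mode}_{lead}", **row.to_dict()})
        pd.DataFrame(rows).to_csv(out / "horizon.csv", index=False)

    if config.get("explain", True):
        wlist = windows.build_windows(cohort.events, 14, 0)
        table = windows.assemble_dataset(cohort, wlist, windows.MODALITIES)
        expl, ranking, _ = explain_mod.explain_early_fusion(table, seed=seed)
        ranking.to_csv(out / "shap_summary.csv", index=False)
        pd.DataFrame(expl.values, columns=list(expl.feature_names)).assign(
            base_value=expl.base_value
        ).to_csv(out / "shap_values.csv", index=False)

    import sklearn

    manifest = {
        "seed": seed,
        "config": json.loads(json.dumps(config, default=str)),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__,
                     "scipy": __import__("scipy").__version__, "sklearn": sklearn.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
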