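"""Synthetic smartphone cohort generator.

Emulates the five streams a phone-based heart-failure monitoring app
collects — 5-Hz tri-axial accelerometer samples, call logs, location fixes
under the app's >=100 m / >=5 min update rule, weekly KCCQ-12 surveys, and a
clinical-event table — with controllable pre-event effects so the full
prediction pipeline can be exercised and validated without any private
cohort data.

Pre-event effects are applied over the ``effect_window_days`` immediately
preceding each decompensated event: the KCCQ summary drops, the call rate
falls while call durations lengthen, motion amplitude is rescaled, and the
excursion radius shrinks. ``effect_shape`` chooses between a step change
over the window and a linear ramp peaking at the event.

Motion can be synthesized in two modes. ``"raw"`` produces genuine 5-Hz
samples passed through the band-pass -> activity-count pipeline; ``"counts"``
(the default at cohort scale) samples the per-second max-of-|noise|
statistic directly from its closed-form distribution and scales it by the
same circadian envelope, reproducing the count statistics of the raw path at
a fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .actigraphy import (
    EPOCH_S,
    EPOCHS_PER_DAY,
    SECONDS_PER_DAY,
    AccelStream,
    EpochCountSeries,
    stream_to_counts,
)
from .geolocation import haversine_km

#: Study origin used when exporting timestamps.
DEFAULT_STUDY_START = "2023-01-02T00:00:00+00:00"

# circadian motion model
WAKE_HOUR, SLEEP_HOUR = 8.0, 22.0
SENSOR_NOISE_G = 0.01

# app location-update rule
MIN_FIX_DISTANCE_KM = 0.1
MIN_FIX_INTERVAL_S = 300.0

_LATENT_STEP_S = 60.0
_GPS_JITTER_DEG = 0.00012  # ~13 m


@dataclass
class EffectSizes:
    """Multiplicative / additive changes applied before decompensated events."""

    kccq_drop: float = 25.0
    call_rate_factor: float = 0.6
    call_duration_factor: float = 1.6
    motion_shift: float = 1.3
    mobility_radius_factor: float = 0.7

    def __post_init__(self) -> None:
        if not 0 <= self.kccq_drop <= 100:
            raise ValueError("kccq_drop must be in [0, 100]")
        for name in ("call_rate_factor", "call_duration_factor", "motion_shift", "mobility_radius_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def neutral(cls) -> "EffectSizes":
        return cls(0.0, 1.0, 1.0, 1.0, 1.0)


@dataclass
class CohortConfig:
    """Cohort-level generator settings.

    Defaults mirror a 28-participant study accruing ~110 clinical events of
    which ~44% are decompensated, observed for ``study_days`` days.
    """

    n_participants: int = 28
    study_days: int = 120
    accel_rate_hz: float = 5.0
    events_per_participant_mean: float = 110 / 28
    p_decompensated: float = 48 / 110
    effect_window_days: int = 14
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    effect_shape: str = "step"
    missingness_rate: float = 0.1
    seed: int = 0
    motion_mode: str = "counts"
    # baseline stream parameters (population means; per-participant variation applied)
    base_call_rate_per_day: float = 4.0
    base_call_duration_s: float = 120.0
    call_duration_sigma: float = 0.9
    motion_amplitude_g: float = 0.3
    kccq_baseline_mean: float = 70.0
    kccq_baseline_sd: float = 8.0
    kccq_noise_sd: float = 6.0
    excursion_radius_km: float = 3.0
    excursions_per_day: float = 2.0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.study_days < 1:
            raise ValueError("n_participants and study_days must be positive")
        if self.accel_rate_hz <= 0:
            raise ValueError("accel_rate_hz must be positive")
        if self.events_per_participant_mean < 0:
            raise ValueError("events_per_participant_mean must be non-negative")
        if not 0 <= self.p_decompensated <= 1:
            raise ValueError("p_decompensated must be a probability")
        if self.effect_window_days < 1:
            raise ValueError("effect_window_days must be >= 1")
        if not 0 <= self.missingness_rate < 1:
            raise ValueError("missingness_rate must be in [0, 1)")
        if self.effect_shape not in ("step", "linear"):
            raise ValueError("effect_shape must be 'step' or 'linear'")
        if self.motion_mode not in ("counts", "raw"):
            raise ValueError("motion_mode must be 'counts' or 'raw'")


@dataclass
class Cohort:
    """All generated streams plus the clinical-event table."""

    config: CohortConfig
    participants: list[str]
    events: pd.DataFrame
    motion_counts: dict[str, EpochCountSeries]
    calls: pd.DataFrame
    locations: pd.DataFrame
    kccq: pd.DataFrame
    accel: dict[str, AccelStream] | None = None
    study_start: str = DEFAULT_STUDY_START


# ---------------------------------------------------------------------------
# effect weighting


def effect_weights(
    event_days: np.ndarray,
    labels: np.ndarray,
    study_days: int,
    window_days: int,
    shape: str = "step",
) -> np.ndarray:
    """Per-day effect weight in [0, 1]; nonzero only in the ``window_days``
    before each decompensated event (step: 1 throughout; linear: ramp that
    peaks the day before the event). Overlapping windows take the max."""
    w = np.zeros(study_days)
    for day, label in zip(np.asarray(event_days, dtype=int), np.asarray(labels, dtype=int)):
        if label != 1:
            continue
        for delta in range(1, window_days + 1):
            d = day - delta
            if 0 <= d < study_days:
                value = 1.0 if shape == "step" else (window_days + 1 - delta) / window_days
                w[d] = max(w[d], value)
    return w


def _mult(factor: float, w: np.ndarray) -> np.ndarray:
    """Interpolate a multiplicative factor: weight 0 -> 1, weight 1 -> factor."""
    return 1.0 + (factor - 1.0) * w


def _day_envelope_epochs() -> np.ndarray:
    """Half-sine circadian activity envelope sampled at epoch midpoints."""
    hours = (np.arange(EPOCHS_PER_DAY) + 0.5) * EPOCH_S / 3600.0
    env = np.sin(np.pi * (hours - WAKE_HOUR) / (SLEEP_HOUR - WAKE_HOUR))
    env[(hours < WAKE_HOUR) | (hours > SLEEP_HOUR)] = 0.0
    return np.clip(env, 0.0, None)


# ---------------------------------------------------------------------------
# per-stream generators


def generate_accel_stream(
    participant_seed,
    days: int,
    rate_hz: float = 5.0,
    day_weights: np.ndarray | None = None,
    motion_shift: float = 1.0,
    amplitude_g: float = 0.3,
    start_day: int = 0,
    participant_id: str = "",
) -> AccelStream:
    """Raw 5-Hz tri-axial synthesis: circadian amplitude envelope times white
    noise on z (plus a 1 g gravity offset), sensor noise on x/y."""
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    rng = np.random.default_rng(participant_seed)
    n = int(round(days * SECONDS_PER_DAY * rate_hz))
    t = start_day * SECONDS_PER_DAY + np.arange(n) / rate_hz
    hours = (t % SECONDS_PER_DAY) / 3600.0
    env = np.sin(np.pi * (hours - WAKE_HOUR) / (SLEEP_HOUR - WAKE_HOUR))
    env[(hours < WAKE_HOUR) | (hours > SLEEP_HOUR)] = 0.0
    day = (t // SECONDS_PER_DAY).astype(int) - start_day
    if day_weights is None:
        shift = np.full(days, motion_shift)[day]
    else:
        shift = _mult(motion_shift, np.asarray(day_weights, dtype=float))[day]
    amplitude = amplitude_g * env * shift + SENSOR_NOISE_G
    z = 1.0 + amplitude * rng.standard_normal(n)  # gravity on z
    x = SENSOR_NOISE_G * rng.standard_normal(n)
    y = SENSOR_NOISE_G * rng.standard_normal(n)
    return AccelStream(participant_id, t, x, y, z, rate_hz)


def _sample_second_maxima(rng: np.random.Generator, n_seconds: int, samples_per_second: int) -> np.ndarray:
    """Exact draws of max(|N(0,1)|) over k iid samples via the inverse CDF
    (2*Phi(m)-1)^k."""
    u = rng.random(n_seconds)
    return ndtri((u ** (1.0 / samples_per_second) + 1.0) / 2.0)


def generate_motion_counts(
    participant_seed,
    days: int,
    rate_hz: float = 5.0,
    day_weights: np.ndarray | None = None,
    motion_shift: float = 1.0,
    amplitude_g: float = 0.3,
    participant_id: str = "",
) -> EpochCountSeries:
    """Direct epoch-count synthesis matching the raw-path count statistics."""
    rng = np.random.default_rng(participant_seed)
    k = max(1, int(round(rate_hz)))
    n_sec = days * SECONDS_PER_DAY
    maxima = _sample_second_maxima(rng, n_sec, k)
    per_epoch = maxima.reshape(-1, int(EPOCH_S)).sum(axis=1)
    env = np.tile(_day_envelope_epochs(), days)
    day = np.repeat(np.arange(days), EPOCHS_PER_DAY)
    if day_weights is None:
        shift = np.full(days, motion_shift)[day]
    else:
        shift = _mult(motion_shift, np.asarray(day_weights, dtype=float))[day]
    amplitude = amplitude_g * env * shift + SENSOR_NOISE_G
    counts = amplitude * per_epoch
    epoch_start = np.arange(days * EPOCHS_PER_DAY) * EPOCH_S
    return EpochCountSeries(participant_id, epoch_start, counts, np.ones(counts.size, bool))


def generate_call_log(
    participant_seed,
    days: int,
    base_rate_per_day: float = 4.0,
    base_duration_s: float = 120.0,
    duration_sigma: float = 0.9,
    day_weights: np.ndarray | None = None,
    call_rate_factor: float = 1.0,
    call_duration_factor: float = 1.0,
    n_contacts: int = 15,
    participant_id: str = "",
) -> pd.DataFrame:
    """Poisson call arrivals with lognormal durations.

    Within effect days the daily rate is multiplied toward
    ``call_rate_factor`` and the median duration toward
    ``call_duration_factor`` (fewer but longer calls for the defaults).
    """
    if base_rate_per_day <= 0 or base_duration_s <= 0:
        raise ValueError("rates and durations must be positive")
    rng = np.random.default_rng(participant_seed)
    w = np.zeros(days) if day_weights is None else np.asarray(day_weights, dtype=float)
    lam = base_rate_per_day * _mult(call_rate_factor, w)
    n_per_day = rng.poisson(lam)
    day = np.repeat(np.arange(days), n_per_day)
    n = int(n_per_day.sum())
    start = day * SECONDS_PER_DAY + rng.random(n) * SECONDS_PER_DAY
    median = base_duration_s * _mult(call_duration_factor, w)[day]
    duration = rng.lognormal(mean=np.log(median), sigma=duration_sigma)
    contacts = np.array([f"{h:08x}" for h in rng.integers(0, 2**32, size=n_contacts)])
    weights = 1.0 / np.arange(1, n_contacts + 1)
    weights /= weights.sum()
    contact = rng.choice(contacts, size=n, p=weights)
    direction = rng.choice(np.array(["incoming", "outgoing"]), size=n, p=[0.45, 0.55])
    df = pd.DataFrame(
        {"participant_id": participant_id, "contact_hash": contact, "direction": direction,
         "start": start, "duration_s": duration}
    )
    return df.sort_values("start", kind="stable").reset_index(drop=True)


def _app_rule_subsample(t: np.ndarray, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Indices of emitted fixes: a fix is recorded only after both >=100 m of
    displacement and >=5 min since the previously emitted fix."""
    n = t.size
    if n == 0:
        return np.empty(0, dtype=int)
    step = max(1, int(round(MIN_FIX_INTERVAL_S / _LATENT_STEP_S)))
    emitted = [0]
    i = 0
    while True:
        j = i + step
        found = -1
        while j < n:
            stop = min(j + 1440, n)
            d = haversine_km(lat[j:stop], lon[j:stop], lat[i], lon[i])
            hit = np.flatnonzero(np.atleast_1d(d) >= MIN_FIX_DISTANCE_KM)
            if hit.size:
                found = j + int(hit[0])
                break
            j = stop
        if found < 0:
            break
        emitted.append(found)
        i = found
    return np.asarray(emitted, dtype=int)


def generate_location_trace(
    participant_seed,
    days: int,
    home_lat: float,
    home_lon: float,
    excursion_radius_km: float = 3.0,
    excursions_per_day: float = 2.0,
    day_weights: np.ndarray | None = None,
    mobility_radius_factor: float = 1.0,
    speed_kmh: float = 30.0,
    participant_id: str = "",
) -> pd.DataFrame:
    """Home-anchored latent trajectory subsampled by the app update rule.

    Each day holds a Poisson number of out-and-back excursions with
    exponentially distributed distances (shrunk toward
    ``mobility_radius_factor`` on effect days); the latent minute-level track
    gets ~13 m GPS jitter before the >=100 m / >=5 min rule is applied.
    """
    if excursion_radius_km <= 0:
        raise ValueError("excursion_radius_km must be positive")
    rng = np.random.default_rng(participant_seed)
    w = np.zeros(days) if day_weights is None else np.asarray(day_weights, dtype=float)
    radius_mult = _mult(mobility_radius_factor, w)
    per_min = int(SECONDS_PER_DAY / _LATENT_STEP_S)
    n = days * per_min
    lat = np.full(n, home_lat)
    lon = np.full(n, home_lon)
    coslat = np.cos(np.radians(home_lat))
    for d in range(days):
        k = rng.poisson(excursions_per_day)
        cursor = d * per_min
        day_end = (d + 1) * per_min
        dep_minutes = np.sort(rng.uniform(WAKE_HOUR * 60, (SLEEP_HOUR - 1) * 60, size=k)).astype(int)
        for dep in dep_minutes:
            dep_i = d * per_min + dep
            if dep_i <= cursor:
                continue
            dist = float(np.clip(rng.exponential(excursion_radius_km) * radius_mult[d], 0.1, 30.0))
            bearing = rng.uniform(0, 2 * np.pi)
            dlat = dist * np.cos(bearing) / 110.574
            dlon = dist * np.sin(bearing) / (111.320 * max(coslat, 0.01))
            travel = max(2, int(round(dist / speed_kmh * 60)))
            dwell = int(rng.uniform(30, 90))
            arr_i = min(dep_i + travel, day_end - 1)
            leave_i = min(arr_i + dwell, day_end - 1)
            back_i = min(leave_i + travel, day_end - 1)
            frac_out = np.linspace(0, 1, arr_i - dep_i + 1)
            lat[dep_i:arr_i + 1] = home_lat + dlat * frac_out
            lon[dep_i:arr_i + 1] = home_lon + dlon * frac_out
            lat[arr_i:leave_i + 1] = home_lat + dlat
            lon[arr_i:leave_i + 1] = home_lon + dlon
            frac_back = np.linspace(1, 0, back_i - leave_i + 1)
            lat[leave_i:back_i + 1] = home_lat + dlat * frac_back
            lon[leave_i:back_i + 1] = home_lon + dlon * frac_back
            cursor = back_i
    lat = lat + rng.normal(0, _GPS_JITTER_DEG, n)
    lon = lon + rng.normal(0, _GPS_JITTER_DEG, n)
    t = np.arange(n) * _LATENT_STEP_S
    idx = _app_rule_subsample(t, lat, lon)
    return pd.DataFrame(
        {"participant_id": participant_id, "t": t[idx], "lat": lat[idx], "lon": lon[idx]}
    )


def generate_kccq_series(
    participant_seed,
    days: int,
    baseline_domains,
    day_weights: np.ndarray | None = None,
    kccq_drop: float = 0.0,
    noise_sd: float = 6.0,
    p_domain_missing: float = 0.05,
    p_skip: float = 0.1,
    participant_id: str = "",
) -> pd.DataFrame:
    """Weekly KCCQ-12 responses with Gaussian noise clipped to [0, 100].

    On effect days every domain is reduced by ``kccq_drop`` (scaled by the
    effect weight); occasional domains are missing and whole surveys are
    occasionally skipped.
    """
    baseline = np.asarray(baseline_domains, dtype=float)
    if baseline.size != 4 or np.any(baseline < 0) or np.any(baseline > 100):
        raise ValueError("baseline_domains must be 4 scores in [0, 100]")
    rng = np.random.default_rng(participant_seed)
    w = np.zeros(days) if day_weights is None else np.asarray(day_weights, dtype=float)
    offset = int(rng.integers(0, 7))
    survey_days = np.arange(offset, days, 7)
    rows = []
    for day in survey_days:
        if rng.random() < p_skip:
            continue
        values = baseline - kccq_drop * w[day] + rng.normal(0, noise_sd, 4)
        values = np.clip(values, 0.0, 100.0)
        missing = rng.random(4) < p_domain_missing
        if np.all(missing):
            missing[rng.integers(0, 4)] = False
        values[missing] = np.nan
        rows.append(
            {"participant_id": participant_id, "t": day * SECONDS_PER_DAY + 9 * 3600.0,
             "phys": values[0], "symp": values[1], "qol": values[2], "social": values[3]}
        )
    return pd.DataFrame(rows, columns=["participant_id", "t", "phys", "symp", "qol", "social"])


# ---------------------------------------------------------------------------
# missingness


def inject_missingness(stream, rate: float, seed) -> "EpochCountSeries | pd.DataFrame":
    """Drop contiguous blocks totalling about ``rate`` of the stream.

    For an EpochCountSeries, blocks of epochs have ``present`` cleared (as
    when the phone stops sharing or runs out of battery); for a time-stamped
    DataFrame (column ``t``), rows inside randomly placed time blocks are
    dropped. Deterministic given ``seed``.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if isinstance(stream, EpochCountSeries):
        present = stream.present.copy()
        n = present.size
        if rate == 0 or n == 0:
            return EpochCountSeries(stream.participant_id, stream.epoch_start.copy(),
                                    stream.count.copy(), present, stream.epoch_s)
        target = int(round(rate * n))
        dropped = int(np.sum(~present))
        baseline_dropped = dropped
        guard = 0
        while dropped - baseline_dropped < target and guard < 100 * n:
            start = int(rng.integers(0, n))
            length = int(rng.geometric(1.0 / 240.0))
            present[start:start + length] = False
            dropped = int(np.sum(~present))
            guard += 1
        return EpochCountSeries(stream.participant_id, stream.epoch_start.copy(),
                                stream.count.copy(), present, stream.epoch_s)
    # time-stamped record table
    df = stream.copy()
    if rate == 0 or len(df) == 0:
        return df
    t = df["t"].to_numpy(dtype=float)
    span = (t.min(), t.max() + 1.0)
    total = span[1] - span[0]
    keep = np.ones(len(df), dtype=bool)
    removed = 0.0
    guard = 0
    while removed < rate * total and guard < 10_000:
        start = rng.uniform(*span)
        length = rng.exponential(0.02 * total)
        newly = keep & (t >= start) & (t < start + length)
        keep[newly] = False
        removed += min(start + length, span[1]) - max(start, span[0]) if length > 0 else 0.0
        guard += 1
    return df.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# cohort orchestration


def _participant_ids(n: int) -> list[str]:
    return [f"P{i:03d}" for i in range(n)]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate every stream plus clinical events; deterministic given the seed."""
    ids = _participant_ids(config.n_participants)
    root = np.random.SeedSequence([config.seed, 20230102])
    per_participant = root.spawn(config.n_participants)
    eff = config.effect_sizes

    event_rows = []
    motion_counts: dict[str, EpochCountSeries] = {}
    accel: dict[str, AccelStream] = {}
    calls, locations, kccq_frames = [], [], []

    for pid, seq in zip(ids, per_participant):
        streams = seq.spawn(7)
        rng_p = np.random.default_rng(streams[0])

        # clinical events
        n_events = int(rng_p.poisson(config.events_per_participant_mean))
        lo = min(config.effect_window_days + 1, config.study_days - 1)
        candidates = np.arange(lo, config.study_days)
        n_events = min(n_events, candidates.size)
        days = np.sort(rng_p.choice(candidates, size=n_events, replace=False))
        labels = (rng_p.random(n_events) < config.p_decompensated).astype(int)
        for day, label in zip(days, labels):
            event_rows.append({"participant_id": pid, "day": int(day), "label": int(label)})
        w = effect_weights(days, labels, config.study_days, config.effect_window_days, config.effect_shape)

        # participant-level baselines
        amplitude = config.motion_amplitude_g * rng_p.lognormal(0.0, 0.15)
        call_rate = config.base_call_rate_per_day * rng_p.lognormal(0.0, 0.3)
        call_dur = config.base_call_duration_s * rng_p.lognormal(0.0, 0.3)
        home_lat = 41.0 + rng_p.uniform(-0.05, 0.05)
        home_lon = -74.0 + rng_p.uniform(-0.05, 0.05)
        base_summary = float(np.clip(rng_p.normal(config.kccq_baseline_mean, config.kccq_baseline_sd), 35, 95))
        domains = np.clip(base_summary + rng_p.normal(0, 5, 4), 0, 100)

        if config.motion_mode == "raw":
            stream = generate_accel_stream(
                streams[1], config.study_days, config.accel_rate_hz, w, eff.motion_shift,
                amplitude, participant_id=pid,
            )
            accel[pid] = stream
            counts = stream_to_counts(stream)
        else:
            counts = generate_motion_counts(
                streams[1], config.study_days, config.accel_rate_hz, w, eff.motion_shift,
                amplitude, participant_id=pid,
            )
        motion_counts[pid] = inject_missingness(counts, config.missingness_rate, streams[2])

        calls.append(
            generate_call_log(
                streams[3], config.study_days, call_rate, call_dur, config.call_duration_sigma,
                w, eff.call_rate_factor, eff.call_duration_factor, participant_id=pid,
            )
        )
        locations.append(
            generate_location_trace(
                streams[4], config.study_days, home_lat, home_lon, config.excursion_radius_km,
                config.excursions_per_day, w, eff.mobility_radius_factor, participant_id=pid,
            )
        )
        kccq_frames.append(
            generate_kccq_series(
                streams[5], config.study_days, domains, w, eff.kccq_drop, config.kccq_noise_sd,
                participant_id=pid,
            )
        )

    events = pd.DataFrame(event_rows, columns=["participant_id", "day", "label"])
    return Cohort(
        config=config,
        participants=ids,
        events=events,
        motion_counts=motion_counts,
        calls=pd.concat(calls, ignore_index=True),
        locations=pd.concat(locations, ignore_index=True),
        kccq=pd.concat(kccq_frames, ignore_index=True),
        accel=accel if config.motion_mode == "raw" else None,
    )
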