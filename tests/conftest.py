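"""Shared fixtures: cohorts at the default study conditions.

The heavy cohorts are session-scoped because several tests (calibration,
parameter recovery, attribution) interrogate the same generated study.
"""

import pytest

import hfsense as h
import hfsense.windows as W

FUSED = ("kccq", "motion", "social")


@pytest.fixture(scope="session")
def planted_cohort():
    """Default planted-effect cohort: 28 participants, ~110 events."""
    return h.generate_cohort(h.CohortConfig(seed=101))


@pytest.fixture(scope="session")
def planted_features(planted_cohort):
    """14-day pre-event feature table, complete cases for kccq/motion/social."""
    wl = W.build_windows(planted_cohort.events, 14, 0)
    table = W.assemble_dataset(planted_cohort, wl)
    complete, _ = W.filter_complete_cases(table, FUSED)
    return complete


@pytest.fixture(scope="session")
def null_cohort():
    """Neutral-effect cohort: labels independent of every stream."""
    return h.generate_cohort(h.CohortConfig(seed=202, effect_sizes=h.EffectSizes.neutral()))


@pytest.fixture(scope="session")
def null_features(null_cohort):
    wl = W.build_windows(null_cohort.events, 14, 0)
    table = W.assemble_dataset(null_cohort, wl)
    complete, _ = W.filter_complete_cases(table, FUSED)
    return complete


@pytest.fixture(scope="session")
def decay_cohort():
    """Planted effects ramping up linearly toward each decompensated event."""
    return h.generate_cohort(h.CohortConfig(seed=303, effect_shape="linear"))


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for structural/IO tests."""
    return h.generate_cohort(
        h.CohortConfig(n_participants=6, study_days=45, events_per_participant_mean=3.0, seed=7)
    )
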