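"""Shared fixtures: one synthetic cohort, epoched and featurized once."""

import pytest

import ppgsqi as p

#: Seed fixing the study conditions for every cohort-level test.
COHORT_SEED = 7


@pytest.fixture(scope="session")
def cohort():
    """Default 8-subject, 3-wavelength synthetic cohort."""
    return p.make_cohort(8, COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_epochs(cohort):
    epochs = []
    for record in cohort:
        filtered = p.attenuate_breathing(record)
        epochs.extend(p.epoch_record(filtered))
    return epochs


@pytest.fixture(scope="session")
def features(cohort_epochs):
    """Feature table: one row per epoch, 19 SQI columns plus metadata."""
    return p.feature_table(cohort_epochs)


@pytest.fixture(scope="session")
def binary_features(features):
    """Clean/noisy rows only (okay epochs excluded from classification)."""
    return features[features["label"].isin(["clean", "noisy"])].reset_index(drop=True)


@pytest.fixture(scope="session")
def clean_epoch(cohort):
    """One clean mid-rest epoch from the first green record."""
    record = next(r for r in cohort if r.wavelength == "green")
    filtered = p.attenuate_breathing(record)
    epochs = p.epoch_record(filtered)
    return next(e for e in epochs if e.label == "clean" and e.start_s > 16)
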