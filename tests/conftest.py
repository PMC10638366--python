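"""Shared fixtures: synthetic specimens and a session-trained pore model.

Everything is generated programmatically at test time; the heavyweight
artifacts (50-specimen cohorts, the trained pixel classifier) are session
scoped so the segmentation, morphometrics and acceptance tests share them.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pytest

from bolipore.synth import SyntheticSpec, generate_cohort, generate_specimen

CLEAN = dict(noise_sigma=0.0, debris_count=0)


@pytest.fixture(scope="session")
def clean_specimen():
    """One noise-free, debris-free specimen with ground truth."""
    return generate_specimen(SyntheticSpec(seed=11, **CLEAN))


@pytest.fixture(scope="session")
def noisy_specimen():
    """One specimen at default noise and debris settings."""
    return generate_specimen(SyntheticSpec(seed=12))


@pytest.fixture(scope="session")
def clean_cohort50():
    """50 noise-free specimens (counts are exactly recoverable)."""
    base = SyntheticSpec(**CLEAN)
    return generate_cohort(50, "default", seed=2024, base_spec=base)


@pytest.fixture(scope="session")
def noisy_cohort50():
    """50 specimens under the default noise/debris conditions."""
    return generate_cohort(50, "default", seed=2024)


@pytest.fixture(scope="session")
def trained_model_bundle():
    """A 52-specimen cohort split 40 train / 12 held out, with the pixel
    classifier trained for 10 epochs at seed 7."""
    from bolipore.learned import train_pore_model

    cohort = generate_cohort(52, "default", seed=123)
    pairs = [(img, gt.pore_mask) for img, gt in cohort[:40]]
    holdout = cohort[40:]
    model = train_pore_model(pairs, epochs=10, seed=7)
    return model, pairs, holdout
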