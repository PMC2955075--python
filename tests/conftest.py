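import warnings

import numpy as np
import pytest

from adswap.config import Config
from adswap.ds_score import DSFactors
from adswap.pipeline import compare_pair
from adswap.synthetic import (FixtureSpec, make_closed_form, make_common_homolog,
                              make_open_form)

warnings.filterwarnings("ignore", message="swap rotation leaves close contacts")

# layout with an elongated swapped domain: its principal axis is dominated by
# the long helix, so both representative-vector methods track a planted
# rotation by construction
ELONGATED_LAYOUT = (
    (("helix", 12), ("strand", 7), ("strand", 5), ("helix", 9)),
    (("helix", 14), ("strand", 6)),
)


@pytest.fixture(scope="session")
def ds_pair():
    """One closed/open fixture pair (C-terminal swap, 120°, mild noise)."""
    spec = FixtureSpec(seed=11, noise_sigma=0.3)
    closed = make_closed_form(spec)
    opened = make_open_form(closed, spec)
    return spec, closed, opened


@pytest.fixture(scope="session")
def clean_pair():
    """Noise-free closed/open pair: open differs from closed only by the
    planted 120° domain rotation."""
    spec = FixtureSpec(seed=2, noise_sigma=0.0)
    closed = make_closed_form(spec)
    opened = make_open_form(closed, spec)
    return spec, closed, opened


def _factors_of(report):
    f = report.factors or {"gamma_theta": 0.0, "gamma_d": None, "mu_sd": None, "s0": 0.0}
    return DSFactors(f["gamma_theta"], f["gamma_d"], f["mu_sd"], report.eta, f["s0"])


@pytest.fixture(scope="session")
def fixture_batch():
    """50 DS pairs and 50 perturbed-copy controls run through the pipeline.

    Shared by the hinge-recovery and classifier tests; returns per-pair
    (spec, report) lists for positives and the factor/label arrays.
    """
    positives, factors, labels = [], [], []
    for seed in range(50):
        spec = FixtureSpec(seed=seed, noise_sigma=0.3)
        closed = make_closed_form(spec)
        opened = make_open_form(closed, spec)
        rep = compare_pair(closed, opened)
        positives.append((spec, rep))
        factors.append(_factors_of(rep))
        labels.append(1)
        homolog = make_common_homolog(closed, 0.5, 1000 + seed)
        rep_neg = compare_pair(closed, homolog)
        factors.append(_factors_of(rep_neg))
        labels.append(0)
    return positives, factors, np.array(labels)
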