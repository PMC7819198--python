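"""Shared fixtures: a small seeded cohort and one full pipeline run.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import pytest

from cgmalarm import RunConfig, run_synthetic
from cgmalarm.synth import make_benchmark


@pytest.fixture(scope="session")
def pipeline_result():
    """One full synthetic study (20 train / 10 held-out subjects, 2 episodes
    each, 3 days): libraries, held-out alerts and the event-level report."""
    return run_synthetic(RunConfig(seed=0), n_train=20, n_test=10,
                         events_per_subject=2, days=3)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight subjects, two moderate (level-II) episodes each."""
    return make_benchmark(8, 2, seed=4, depth_choices=(3.4,), depth_probs=(1.0,))
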