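"""Shared fixtures: small synthetic runs reused across test modules.

Runs are generated once per session; tests treating them as read-only.
"""

import pytest

from dnbaudit import InsertModel, RunConfig, resolve_inputs, simulate_pairs


@pytest.fixture(scope="session")
def small_run():
    """Default-conditions run, small enough for unit tests."""
    config = RunConfig(n_pairs=4000, n_fovs=8, seed=11)
    pairs, truth = simulate_pairs(config)
    panel, refs = resolve_inputs(config)
    return config, pairs, truth, panel, refs


@pytest.fixture(scope="session")
def clean_short_run():
    """Error-free, artifact-free run with uniformly short-to-long inserts,
    used for layout and insert-arithmetic oracles."""
    config = RunConfig(
        n_pairs=600,
        n_fovs=2,
        seed=23,
        insert_model=InsertModel(name="uniform", low=50),
        misdemux_rate=0.0,
        improper_pair_rate=0.0,
        duplicate_rate=0.0,
        chimera_rate=0.0,
        substitution_error_rate=0.0,
    )
    pairs, truth = simulate_pairs(config)
    panel, refs = resolve_inputs(config)
    return config, pairs, truth, panel, refs


@pytest.fixture(scope="session")
def noise_free_run():
    """Error-free run with all artifact classes planted."""
    config = RunConfig(n_pairs=6000, n_fovs=6, seed=29, substitution_error_rate=0.0)
    pairs, truth = simulate_pairs(config)
    panel, refs = resolve_inputs(config)
    return config, pairs, truth, panel, refs
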