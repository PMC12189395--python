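"""Shared study conditions for the numbered analysis scripts.

Each script regenerates (or reuses) the same synthetic PE300-style run:
50,000 read pairs across 50 FOVs with the default planted-artifact rates.
FASTQ and the truth table live under scratch/run/ (bulky, regenerable);
result tables go to results/.
"""

from pathlib import Path

from dnbaudit import RunConfig, generate_run, resolve_inputs, simulate_pairs

REPO = Path(__file__).resolve().parent.parent
SCRATCH = REPO / "scratch" / "run"
RESULTS = REPO / "results"

STUDY_SEED = 1


def study_config(seed: int = STUDY_SEED) -> RunConfig:
    return RunConfig(n_pairs=50_000, seed=seed)


def load_run(seed: int = STUDY_SEED):
    """The study run, generated in memory (fast: a few seconds)."""
    config = study_config(seed)
    pairs, truth = simulate_pairs(config)
    panel, refs = resolve_inputs(config)
    return config, pairs, truth, panel, refs


def write_run_to_scratch(seed: int = STUDY_SEED):
    config = study_config(seed)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    return generate_run(config, SCRATCH, prefix=f"study_seed{seed}")


def results_dir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
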