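"""Shared helpers for the analysis drivers: locate the repository, load the
simulated cohort written by 01_simulate_cohort.py (regenerating it if the
driver is run standalone)."""

from pathlib import Path

REPO = Path(__file__).resolve().parents[1]
RESULTS = REPO / "results"
COHORT_DIR = RESULTS / "cohort"


def load_cohort(seed: int = 0):
    from m6astrat.synthetic_cohort import SimulationConfig, simulate_cohort
    return simulate_cohort(SimulationConfig(seed=seed))


def ensure_dir(path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    return path
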