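"""Shared plumbing for the analysis drivers: default synthetic cohort and
output locations. Heavy intermediates live under scratch/, final tables
under results/."""

from pathlib import Path

from opsccrna.synthetic import SimulationConfig, write_bundle

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "synthetic_inputs"
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)


def default_bundle(seed: int = 20240228):
    """The synthetic study cohort (23 HPV-negative vs 39 HPV-positive
    samples, planted 50-gene set, hub gene with three partners)."""
    cfg = SimulationConfig(seed=seed)
    paths = write_bundle(SCRATCH, cfg)
    return cfg, paths
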