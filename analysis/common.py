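"""Shared plumbing for the numbered analysis drivers.

The drivers operate on one simulated single-embryo dataset (seed 1,
default study design) kept under scratch/ — large alignment files stay
out of the results tree — and write their tables under results/.
"""

from pathlib import Path

from hivemzt.pipeline import PipelineConfig, run_pipeline
from hivemzt.simulate import SimulationConfig, simulate_dataset

ROOT = Path(__file__).resolve().parents[1]
DATASET_DIR = ROOT / "scratch" / "dataset"
RESULTS = ROOT / "results"
SEED = 1


def ensure_dataset():
    """Simulate the default dataset once; reuse it across drivers."""
    if not (DATASET_DIR / "reads.sam").exists():
        print(f"simulating default dataset (seed {SEED}) -> {DATASET_DIR}")
        simulate_dataset(SimulationConfig(seed=SEED), DATASET_DIR)
    return DATASET_DIR


def load_dataset():
    """Rebuild the in-memory dataset objects deterministically."""
    from hivemzt.simulate import SimulatedDataset, build_toy_genome

    ensure_dataset()
    cfg = SimulationConfig(seed=SEED)
    toy = build_toy_genome(cfg)
    return cfg, toy


def stage_config(outdir: Path, **toggles) -> PipelineConfig:
    ensure_dataset()
    flags = {
        f"run_{s}": False
        for s in ("expression", "lncrna", "polya", "splicing", "coexpression")
    }
    flags.update(toggles)
    return PipelineConfig(
        genome=str(DATASET_DIR / "genome.fa"),
        annotation=str(DATASET_DIR / "annotation.gff3"),
        alignments=str(DATASET_DIR / "reads.sam"),
        sample_sheet=str(DATASET_DIR / "sample_sheet.tsv"),
        outdir=str(outdir),
        seed=SEED,
        **flags,
    )


def run_stage(name: str, **toggles):
    outdir = RESULTS / name
    outdir.mkdir(parents=True, exist_ok=True)
    return run_pipeline(stage_config(outdir, **toggles)), outdir
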