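#!/usr/bin/env python
"""Simulate the single-embryo study design and summarize its genome.

Generates the default synthetic dataset — 36 single-embryo samples
(2 sexes x {24, 48, 72} h AEL x 2 queens x 3 embryos), a multi-gene toy
genome with long lncRNA-hosting introns, spliced reads with soft-clipped
poly(A)/(T) tails and internal-priming artifacts — and reports what was
planted.  Truth tables are copied into results/01_simulation/.
"""

import shutil
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import DATASET_DIR, RESULTS, ensure_dataset, load_dataset  # noqa: E402

from hivemzt.core import genome_partition, long_intron_stats  # noqa: E402


def main():
    ensure_dataset()
    _cfg, toy = load_dataset()
    outdir = RESULTS / "01_simulation"
    outdir.mkdir(parents=True, exist_ok=True)
    for tsv in sorted((DATASET_DIR / "truth").glob("*.tsv")):
        shutil.copy(tsv, outdir / tsv.name)

    parts = genome_partition(toy.annotation, toy.chrom_lengths)
    introns = long_intron_stats(toy.annotation, min_length=2000)
    print(f"genome: {len(toy.chrom_lengths)} chromosomes, "
          f"{parts['total']:,} bp total")
    print(f"  exonic {parts['exonic']:,} bp, intronic {parts['intronic']:,} bp "
          f"({parts['intronic'] / parts['total']:.1%} of the genome), "
          f"intergenic {parts['intergenic']:,} bp")
    print(f"  {introns['n_introns']} annotated introns, "
          f"{introns['n_long']} ({introns['long_fraction']:.1%}) "
          "longer than 2,000 nt — long enough to host whole lncRNA loci")
    print(f"planted lncRNAs by class:\n"
          f"{toy.lncrna_truth['class'].value_counts().to_string()}")
    print(f"gene labels:\n{toy.labels.value_counts().to_string()}")
    print(f"truth tables copied to {outdir}")


if __name__ == "__main__":
    main()
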