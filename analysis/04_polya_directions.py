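#!/usr/bin/env python
"""Tail reads, PAS clusters and lncRNA transcription direction.

Detects soft-clipped poly(A)/(T) tails (> 10 nt, <= 10% error), removes
internal-priming artifacts by the genomic A-content beyond the anchor,
clusters anchors into polyadenylation sites (20-bp single linkage) and
infers each lncRNA candidate's strand from flanking PAS evidence.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd  # noqa: E402
from common import DATASET_DIR, run_stage  # noqa: E402

from hivemzt.evaluate import (  # noqa: E402
    direction_recovery,
    match_candidates_to_truth,
    pas_recovery,
    priming_specificity,
)


def main():
    result, outdir = run_stage(
        "04_polya", run_polya=True, run_lncrna=True
    )
    truth_dir = DATASET_DIR / "truth"
    pas_truth = pd.read_csv(truth_dir / "pas.tsv", sep="\t", index_col=0)
    tail_truth = pd.read_csv(truth_dir / "tail_reads.tsv", sep="\t")
    lnc_truth = pd.read_csv(truth_dir / "lncrnas.tsv", sep="\t", index_col=0)

    print(f"tails detected: {len(result.tails)}, kept after "
          f"internal-priming filter: {len(result.tails_kept)}")
    prim = priming_specificity(tail_truth, result.tails, result.tails_kept)
    print(f"  artifact removal: {prim['removal_specificity']:.1%}, "
          f"true-tail retention: {prim['true_tail_retention']:.1%}")
    pas = pas_recovery(result.pas_clusters, pas_truth)
    print(f"PAS clusters (support >= 3): {pas['n_clusters']}, "
          f"{pas['fraction_within_tolerance']:.1%} within 10 nt of a "
          "planted site")
    assigned = match_candidates_to_truth(result.candidates, lnc_truth)
    rec = direction_recovery(assigned, lnc_truth, result.directions)
    print(f"direction assigned for {rec['n_assigned']} matched lncRNAs, "
          f"accuracy {rec['accuracy']:.1%}")
    print("per-group mean tail length (sex x hours):")
    print(result.tail_summary.groupby(["sex", "hours"])["mean"].mean()
          .round(1).to_string())
    print(f"one-way ANOVA across timepoints: {result.tail_anova} "
          "(male tails lengthen with age, female tails stay flat)")
    print(f"tables in {outdir}")


if __name__ == "__main__":
    main()
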