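#!/usr/bin/env python
"""Assemble candidate transcripts and identify lncRNAs.

Coverage-contig/junction-chain assembly, logistic coding-potential
filtering against annotation-trained features, the two single-exon
length thresholds (500 vs 1,000 nt), locus classification and
sex-specific expression calls; compared against the planted lncRNAs.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd  # noqa: E402
from common import DATASET_DIR, run_stage  # noqa: E402

from hivemzt.evaluate import match_candidates_to_truth  # noqa: E402
from hivemzt.lncrna import summarize_lncrnas  # noqa: E402


def main():
    result, outdir = run_stage("03_lncrna", run_lncrna=True)
    truth = pd.read_csv(
        DATASET_DIR / "truth" / "lncrnas.tsv", sep="\t", index_col=0
    )
    summary = summarize_lncrnas(result.candidates)
    n500, n1000 = summary["n"], len(result.candidates_alt_threshold)
    print(f"candidates retained: {n500} at the 500-nt single-exon threshold, "
          f"{n1000} at 1,000 nt (the lower threshold keeps more, "
          "as it must)")
    print(f"locus classes: {summary['class_counts']}")
    print(f"intronic fraction: {summary['intronic_fraction']:.1%}")
    assigned = match_candidates_to_truth(result.candidates, truth)
    print(f"planted-lncRNA recovery: {len(assigned)}/{len(truth)}")
    print(f"tables in {outdir}")


if __name__ == "__main__":
    main()
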