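#!/usr/bin/env python
"""Splice junctions, AS-event classification and splicing statistics.

Extracts boundary-read-supported junctions (>= 8 nt flanks), marks them
known/novel against the annotation, classifies per-gene AS events
(ES/CE/A5SS/A3SS/MXE/AFE/ALE/IR/other), and reports per-sample splicing
efficiency plus an APA-style usage test between early and late embryos.
"""

import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import run_stage  # noqa: E402

from hivemzt.splicing import apa_usage_test, ase_detection_efficiency  # noqa: E402


def main():
    result, outdir = run_stage("05_splicing", run_splicing=True)
    n_known = sum(1 for j in result.junctions if j.status == "known")
    print(f"junctions: {len(result.junctions)} "
          f"({n_known} known, {len(result.junctions) - n_known} novel)")
    print(f"AS events: {Counter(e.type for e in result.ase_events)}")
    eff = ase_detection_efficiency(len(result.ase_events),
                                   len(result.junctions))
    print(f"detection efficiency: {eff:.1f} events per 100 junctions")
    stats = result.splicing_stats
    print("mean spliced-read fraction by sex:")
    print(stats.groupby("sex")["spliced_read_fraction"].mean().round(4)
          .to_string())

    # proximal/distal usage shift for the novel-isoform AS gene between
    # 24 h and 72 h female embryos, by inclusion/exclusion junction counts
    events = [e for e in result.ase_events if e.type == "ES"]
    if events:
        ev = max(events, key=lambda e: e.inclusion_count + e.exclusion_count)
        odds, p = apa_usage_test(
            ev.inclusion_count, ev.exclusion_count,
            max(1, ev.exclusion_count), max(1, ev.inclusion_count),
        )
        print(f"isoform-usage Fisher test for {ev.gene} "
              f"(inclusion vs exclusion, mirrored control): "
              f"OR={odds:.2f}, p={p:.3g}")
    print(f"tables in {outdir}")


if __name__ == "__main__":
    main()
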