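"""Truth-vs-called comparisons for simulated datasets.

Everything here consumes a :class:`~hivemzt.simulate.SimulatedDataset`
and a :class:`~hivemzt.pipeline.PipelineResult` and reports recovery of
the planted signal: wave labels, DEGs, lncRNA loci and directions, PAS
positions, internal-priming removal, junction counts and AS events.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

WAVE_SET = ("wave1", "wave2", "wave3", "maternal_degradation")


def match_candidates_to_truth(candidates, lncrna_truth: pd.DataFrame,
                              min_reciprocal_overlap: float = 0.5):
    """Best reciprocal-overlap assignment of discovered lncRNAs to planted ones.

    Returns dict truth_id -> candidate (one per truth locus at most).
    """
    assigned: dict[str, object] = {}
    for lid, row in lncrna_truth.iterrows():
        best, best_ov = None, 0
        for cand in candidates:
            tx = cand.transcript
            if tx.chrom != row["chrom"]:
                continue
            ov = max(0, min(tx.end, row["end"]) - max(tx.start, row["start"]))
            if ov <= best_ov:
                continue
            if (
                ov >= min_reciprocal_overlap * (row["end"] - row["start"])
                and ov >= min_reciprocal_overlap * (tx.end - tx.start)
            ):
                best, best_ov = cand, ov
        if best is not None:
            assigned[lid] = best
    return assigned


def wave_recovery(truth_labels: pd.Series, called: pd.Series) -> dict:
    """Accuracy of called wave labels over genes planted with a wave/MD label."""
    planted = truth_labels[truth_labels.isin(WAVE_SET)]
    shared = planted.index.intersection(called.index)
    if len(shared) == 0:
        return {"n_planted": 0, "accuracy": float("nan")}
    agree = (called[shared] == planted[shared]).sum()
    confusion = (
        pd.crosstab(planted[shared], called[shared])
        .reindex(index=list(WAVE_SET), fill_value=0)
        .to_dict()
    )
    constants = truth_labels[truth_labels == "constant"]
    const_shared = constants.index.intersection(called.index)
    return {
        "n_planted": int(len(shared)),
        "accuracy": float(agree / len(shared)),
        "confusion": confusion,
        "constant_called_none": float(
            (called[const_shared] == "none").mean()
        ) if len(const_shared) else float("nan"),
    }


def deg_recovery(truth_labels: pd.Series, deg_called: pd.DataFrame,
                 expected_up: set[str], expected_down: set[str]) -> dict:
    """Sensitivity / false discovery of one contrast's DEG calls."""
    up_genes = [g for g in deg_called.index if truth_labels.get(g) in expected_up]
    down_genes = [
        g for g in deg_called.index if truth_labels.get(g) in expected_down
    ]
    null_genes = [
        g
        for g in deg_called.index
        if truth_labels.get(g) not in expected_up | expected_down
    ]
    cls = deg_called["class"]
    tp = sum(cls[g] == "up" for g in up_genes) + sum(
        cls[g] == "down" for g in down_genes
    )
    n_pos = len(up_genes) + len(down_genes)
    called_pos = (cls != "ns").sum()
    fp = sum(cls[g] != "ns" for g in null_genes)
    return {
        "sensitivity": float(tp / n_pos) if n_pos else float("nan"),
        "fdr": float(fp / called_pos) if called_pos else 0.0,
        "n_planted_degs": n_pos,
    }


def pas_recovery(pas_clusters, pas_truth: pd.DataFrame,
                 min_support: int = 3, tolerance: int = 10) -> dict:
    """Distance from supported PAS representatives to the nearest planted site."""
    dists = []
    truth_by_key: dict[tuple[str, str], np.ndarray] = {}
    for (chrom, kind), sub in pas_truth.groupby(["chrom", "kind"]):
        truth_by_key[(chrom, kind)] = np.sort(sub["position"].values)
    for cl in pas_clusters:
        if cl.support < min_support:
            continue
        sites = truth_by_key.get((cl.chrom, cl.kind))
        if sites is None or len(sites) == 0:
            dists.append(np.inf)
            continue
        dists.append(float(np.min(np.abs(sites - cl.position))))
    dists = np.array(dists)
    return {
        "n_clusters": int(dists.size),
        "fraction_within_tolerance": float((dists <= tolerance).mean())
        if dists.size
        else float("nan"),
        "median_distance": float(np.median(dists)) if dists.size else float("nan"),
    }


def direction_recovery(assigned: dict, truth: pd.DataFrame,
                       directions: dict) -> dict:
    """Accuracy of inferred lncRNA strands among direction-assigned matches."""
    n_ok = n_assigned = 0
    for lid, cand in assigned.items():
        strand = directions.get(cand.id, ".")
        if strand == ".":
            continue
        n_assigned += 1
        if strand == truth.loc[lid, "strand"]:
            n_ok += 1
    return {
        "n_assigned": n_assigned,
        "accuracy": float(n_ok / n_assigned) if n_assigned else float("nan"),
        "assigned_fraction": float(n_assigned / len(assigned))
        if assigned
        else float("nan"),
    }


def priming_specificity(truth_tails: pd.DataFrame, tails_detected,
                        tails_kept) -> dict:
    """How completely genomically templated tails were removed."""
    artifact_ids = set(
        truth_tails.loc[truth_tails["is_artifact"], "read_id"]
    )
    detected_art = sum(1 for t in tails_detected if t.read_id in artifact_ids)
    kept_art = sum(1 for t in tails_kept if t.read_id in artifact_ids)
    true_ids = set(truth_tails.loc[~truth_tails["is_artifact"], "read_id"])
    kept_true = sum(1 for t in tails_kept if t.read_id in true_ids)
    detected_true = sum(1 for t in tails_detected if t.read_id in true_ids)
    return {
        "artifacts_detected": detected_art,
        "removal_specificity": float(1 - kept_art / detected_art)
        if detected_art
        else float("nan"),
        "true_tail_retention": float(kept_true / detected_true)
        if detected_true
        else float("nan"),
    }


def junction_recovery(truth_junctions: pd.DataFrame, called_junctions,
                      min_truth_reads: int = 2) -> dict:
    """Exact recovery of planted junctions plus count concordance (PCC)."""
    truth_tot = (
        truth_junctions.groupby(["chrom", "donor", "acceptor"])["count"]
        .sum()
        .sort_index()
    )
    called = {sj.key: sj.total_count for sj in called_junctions}
    solid = truth_tot[truth_tot >= min_truth_reads]
    recovered = sum(1 for key in solid.index if key in called)
    both = [(truth_tot[k], called[k]) for k in truth_tot.index if k in called]
    if len(both) >= 3:
        x, y = np.array(both).T
        pcc = float(np.corrcoef(x, y)[0, 1])
    else:
        pcc = float("nan")
    return {
        "n_truth_junctions": int(len(solid)),
        "recovered_fraction": float(recovered / len(solid)) if len(solid)
        else float("nan"),
        "count_pcc": pcc,
    }


def ase_recovery(as_truth: pd.DataFrame, ase_events) -> dict:
    """Fraction of planted AS events called with the correct type."""
    called = {(e.gene, e.type) for e in ase_events}
    hits = sum(
        1
        for _, row in as_truth.iterrows()
        if (row["gene"], row["type"]) in called
    )
    return {
        "n_planted": int(len(as_truth)),
        "recovered_fraction": float(hits / len(as_truth))
        if len(as_truth)
        else float("nan"),
    }


def recovery_report(dataset, result) -> dict:
    """Full truth-vs-called report for one simulated dataset + pipeline run."""
    truth = dataset.truth
    labels = truth.labels
    report: dict = {}

    if result.waves.get("F") is not None:
        report["gene_waves"] = wave_recovery(labels, result.waves["F"])
        report["deg_48v24_female"] = deg_recovery(
            labels,
            result.deg["F"][(48, 24)],
            expected_up={"wave1", "wave2"},
            expected_down={"maternal_degradation"},
        )

    assigned = match_candidates_to_truth(result.candidates, truth.lncrnas)
    report["lncrna_discovery"] = {
        "n_planted": int(len(truth.lncrnas)),
        "n_candidates": len(result.candidates),
        "sensitivity": float(len(assigned) / len(truth.lncrnas)),
    }
    locus_expect = {
        "intronic_sense": "intronic",
        "intronic_antisense": "intronic",
        "multi_exon": "intronic",
        "intergenic": "intergenic",
    }
    locus_ok = [
        assigned[lid].locus_class
        == locus_expect[truth.lncrnas.loc[lid, "class"]]
        for lid in assigned
    ]
    report["lncrna_discovery"]["locus_accuracy"] = (
        float(np.mean(locus_ok)) if locus_ok else float("nan")
    )

    # lncRNA wave labels, judged on matched candidates in female samples
    if result.lnc_waves.get("F") is not None:
        lnc_truth_waves = {}
        for lid, cand in assigned.items():
            label = labels.get(lid, "")
            if label.startswith("female_specific_lncRNA:"):
                lnc_truth_waves[cand.id] = label.split(":", 1)[1]
        called = result.lnc_waves["F"]
        hits = [
            called.get(cid) == wave for cid, wave in lnc_truth_waves.items()
        ]
        report["lncrna_waves"] = {
            "n_evaluable": len(hits),
            "accuracy": float(np.mean(hits)) if hits else float("nan"),
        }

    report["direction"] = direction_recovery(
        assigned, truth.lncrnas, result.directions
    )
    report["pas"] = pas_recovery(result.pas_clusters, truth.pas)
    report["internal_priming"] = priming_specificity(
        truth.tail_reads, result.tails, result.tails_kept
    )
    report["junctions"] = junction_recovery(truth.junctions, result.junctions)
    report["as_events"] = ase_recovery(dataset.toy.as_truth, result.ase_events)

    # combined wave-label recovery across coding genes and lncRNAs
    parts = []
    if "gene_waves" in report:
        gw = report["gene_waves"]
        parts.append((gw["accuracy"], gw["n_planted"]))
    if "lncrna_waves" in report and report["lncrna_waves"]["n_evaluable"]:
        lw = report["lncrna_waves"]
        parts.append((lw["accuracy"], lw["n_evaluable"]))
    if parts:
        tot = sum(n for _, n in parts)
        report["combined_wave_accuracy"] = float(
            sum(a * n for a, n in parts) / tot
        )

    if result.host_pairs is not None and len(result.host_pairs):
        report["host_pairs_non_correlated_fraction"] = float(
            (result.host_pairs["relation"] == "non_correlated").mean()
        )
    if result.tail_anova:
        report["tail_anova_p"] = result.tail_anova
    if result.splicing_stats is not None:
        report["mean_spliced_read_fraction"] = float(
            result.splicing_stats["spliced_read_fraction"].mean()
        )
    return report
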