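"""Read counting, normalization, NB differential expression and wave calls.

Differential expression follows the exact conditional negative-binomial
test: replicate counts are normalized by size factors, pooled per group,
and the observed split of the gene's total between groups is compared
with its conditional null distribution.  Genes are then classified into
zygotic-activation waves from the three pairwise calls 48vs24, 72vs48
and 72vs24 within one sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .core import Annotation

log = logging.getLogger(__name__)

WAVE_LABELS = ("wave1", "wave2", "wave3", "maternal_degradation", "none")


@dataclass
class ExpressionMatrix:
    """Raw counts (genes x samples) with metadata and derived layers."""

    counts: pd.DataFrame
    gene_lengths: pd.Series  # exonic union length per gene, nt
    samples: pd.DataFrame  # index sample_id; columns sex, hours, queen, replicate

    def __post_init__(self) -> None:
        self.counts = self.counts.loc[:, self.samples.index]
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        self.gene_lengths = self.gene_lengths.loc[self.counts.index]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def rpkm_layer(self) -> pd.DataFrame:
        return rpkm(self.counts, self.gene_lengths, self.library_sizes)

    def tpm_layer(self) -> pd.DataFrame:
        return tpm(self.counts, self.gene_lengths)

    def samples_where(self, **conditions) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        for col, val in conditions.items():
            mask &= self.samples[col] == val
        return list(self.samples.index[mask])


def count_reads(
    alignments,
    annotation: Annotation,
    chrom_lengths: dict[str, int],
    sample_of_read=None,
    min_overlap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Count unique reads per gene per sample by majority exonic overlap.

    A read increments a gene iff at least ``min_overlap_fraction`` of its
    aligned bases fall in that gene's exonic union and no other gene ties
    it.  Reads overlapping no gene are not counted.
    """
    genes = sorted(annotation.genes)
    if not genes:
        raise ValueError("empty annotation")
    gene_idx = {g: i for i, g in enumerate(genes)}
    maps = {c: np.full(n, -1, dtype=np.int32) for c, n in chrom_lengths.items()}
    for g in genes:
        for iv in annotation.exonic_union(g):
            maps[iv.chrom][iv.start : iv.end] = gene_idx[g]
    counts: dict[str, np.ndarray] = {}
    n_genes = len(genes)
    for rec in alignments:
        arr = maps.get(rec.chrom)
        if arr is None:
            raise ValueError(f"unknown reference {rec.chrom}")
        sample = sample_of_read(rec) if sample_of_read else (rec.sample_id or "sample")
        if sample not in counts:
            counts[sample] = np.zeros(n_genes, dtype=np.int64)
        hits = np.concatenate([arr[b.start : b.end] for b in rec.blocks])
        per_gene = np.bincount(hits[hits >= 0], minlength=n_genes)
        if per_gene.sum() == 0:
            continue
        best = int(per_gene.argmax())
        best_n = per_gene[best]
        if best_n < min_overlap_fraction * hits.size:
            continue
        per_gene[best] = 0
        if per_gene.max() == best_n:  # tie between two genes: drop
            continue
        counts[sample][best] += 1
    return pd.DataFrame(
        {s: counts[s] for s in sorted(counts)}, index=pd.Index(genes, name="gene")
    )


def rpkm(counts: pd.DataFrame, lengths: pd.Series, library_sizes: pd.Series):
    """Reads per kilobase of exon model per million mapped reads."""
    lengths = lengths.loc[counts.index]
    if (lengths <= 0).any():
        raise ValueError("non-positive gene length")
    if (library_sizes <= 0).any():
        raise ValueError("non-positive library size")
    denom = np.outer(lengths / 1e3, library_sizes / 1e6)
    return pd.DataFrame(
        counts.values / denom, index=counts.index, columns=counts.columns
    )


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million; each column sums to 1e6 (all-zero columns stay zero)."""
    lengths = lengths.loc[counts.index]
    if (lengths <= 0).any():
        raise ValueError("non-positive gene length")
    rate = counts.values / lengths.values[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        log.warning("all-zero sample(s) in TPM: %s", list(counts.columns[zero]))
        colsum[zero] = 1.0
    return pd.DataFrame(
        rate / colsum * 1e6, index=counts.index, columns=counts.columns
    )


def deseq_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean pseudo-reference.

    Genes with any zero count are excluded from the reference.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError(
            "no gene with all-positive counts; filter low-coverage genes first"
        )
    logc = np.log(positive.values.astype(float))
    log_geomean = logc.mean(axis=1)
    factors = np.exp(np.median(logc - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def detect_expressed(rpkm_layer: pd.DataFrame, threshold: float = 0.1):
    """Strict RPKM > threshold detection; returns (mask, summary)."""
    detected = rpkm_layer > threshold
    summary = {
        "per_sample_rate": detected.mean(axis=0),
        "union_rate": float(detected.any(axis=1).mean()),
        "union_count": int(detected.any(axis=1).sum()),
        "n_genes": int(detected.shape[0]),
    }
    return detected, summary


def estimate_dispersions(
    counts: pd.DataFrame,
    groups: dict[str, list[str]],
    size_factors: pd.Series | None = None,
    fallback: float = 0.1,
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments, shrunk toward the trend.

    Within-group moments are computed on normalized counts and averaged
    over groups with >= 2 replicates; the per-gene raw estimate is then
    blended with the across-gene mean dispersion (weight ``shrink_weight``
    on the trend).  With no replicated group, ``fallback`` is used.
    """
    if size_factors is None:
        size_factors = pd.Series(1.0, index=counts.columns)
    raw = np.full(counts.shape[0], np.nan)
    per_group = []
    for cols in groups.values():
        if len(cols) < 2:
            continue
        norm = counts[cols].values / size_factors[cols].values
        mean = norm.mean(axis=1)
        var = norm.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (var - mean) / mean**2
        phi[~np.isfinite(phi)] = np.nan
        per_group.append(phi)
    if per_group:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN genes
            raw = np.nanmean(np.vstack(per_group), axis=0)
    raw = np.clip(raw, 0.0, None)
    trend = float(np.nanmean(raw)) if np.isfinite(raw).any() else fallback
    shrunk = np.where(
        np.isnan(raw), fallback, (1 - shrink_weight) * raw + shrink_weight * trend
    )
    return pd.Series(np.clip(shrunk, 1e-8, None), index=counts.index,
                     name="dispersion")


def _nb_logpmf_cumulative(total: int, mu: float, r: float) -> np.ndarray:
    """Unnormalized log NB pmf at k = 0..total via the pmf ratio recurrence.

    Stable for arbitrarily large r (the Poisson limit), where direct
    gammaln differences lose precision.
    """
    if total == 0:
        return np.zeros(1)
    k = np.arange(total, dtype=float)
    log_ratio = np.log((k + r) / (k + 1)) + np.log(mu / (mu + r))
    return np.concatenate([[0.0], np.cumsum(log_ratio)])


def nb_exact_test(
    counts_a,
    counts_b,
    size_factors_a=None,
    size_factors_b=None,
    dispersion: float = 0.1,
    pseudocount: float = 1.0,
) -> tuple[float, float]:
    """Two-sided exact NB test of group B vs group A for one gene.

    Replicates are normalized and pooled; conditioning on the gene's
    total, the p-value sums the probabilities of all splits no more
    likely than the observed one.  Returns ``(log2_fold_change, p)``
    with fold change = (mean_B + pseudocount) / (mean_A + pseudocount)
    on normalized counts.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative counts")
    sfa = np.ones_like(a) if size_factors_a is None else np.asarray(size_factors_a)
    sfb = np.ones_like(b) if size_factors_b is None else np.asarray(size_factors_b)
    norm_a, norm_b = a / sfa, b / sfb
    mean_a, mean_b = norm_a.mean(), norm_b.mean()
    log2fc = float(np.log2((mean_b + pseudocount) / (mean_a + pseudocount)))
    ka = int(round(norm_a.sum()))
    kb = int(round(norm_b.sum()))
    total = ka + kb
    if total == 0:
        return log2fc, 1.0
    n_a, n_b = len(a), len(b)
    mu = total / (n_a + n_b)  # common per-replicate mean under the null
    # pooled group totals: sum of n iid NB(mu, phi) is NB(n*mu, phi/n)
    logw = (
        _nb_logpmf_cumulative(total, n_a * mu, n_a / dispersion)
        + _nb_logpmf_cumulative(total, n_b * mu, n_b / dispersion)[::-1]
    )
    logw -= logsumexp(logw)
    obs = logw[ka]
    p = float(np.exp(logw[logw <= obs + 1e-8]).sum())
    return log2fc, min(p, 1.0)


def deg_table(
    matrix: ExpressionMatrix,
    samples_a: list[str],
    samples_b: list[str],
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    fallback_dispersion: float = 0.1,
) -> pd.DataFrame:
    """Per-gene exact NB test of B vs A with BH adjustment."""
    counts = matrix.counts
    if size_factors is None:
        size_factors = deseq_size_factors(counts[samples_a + samples_b])
    if dispersions is None:
        dispersions = estimate_dispersions(
            counts,
            {"a": samples_a, "b": samples_b},
            size_factors=size_factors,
            fallback=fallback_dispersion,
        )
    rows = []
    sfa = size_factors[samples_a].values
    sfb = size_factors[samples_b].values
    for gene in counts.index:
        l2fc, p = nb_exact_test(
            counts.loc[gene, samples_a].values,
            counts.loc[gene, samples_b].values,
            sfa,
            sfb,
            dispersion=float(dispersions[gene]),
        )
        rows.append((gene, l2fc, p))
    df = pd.DataFrame(rows, columns=["gene", "log2_fold_change", "p_value"])
    df["adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.set_index("gene")


def call_degs(test_results: pd.DataFrame, mode: str = "fdr") -> pd.DataFrame:
    """Classify genes as up / down / ns under one of the two criteria.

    ``rawp``: fold change > 2 or < 0.5 and p < 0.01 (both strict);
    ``fdr``: BH-adjusted p < 0.05 and |log2FC| > 1.
    """
    df = test_results.copy()
    fc = 2.0 ** df["log2_fold_change"]
    if mode == "rawp":
        sig = df["p_value"] < 0.01
        up = sig & (fc > 2.0)
        down = sig & (fc < 0.5)
    elif mode == "fdr":
        sig = df["adjusted_p"] < 0.05
        up = sig & (df["log2_fold_change"] > 1.0)
        down = sig & (df["log2_fold_change"] < -1.0)
    else:
        raise ValueError(f"unknown DEG mode {mode!r}")
    df["class"] = np.where(up, "up", np.where(down, "down", "ns"))
    return df


def assign_waves(
    deg_48v24: pd.DataFrame, deg_72v48: pd.DataFrame, deg_72v24: pd.DataFrame
) -> pd.Series:
    """Zygotic-activation wave labels from three pairwise DEG calls.

    wave1: up 24->48 then down 48->72 (activated, then re-silenced);
    wave2: up 24->48, sustained to 72; wave3: activated only 48->72;
    maternal_degradation: declining from 24 h.  Precedence
    wave1 > wave2 > wave3 > MD; everything else "none".
    """
    for df in (deg_72v48, deg_72v24):
        if not df.index.equals(deg_48v24.index):
            raise ValueError("DEG tables cover different gene sets")
    c1 = deg_48v24["class"]
    c2 = deg_72v48["class"]
    c3 = deg_72v24["class"]
    labels = pd.Series("none", index=deg_48v24.index, name="wave")
    md = (c1 == "down") | ((c1 != "up") & (c3 == "down"))
    w3 = (c1 != "up") & (c2 == "up")
    w2 = (c1 == "up") & (c2 != "down")
    w1 = (c1 == "up") & (c2 == "down")
    labels[md] = "maternal_degradation"
    labels[w3] = "wave3"
    labels[w2] = "wave2"
    labels[w1] = "wave1"
    return labels


def ddct(
    ct_target: float,
    ct_reference: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Relative quantity by the 2^-ddCt method."""
    for v in (ct_target, ct_reference, ct_target_calibrator, ct_reference_calibrator):
        if not np.isfinite(v):
            raise ValueError("non-finite Ct value")
    ddct_val = (ct_target - ct_reference) - (
        ct_target_calibrator - ct_reference_calibrator
    )
    return float(2.0 ** (-ddct_val))
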