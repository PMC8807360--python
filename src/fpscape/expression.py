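"""Expression statistics stratified by CGI status and forest/prairie domain.

TPM conversion, the carcinogenesis fold change
``log2((mean TPM_cancer + 1) / (mean TPM_normal + 1))``, GTEx-style tissue
specificity ``s_it = (eps_it - mu_i) / mu_i`` (specific when s > 2), gene
classification into the four {F, P} x {CGI, non-CGI} groups, per-sample
group contrasts, fold change binned by exon CpG density, and significance
filtering of externally produced differential-expression tables (DESeq2
output is consumed, never re-fitted here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as ivl
from .genomeseg import CGITrack, DomainSet

CONTRASTS = [
    ("F-CGI", "F-non-CGI"),
    ("P-CGI", "P-non-CGI"),
    ("F-CGI", "P-CGI"),
    ("F-non-CGI", "P-non-CGI"),
]


@dataclass
class ExpressionTable:
    """Gene x sample counts with TPM layer and sample metadata.

    ``counts`` and ``tpm`` are genes x samples frames; ``samples`` maps
    sample name -> condition ("normal" / "cancer") and optional tissue.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame  # index: sample, columns: condition[, tissue]
    tpm: pd.DataFrame | None = None

    def condition_samples(self, condition: str) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == condition])


def counts_to_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from raw counts and effective gene lengths.

    ``TPM_g = (count_g / length_g) / sum_h (count_h / length_h) * 1e6``;
    every column sums to one million.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("all genes need a positive effective length")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        bad = list(denom.index[denom == 0])
        raise ValueError(f"all-zero samples: {bad}")
    return rate.div(denom, axis=1) * 1e6


def fold_change(expr: ExpressionTable) -> pd.Series:
    """Per-gene carcinogenesis fold change on mean TPM with +1 pseudocount."""
    if expr.tpm is None:
        raise ValueError("run counts_to_tpm first")
    normal = expr.condition_samples("normal")
    cancer = expr.condition_samples("cancer")
    if not normal or not cancer:
        raise ValueError("need at least one sample per condition")
    mean_n = expr.tpm[normal].mean(axis=1)
    mean_c = expr.tpm[cancer].mean(axis=1)
    return np.log2((mean_c + 1.0) / (mean_n + 1.0))


def tissue_specificity(
    tissue_means: pd.DataFrame, threshold: float = 2.0
) -> pd.DataFrame:
    """Tissue specificity ``s_it`` for every gene x tissue.

    ``s_it = (eps_it - mu_i) / mu_i`` with ``mu_i`` the gene's mean over all
    tissues; a gene is specific to tissue t when ``s_it`` strictly exceeds
    `threshold`.  Genes with ``mu_i = 0`` get NaN.  Returns a long frame
    with columns ``gene, tissue, s, specific``.
    """
    mu = tissue_means.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = tissue_means.sub(mu, axis=0).div(mu, axis=0)
    s[mu == 0] = np.nan
    long = s.stack(future_stack=True).rename("s").reset_index()
    long.columns = ["gene", "tissue", "s"]
    long["specific"] = long["s"] > threshold
    long.loc[long["s"].isna(), "specific"] = False
    return long


def complementary_specific_genes(
    spec: pd.DataFrame, focal_tissue: str
) -> set[str]:
    """Genes specific to at least one non-focal tissue but not the focal one."""
    by_gene = spec[spec["specific"]].groupby("gene")["tissue"].agg(set)
    return {
        g
        for g, tissues in by_gene.items()
        if focal_tissue not in tissues and len(tissues) > 0
    }


def classify_genes(
    genes: pd.DataFrame,
    cgi: CGITrack,
    domains: DomainSet,
    promoter: tuple[int, int] = (1000, 500),
    exons: dict[str, list[np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Attach CGI status, domain label and CpG densities to gene models.

    `genes` needs columns ``gene_id, chrom, strand, start, end, tss``;
    `exons` optionally maps gene_id -> interval array of merged exons (the
    gene body is used otherwise).  A gene is a CGI gene when any CGI
    overlaps its promoter (TSS - promoter[0] / + promoter[1], strand-aware)
    or its body by >= 1 bp.  The domain label follows the TSS; exon CpG
    density is CpGs per bp of merged exon; ``tss_cpg_density`` covers
    TSS +/- 1 kb.
    """
    up, down = promoter
    out = genes.copy()
    n = len(genes)
    cgi_flags = np.zeros(n, dtype=bool)
    dom_labels = np.full(n, None, dtype=object)
    exon_dens = np.full(n, np.nan)
    tss_dens = np.full(n, np.nan)
    for chrom, gidx in genes.groupby("chrom", sort=False).groups.items():
        sub = genes.loc[gidx]
        cgis = ivl.merge(cgi.cgi.get(chrom, np.empty((0, 2), np.int64)))
        pos = cgi.cpg_positions.get(chrom, np.empty(0, np.int64))
        tss = sub["tss"].to_numpy(np.int64)
        minus = (sub["strand"] == "-").to_numpy()
        prom_s = np.where(minus, tss - down, tss - up)
        prom_e = np.where(minus, tss + up, tss + down)
        span_s = np.maximum(np.minimum(prom_s, sub["start"].to_numpy()), 0)
        span_e = np.maximum(prom_e, sub["end"].to_numpy())
        pos_idx = np.asarray(gidx)
        if len(cgis):
            # overlap exists iff the first CGI ending after span_s starts
            # before span_e (CGIs sorted, non-overlapping)
            i0 = np.searchsorted(cgis[:, 1], span_s, side="right")
            hit = (i0 < len(cgis)) & (cgis[np.minimum(i0, len(cgis) - 1), 0] < span_e)
            cgi_flags[pos_idx] = hit
        doms = domains.domains.get(chrom, [])
        if doms:
            dom_arr = np.asarray([(s, e) for s, e, _ in doms], dtype=np.int64)
            labs = np.asarray([l for _, _, l in doms], dtype=object)
            loc = ivl.locate(tss, dom_arr)
            dom_labels[pos_idx] = np.where(loc >= 0, labs[np.clip(loc, 0, None)], None)
        if exons:
            for k, gid in zip(pos_idx, sub["gene_id"]):
                ex = exons.get(gid)
                ex = (
                    ivl.merge(ex)
                    if ex is not None and len(ex)
                    else np.asarray(
                        [[genes.at[k, "start"], genes.at[k, "end"]]], np.int64
                    )
                )
                ex_len = ivl.total_length(ex)
                n_cpg = sum(
                    int(np.searchsorted(pos, e) - np.searchsorted(pos, s))
                    for s, e in ex
                )
                exon_dens[k] = n_cpg / ex_len if ex_len > 0 else np.nan
        else:
            gs_, ge_ = sub["start"].to_numpy(), sub["end"].to_numpy()
            counts = np.searchsorted(pos, ge_) - np.searchsorted(pos, gs_)
            lens = (ge_ - gs_).astype(float)
            exon_dens[pos_idx] = np.where(lens > 0, counts / lens, np.nan)
        t0 = np.maximum(tss - 1000, 0)
        t1 = tss + 1000
        tss_dens[pos_idx] = (np.searchsorted(pos, t1) - np.searchsorted(pos, t0)) / (
            t1 - t0
        )
    out["cgi_gene"] = cgi_flags
    out["domain"] = dom_labels
    out["exon_cpg_density"] = exon_dens
    out["tss_cpg_density"] = tss_dens
    out["gene_class"] = [
        f"{d}-{'CGI' if c else 'non-CGI'}" if d else None
        for d, c in zip(dom_labels, cgi_flags)
    ]
    return out


def group_expression_contrasts(
    expr: ExpressionTable,
    classes: pd.Series,
    min_genes: int = 10,
) -> pd.DataFrame:
    """Per-sample mean-TPM differences between gene classes.

    `classes` maps gene_id -> four-class label.  For every sample the mean
    TPM of each class is computed (classes with fewer than `min_genes`
    genes are dropped with a warning) and the four standard contrasts are
    reported alongside the sample's condition.
    """
    if expr.tpm is None:
        raise ValueError("run counts_to_tpm first")
    classes = classes.reindex(expr.tpm.index)
    rows = []
    group_means = {}
    for cls, idx in classes.groupby(classes).groups.items():
        if len(idx) < min_genes:
            warnings.warn(f"group {cls} has {len(idx)} < {min_genes} genes: skipped")
            continue
        group_means[cls] = expr.tpm.loc[idx].mean(axis=0)
    for sample in expr.tpm.columns:
        row = {
            "sample": sample,
            "condition": expr.samples.loc[sample, "condition"],
        }
        for a, b in CONTRASTS:
            name = f"{a} - {b}"
            if a in group_means and b in group_means:
                row[name] = group_means[a][sample] - group_means[b][sample]
            else:
                row[name] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def fold_change_by_density(
    fc: pd.Series,
    classes: pd.DataFrame,
    density_edges: list[float] | np.ndarray,
) -> pd.DataFrame:
    """Mean/median fold change per (domain label, exon-CpG-density bin)."""
    df = classes[["domain", "exon_cpg_density"]].copy()
    df["fc"] = fc.reindex(classes.index)
    df = df.dropna(subset=["fc", "exon_cpg_density", "domain"])
    df["dbin"] = pd.cut(df["exon_cpg_density"], bins=np.asarray(density_edges))
    out = (
        df.groupby(["domain", "dbin"], observed=False)["fc"]
        .agg(["mean", "median", "count"])
        .reset_index()
    )
    out.loc[out["count"] == 0, ["mean", "median"]] = np.nan
    return out


def filter_significant(
    de_table: pd.DataFrame, p_thresh: float = 0.05, fc_thresh: float = 1.0
) -> tuple[set[str], set[str]]:
    """Split a DE table into up/down gene sets.

    Up: ``pvalue < p_thresh`` and ``log2FC > fc_thresh``; down: ``pvalue <
    p_thresh`` and ``log2FC < -fc_thresh``.  Needs columns ``gene_id,
    log2FC, pvalue``.
    """
    need = {"gene_id", "log2FC", "pvalue"}
    if not need.issubset(de_table.columns):
        raise ValueError(f"DE table needs columns {sorted(need)}")
    sig = de_table[de_table["pvalue"] < p_thresh]
    up = set(sig.loc[sig["log2FC"] > fc_thresh, "gene_id"])
    down = set(sig.loc[sig["log2FC"] < -fc_thresh, "gene_id"])
    return up, down


def common_de(per_cancer_sets: dict[str, set[str]], min_types: int = 7) -> set[str]:
    """Genes recurrent in strictly more than `min_types` cancer types."""
    counts: dict[str, int] = {}
    for genes in per_cancer_sets.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c > min_types}
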