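"""Readers, writers and the run manifest.

Plain-text dialects only: BED (intervals, 0-based half-open), chrom.sizes
TSV, bismark-style CpG reports (1-based positions, converted on read), COO
contact triplets with a bin table, GTF gene models, and generic TSV tables.
Every writer is the inverse of its reader on supported fields, and every
CLI run drops a ``manifest.json`` (config hash, seed, versions) so runs can
be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genomeseg import CGITrack, DomainSet
from .hicstruct import ContactMatrix


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path) -> dict[str, np.ndarray]:
    """BED intervals as per-chromosome sorted (n, 2) arrays."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby(0, sort=False):
        iv = sub[[1, 2]].to_numpy(np.int64)
        if np.any(np.diff(iv[:, 0]) < 0):
            warnings.warn(f"{path}: unsorted intervals on {chrom}, sorting")
            iv = iv[np.argsort(iv[:, 0])]
        out[str(chrom)] = iv
    return out


def write_bed(intervals: dict[str, np.ndarray], path, names=None) -> None:
    with open(path, "w") as fh:
        for chrom, iv in intervals.items():
            for k, (s, e) in enumerate(np.asarray(iv).reshape(-1, 2)):
                name = f"\t{names[chrom][k]}" if names else ""
                fh.write(f"{chrom}\t{s}\t{e}{name}\n")


def read_domains_bed(path) -> DomainSet:
    """Domains BED with the F/P label in the name column."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "label"]
    )
    domains = {
        str(chrom): [
            (int(r.start), int(r.end), str(r.label))
            for r in sub.sort_values("start").itertuples()
        ]
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    return DomainSet(domains=domains)


def write_domains_bed(ds: DomainSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, doms in ds.domains.items():
            for s, e, lab in doms:
                fh.write(f"{chrom}\t{s}\t{e}\t{lab}\n")


def read_cpg_report(path) -> pd.DataFrame:
    """Bismark-style CpG report: chrom, pos (1-based), strand, M, U.

    Positions are converted to 0-based on read.  A header line is optional.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "pos", "strand", "M", "U"],
        comment="#",
        dtype={"chrom": str},
    )
    if df.iloc[0]["chrom"] == "chrom":  # tolerate a header row
        df = df.iloc[1:].reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64) - 1
    df["M"] = df["M"].astype(np.int64)
    df["U"] = df["U"].astype(np.int64)
    return df


def write_cpg_report(table: pd.DataFrame, path) -> None:
    """Write per-CpG counts as a 1-based CpG report (plus strand)."""
    out = table[["chrom", "pos", "M", "U"]].copy()
    out["pos"] = out["pos"] + 1
    out["strand"] = "+"
    out[["chrom", "pos", "strand", "M", "U"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_coo_matrix(path, bins_path, resolution: int | None = None) -> ContactMatrix:
    """COO triplets (bin_i, bin_j, count) + bin table -> dense matrices.

    Bin indices are global over the bin table; triplets are mirrored so the
    matrices come back symmetric regardless of which triangle was stored.
    """
    bins = pd.read_csv(
        bins_path, sep="\t", header=None, names=["chrom", "start", "end"]
    )
    if resolution is None:
        resolution = int((bins["end"] - bins["start"]).max())
    coo = pd.read_csv(
        path, sep="\t", header=None, names=["i", "j", "count"]
    )
    matrices = {}
    offset = 0
    for chrom, sub in bins.groupby("chrom", sort=False):
        n = len(sub)
        mat = np.zeros((n, n))
        sel = coo[(coo["i"] >= offset) & (coo["i"] < offset + n)]
        i = sel["i"].to_numpy() - offset
        j = sel["j"].to_numpy() - offset
        c = sel["count"].to_numpy(float)
        mat[i, j] = c
        mat[j, i] = c
        matrices[str(chrom)] = mat
        offset += n
    return ContactMatrix(resolution=resolution, matrices=matrices)


def write_coo_matrix(cm: ContactMatrix, path, bins_path) -> None:
    """Write the upper triangle of every chromosome plus the bin table."""
    offset = 0
    with open(path, "w") as fh, open(bins_path, "w") as bh:
        for chrom, mat in cm.matrices.items():
            n = len(mat)
            for k in range(n):
                s = k * cm.resolution
                bh.write(f"{chrom}\t{s}\t{s + cm.resolution}\n")
            iu = np.triu_indices(n)
            vals = mat[iu]
            nz = vals != 0
            for i, j, c in zip(iu[0][nz] + offset, iu[1][nz] + offset, vals[nz]):
                fh.write(f"{i}\t{j}\t{c:.6g}\n")
            offset += n


def write_gtf(genes: pd.DataFrame, path, source: str = "fpscape") -> None:
    """Emit one gene + one exon (= body) feature per gene model."""
    with open(path, "w") as fh:
        for _, g in genes.iterrows():
            attrs = f'gene_id "{g["gene_id"]}";'
            for feat in ("gene", "exon"):
                fh.write(
                    f'{g["chrom"]}\t{source}\t{feat}\t{g["start"] + 1}\t'
                    f'{g["end"]}\t.\t{g["strand"]}\t.\t{attrs}\n'
                )


def read_gtf(path) -> pd.DataFrame:
    """Gene models (gene_id, chrom, strand, start, end, tss) from a GTF."""
    cols = [
        "chrom",
        "source",
        "feature",
        "start",
        "end",
        "score",
        "strand",
        "frame",
        "attrs",
    ]
    df = pd.read_csv(
        path, sep="\t", header=None, names=cols, comment="#", dtype={"chrom": str}
    )
    df = df[df["feature"] == "gene"].copy()
    df["gene_id"] = df["attrs"].str.extract(r'gene_id "([^"]+)"')
    df["start"] = df["start"].astype(np.int64) - 1
    df["end"] = df["end"].astype(np.int64)
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df[["gene_id", "chrom", "strand", "start", "end", "tss"]].reset_index(
        drop=True
    )


def write_counts(counts: pd.DataFrame, samples: pd.DataFrame, prefix) -> None:
    counts.to_csv(f"{prefix}.counts.tsv", sep="\t")
    samples.to_csv(f"{prefix}.samples.tsv", sep="\t")


def read_counts(prefix):
    counts = pd.read_csv(f"{prefix}.counts.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(f"{prefix}.samples.tsv", sep="\t", index_col=0)
    return counts, samples


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir, config: dict, seed: int | None, n_warnings: int = 0):
    """Machine-readable record of a run: config hash, seed, versions."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "fpscape_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": {k: str(v) for k, v in sorted(config.items())},
        "n_warnings": n_warnings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
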