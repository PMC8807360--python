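"""Per-CpG methylation levels and domain-scale methylation statistics.

The methylation level of a CpG site is ``beta = M / (M + U) * 100%`` with M
and U the methylated/unmethylated read counts; only sites with coverage
strictly greater than a threshold (default 3) contribute.  On top of the
forest/prairie segmentation this module computes:

* per-domain *open-sea* methylation ``q`` (mean beta over CpGs outside CGIs
  and their +/-4 kb flanks),
* the **MDI** of domain *i*,
  ``MDI_i = (q_i - (q_{i-1} + q_{i+1})/2) / ((q_i + q_{i-1} + q_{i+1})/3)``,
  a scale-invariant contrast of a domain against its two neighbours — in
  normal tissue forest MDIs are positive and grow as prairies demethylate,
* per-group methylation-change distributions (compartment-switch classes
  AA/AB/BA/BB, CpG-density strata, ...),
* solo-WCGW site calls (isolated CpGs in an A/T context, the most
  demethylation-prone class),
* signal profiles stratified jointly by methylation level and a grouping
  such as CpG-density class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as ivl
from .genomeseg import DomainSet

CHANGE_HIST_EDGES = np.round(np.arange(-1.0, 1.0001, 0.05), 10)


@dataclass
class MethylomeTrack:
    """Per-CpG (M, U) counts with derived beta and a coverage mask.

    ``table`` holds columns ``chrom, pos, M, U, coverage, beta`` where beta
    (percent) is NaN at sites whose coverage does not exceed
    ``min_coverage``.
    """

    table: pd.DataFrame
    min_coverage: int = 3

    def betas(self, chrom: str) -> pd.DataFrame:
        sub = self.table[self.table["chrom"] == chrom]
        return sub[["pos", "beta"]]


@dataclass
class DomainMethylation:
    """Per-domain open-sea methylation and MDI.

    ``table``: chrom, start, end, label, q (fraction), n_cpg, mdi.
    """

    table: pd.DataFrame
    min_cpg: int = 1


def load_methylome(records: pd.DataFrame, min_coverage: int = 3) -> MethylomeTrack:
    """Build a :class:`MethylomeTrack` from per-CpG count records.

    `records` needs columns ``chrom, pos, M, U`` (0-based positions; file
    readers convert from 1-based) and optionally ``strand``: minus-strand
    calls are shifted to the plus-strand C of the same CpG dinucleotide and
    the two strands' counts are summed before the coverage filter.
    """
    df = records.copy()
    required = {"chrom", "pos", "M", "U"}
    if not required.issubset(df.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    if (df["M"] < 0).any() or (df["U"] < 0).any():
        raise ValueError("negative methylation counts")
    if "strand" in df.columns:
        df.loc[df["strand"] == "-", "pos"] -= 1
    df = df.sort_values(["chrom", "pos"], ignore_index=True)
    if df.duplicated(["chrom", "pos"]).any():
        df = df.groupby(["chrom", "pos"], as_index=False)[["M", "U"]].sum()
    else:
        df = df[["chrom", "pos", "M", "U"]]
    df["coverage"] = df["M"] + df["U"]
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = df["M"] / df["coverage"] * 100.0
    df["beta"] = beta.where(df["coverage"] > min_coverage)
    assert ((df["beta"].dropna() >= 0) & (df["beta"].dropna() <= 100)).all()
    return MethylomeTrack(table=df, min_coverage=min_coverage)


def domain_open_sea_methylation(
    meth: MethylomeTrack,
    domains: DomainSet,
    open_sea: dict[str, np.ndarray],
    min_cpg: int = 10,
) -> DomainMethylation:
    """Mean open-sea methylation ``q`` (fraction) per forest/prairie domain.

    ``q`` is the unweighted mean beta over covered open-sea CpGs inside the
    domain; domains with fewer than `min_cpg` contributing CpGs get
    ``q = NaN``.  The MDI column is initialised to NaN — fill it with
    :func:`compute_mdi`.
    """
    rows = []
    for chrom, doms in domains.domains.items():
        sub = meth.table[meth.table["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        beta = sub["beta"].to_numpy()
        os_iv = open_sea.get(chrom, np.empty((0, 2), np.int64))
        in_os = ivl.locate(pos, os_iv) >= 0
        ok = in_os & ~np.isnan(beta)
        pos_ok, beta_ok = pos[ok], beta[ok]
        for s, e, lab in doms:
            lo, hi = np.searchsorted(pos_ok, [s, e])
            n = hi - lo
            q = beta_ok[lo:hi].mean() / 100.0 if n >= min_cpg else np.nan
            rows.append((chrom, s, e, lab, q, int(n), np.nan))
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "label", "q", "n_cpg", "mdi"]
    )
    return DomainMethylation(table=table, min_cpg=min_cpg)


def compute_mdi(dm: DomainMethylation) -> DomainMethylation:
    """Fill the MDI column from each interior domain's q and its neighbours.

    Terminal domains and domains with an undefined own or flanking q stay
    NaN.  A 0/0 case (all three q zero) is left NaN with a warning.
    """
    table = dm.table.copy()
    n_degenerate = 0
    for chrom, idx in table.groupby("chrom", sort=False).groups.items():
        q = table.loc[idx, "q"].to_numpy(float)
        mdi = np.full(len(q), np.nan)
        for i in range(1, len(q) - 1):
            trio = q[[i - 1, i, i + 1]]
            if np.isnan(trio).any():
                continue
            denom = trio.sum() / 3.0
            if denom == 0:
                n_degenerate += 1
                continue
            mdi[i] = (trio[1] - (trio[0] + trio[2]) / 2.0) / denom
        table.loc[idx, "mdi"] = mdi
    if n_degenerate:
        warnings.warn(f"{n_degenerate} domains with all-zero q: MDI undefined")
    return DomainMethylation(table=table, min_cpg=dm.min_cpg)


def averaged_mdi(dm: DomainMethylation, label: str) -> float:
    """Genome-wide mean of defined MDIs over domains with the given label."""
    sel = dm.table[(dm.table["label"] == label) & dm.table["mdi"].notna()]
    if len(sel) == 0:
        raise ValueError(f"no defined MDIs for label {label!r}")
    return float(sel["mdi"].mean())


def methylation_change_by_group(
    meth_a: MethylomeTrack,
    meth_b: MethylomeTrack,
    grouping: pd.DataFrame,
    open_sea: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Distribution of per-bin methylation change (b - a) for each group.

    `grouping` needs columns ``chrom, start, end, group`` (any per-bin
    labelling: compartment-switch classes, density groups, ...).  Shared
    covered CpGs — optionally restricted to `open_sea` — are averaged within
    each grouping bin (beta as fraction); per group the mean, median, count
    and a fixed-edge histogram over [-1, 1] (width 0.05) are reported.
    Groups without any covered CpGs are reported empty.
    """
    a = meth_a.table[["chrom", "pos", "beta"]].rename(columns={"beta": "beta_a"})
    b = meth_b.table[["chrom", "pos", "beta"]].rename(columns={"beta": "beta_b"})
    m = a.merge(b, on=["chrom", "pos"]).dropna(subset=["beta_a", "beta_b"])
    out = []
    for group, gsub in grouping.groupby("group", sort=True):
        deltas = []
        for chrom, csub in gsub.groupby("chrom", sort=False):
            mm = m[m["chrom"] == chrom]
            pos = mm["pos"].to_numpy()
            if open_sea is not None:
                keep = ivl.locate(pos, open_sea.get(chrom, np.empty((0, 2)))) >= 0
                mm = mm[keep]
                pos = mm["pos"].to_numpy()
            delta = (mm["beta_b"].to_numpy() - mm["beta_a"].to_numpy()) / 100.0
            iv = csub[["start", "end"]].to_numpy()
            order = np.argsort(iv[:, 0])
            idx = ivl.locate(pos, iv[order])
            ok = idx >= 0
            if ok.sum() == 0:
                continue
            df = pd.DataFrame({"bin": idx[ok], "delta": delta[ok]})
            deltas.append(df.groupby("bin")["delta"].mean().to_numpy())
        if deltas:
            vals = np.concatenate(deltas)
            hist, _ = np.histogram(vals, bins=CHANGE_HIST_EDGES)
            out.append(
                {
                    "group": group,
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "median": float(np.median(vals)),
                    "hist": hist,
                }
            )
        else:
            out.append(
                {"group": group, "n": 0, "mean": np.nan, "median": np.nan, "hist": None}
            )
    return pd.DataFrame(out)


def find_solo_wcgw(context: pd.DataFrame, solo_window: int = 35) -> pd.DataFrame:
    """Call solo-WCGW sites from per-CpG sequence context.

    A CpG qualifies when its nearest CpG neighbours on both sides are more
    than `solo_window` bp away ("solo") and its immediate flanking bases
    form W-C-G-W with W in {A, T}.  `context` needs columns ``chrom, pos,
    left_base, right_base, dist_left, dist_right``; rows with missing
    context are skipped and counted in the ``n_skipped`` attribute of the
    returned frame.
    """
    df = context.copy()
    need = ["left_base", "right_base", "dist_left", "dist_right"]
    missing = df[need].isna().any(axis=1)
    df = df[~missing]
    w = {"A", "T"}
    is_w = df["left_base"].str.upper().isin(w) & df["right_base"].str.upper().isin(w)
    is_solo = (df["dist_left"] > solo_window) & (df["dist_right"] > solo_window)
    out = df[is_w & is_solo][["chrom", "pos"]].reset_index(drop=True)
    out.attrs["n_skipped"] = int(missing.sum())
    return out


def cpg_neighbor_distances(positions: np.ndarray) -> pd.DataFrame:
    """Distance to the nearest CpG on each side (inf at chromosome ends)."""
    pos = np.asarray(positions, dtype=np.int64)
    left = np.full(len(pos), np.inf)
    right = np.full(len(pos), np.inf)
    if len(pos) > 1:
        d = np.diff(pos).astype(float)
        left[1:] = d
        right[:-1] = d
    return pd.DataFrame({"pos": pos, "dist_left": left, "dist_right": right})


@dataclass
class StratifiedProfile:
    """Mean signal in cells of (stratum x methylation-level bin)."""

    means: pd.DataFrame  # strata rows x beta-bin columns
    counts: pd.DataFrame
    beta_edges: np.ndarray = field(default_factory=lambda: np.linspace(0, 100, 11))


def stratified_signal_profile(
    signal: np.ndarray,
    beta: np.ndarray,
    strata: np.ndarray,
    beta_edges: np.ndarray | None = None,
) -> StratifiedProfile:
    """Average a per-bin signal in cells of (stratum, methylation bin).

    All three inputs are aligned per-bin vectors (signal value, mean beta in
    percent, stratum label).  Cells without observations are NaN, not zero.
    """
    if beta_edges is None:
        beta_edges = np.linspace(0.0, 100.0, 11)
    signal = np.asarray(signal, float)
    beta = np.asarray(beta, float)
    strata = np.asarray(strata, object)
    ok = ~(np.isnan(signal) | np.isnan(beta)) & (strata != "NA")
    bin_idx = np.clip(
        np.digitize(beta[ok], beta_edges) - 1, 0, len(beta_edges) - 2
    )
    df = pd.DataFrame(
        {"stratum": strata[ok], "bbin": bin_idx, "signal": signal[ok]}
    )
    grp = df.groupby(["stratum", "bbin"])["signal"]
    means = grp.mean().unstack("bbin")
    counts = grp.size().unstack("bbin").fillna(0).astype(int)
    all_bins = range(len(beta_edges) - 1)
    means = means.reindex(columns=all_bins)
    counts = counts.reindex(columns=all_bins, fill_value=0)
    return StratifiedProfile(means=means, counts=counts, beta_edges=beta_edges)
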