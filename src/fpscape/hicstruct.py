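"""Contact-matrix statistics on the forest/prairie segmentation.

All operations work on binned, ICE-balanced intra-chromosomal contact
matrices (40-kb native resolution; compartments at 200 kb):

* :func:`preprocess` — SV masking, sparse-bin removal, iterative correction,
* :func:`call_compartments` — per-arm A/B eigenvector compartments,
* :func:`compartment_index` — ``CI_i = ln(<C to A> / <C to B>)``,
* :func:`distance_decay` / :func:`decay_slopes` — contact probability
  ``P(s)`` by pair type (FF/PP/FP) and its log-log slopes,
* :func:`segregation factors <distance_decay>` — ``SF_F = P_FF / P_FP``,
* :func:`cluster_samples_by_slopes` — single-linkage sample clustering,
* :func:`interaction_strength` — per-bin contact fractions to the four
  classes {F-CGI, F-non-CGI, P-CGI, P-non-CGI},
* :func:`classify_cgi_aggregation` — CGI bins whose same-type contacts rise
  in every cancer sample ("conservative" CGIs),
* :func:`detect_contact_loss` — bins whose mid-range (600 kb - 2 Mb)
  same-type contact drops below average in cancer,
* :func:`insulation_domain_pairs` / :func:`insulation_boundary_profile` —
  the insulation score ``IS = ln(1 + a1/b + a2/b)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from . import intervals as ivl
from .genomeseg import BinAnnotation, DomainSet

FOUR_CLASSES = ["F-CGI", "F-non-CGI", "P-CGI", "P-non-CGI"]

_EPS = 1e-9


@dataclass
class ContactMatrix:
    """Per-chromosome symmetric contact matrices with bin masks.

    ``matrices[chrom]`` is a dense symmetric array; ``bin_mask[chrom]`` is
    True at removed bins (outliers, SV overlaps).  ``arm_split[chrom]``
    holds the bin index of the centromere where known so eigenvector
    analysis can run per arm.
    """

    resolution: int
    matrices: dict[str, np.ndarray]
    bin_mask: dict[str, np.ndarray] = field(default_factory=dict)
    balanced: bool = False
    arm_split: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, mat in self.matrices.items():
            if not np.allclose(mat, mat.T, atol=1e-8):
                raise ValueError(f"matrix for {chrom} not symmetric")
            if np.any(mat < 0):
                raise ValueError(f"negative contacts on {chrom}")
            if chrom not in self.bin_mask:
                self.bin_mask[chrom] = np.zeros(len(mat), dtype=bool)

    def n_bins(self, chrom: str) -> int:
        return len(self.matrices[chrom])

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            resolution=self.resolution,
            matrices={c: m.copy() for c, m in self.matrices.items()},
            bin_mask={c: m.copy() for c, m in self.bin_mask.items()},
            balanced=self.balanced,
            arm_split=dict(self.arm_split),
        )


def ice_balance(
    mat: np.ndarray, mask: np.ndarray, n_iter: int = 50, tol: float = 1e-5
) -> np.ndarray:
    """Iterative correction: rescale rows/columns to equal visibility."""
    w = mat.copy().astype(float)
    keep = ~mask
    for _ in range(n_iter):
        s = w[np.ix_(keep, keep)].sum(axis=1)
        m = s[s > 0].mean() if np.any(s > 0) else 1.0
        s = s / m
        s[s == 0] = 1.0
        sub = w[np.ix_(keep, keep)]
        sub /= np.outer(s, s)
        w[np.ix_(keep, keep)] = sub
        if np.max(np.abs(s - 1.0)) < tol:
            break
    w[mask, :] = 0.0
    w[:, mask] = 0.0
    return w


def preprocess(
    cm: ContactMatrix,
    sv_regions: dict[str, np.ndarray] | None = None,
    outlier_quantile: float = 0.99,
    n_iter: int = 50,
    tol: float = 1e-5,
    min_bins: int = 10,
) -> ContactMatrix:
    """Mask SV/sparse bins and apply iterative-correction balancing.

    Bins overlapping `sv_regions` are masked, as are bins with zero contact
    to more than ``outlier_quantile`` of the other bins.  Chromosomes left
    with fewer than `min_bins` unmasked bins are dropped with a warning.
    """
    sv_regions = sv_regions or {}
    out_m, out_mask = {}, {}
    for chrom, mat in cm.matrices.items():
        n = len(mat)
        mask = cm.bin_mask[chrom].copy()
        if chrom in sv_regions and len(sv_regions[chrom]):
            starts = np.arange(n, dtype=np.int64) * cm.resolution
            ends = starts + cm.resolution
            cov = ivl.overlap_lengths(starts, ends, sv_regions[chrom])
            mask |= cov > 0
        zero_partners = (mat == 0).sum(axis=1) - (np.diag(mat) == 0)
        mask |= zero_partners > outlier_quantile * (n - 1)
        if (~mask).sum() < min_bins:
            warnings.warn(f"{chrom}: fewer than {min_bins} usable bins, dropped")
            continue
        out_m[chrom] = ice_balance(mat, mask, n_iter=n_iter, tol=tol)
        out_mask[chrom] = mask
    return ContactMatrix(
        resolution=cm.resolution,
        matrices=out_m,
        bin_mask=out_mask,
        balanced=True,
        arm_split={c: v for c, v in cm.arm_split.items() if c in out_m},
    )


def aggregate(cm: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum ``factor x factor`` blocks to a coarser resolution and re-balance.

    An aggregated bin is masked when more than half of its source bins are.
    """
    out_m, out_mask, arm = {}, {}, {}
    for chrom, mat in cm.matrices.items():
        n = len(mat)
        n_new = int(np.ceil(n / factor))
        pad = n_new * factor - n
        if pad:
            mat = np.pad(mat, ((0, pad), (0, pad)))
        agg = mat.reshape(n_new, factor, n_new, factor).sum(axis=(1, 3))
        msk = np.pad(cm.bin_mask[chrom], (0, pad), constant_values=True)
        frac = msk.reshape(n_new, factor).mean(axis=1)
        new_mask = frac > 0.5
        out_m[chrom] = ice_balance(agg, new_mask)
        out_mask[chrom] = new_mask
        if chrom in cm.arm_split:
            arm[chrom] = cm.arm_split[chrom] // factor
    return ContactMatrix(
        resolution=cm.resolution * factor,
        matrices=out_m,
        bin_mask=out_mask,
        balanced=True,
        arm_split=arm,
    )


# ---------------------------------------------------------------------------
# compartments


def _observed_expected(sub: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Divide each diagonal by its mean over unmasked entries."""
    n = len(sub)
    oe = np.zeros_like(sub, dtype=float)
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        ok = keep[i] & keep[j]
        vals = sub[i, j]
        mean = vals[ok].mean() if np.any(ok) else 0.0
        scaled = vals / (mean + _EPS)
        oe[i, j] = scaled
        oe[j, i] = scaled
    return oe


def call_compartments(
    cm: ContactMatrix,
    orientation: dict[str, np.ndarray],
    min_arm_bins: int = 20,
) -> pd.DataFrame:
    """A/B compartments from the leading eigenvector, per chromosome arm.

    The balanced matrix is distance-normalised (observed/expected), turned
    into a Pearson correlation matrix, and its first eigenvector is
    extracted separately for the p and q arms.  The eigenvector sign is
    oriented so that it correlates positively with `orientation` (typically
    per-bin CpG density, since compartment A is the CGI/gene-rich class);
    bins with positive components are labelled A.

    Returns a frame with columns ``chrom, bin, start, end, arm, V, label``
    (V is NaN at masked bins).  Arms shorter than `min_arm_bins` unmasked
    bins are skipped.
    """
    rows = []
    for chrom, mat in cm.matrices.items():
        n = len(mat)
        mask = cm.bin_mask[chrom]
        split = cm.arm_split.get(chrom, 0)
        arms = [("p", 0, split), ("q", split, n)] if 0 < split < n else [("q", 0, n)]
        orient = np.asarray(orientation[chrom], dtype=float)
        V = np.full(n, np.nan)
        labels = np.full(n, "NA", dtype=object)
        arm_of = np.full(n, "", dtype=object)
        for arm_name, a, b in arms:
            keep = ~mask[a:b]
            arm_of[a:b] = arm_name
            if keep.sum() < min_arm_bins:
                continue
            sub = mat[a:b, a:b]
            oe = _observed_expected(sub, keep)
            kept = np.flatnonzero(keep)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(oe[np.ix_(kept, kept)])
            corr = np.nan_to_num(corr)
            evals, evecs = np.linalg.eigh(corr)
            v = evecs[:, -1]
            if np.ptp(v) < 1e-12:
                warnings.warn(f"{chrom} {arm_name}-arm: no compartment signal")
                continue
            o = orient[a:b][keep]
            ok = ~np.isnan(o)
            if ok.sum() >= 2 and np.std(o[ok]) > 0 and np.std(v[ok]) > 0:
                if np.corrcoef(o[ok], v[ok])[0, 1] < 0:
                    v = -v
            V[a + kept] = v
            labels[a + kept] = np.where(v > 0, "A", "B")
        starts = np.arange(n, dtype=np.int64) * cm.resolution
        for i in range(n):
            rows.append(
                (
                    chrom,
                    i,
                    int(starts[i]),
                    int(starts[i]) + cm.resolution,
                    arm_of[i],
                    V[i],
                    labels[i],
                )
            )
    return pd.DataFrame(
        rows, columns=["chrom", "bin", "start", "end", "arm", "V", "label"]
    )


def compartment_index(cm: ContactMatrix, profile: pd.DataFrame) -> pd.DataFrame:
    """Per-bin compartment index, natural-log contrast of A vs B contact.

    ``CI_i = ln[(sum_{j!=i} C_ij d_j / N_A) / (sum_{j!=i} C_ij (1-d_j) / N_B)]``
    with ``d_j = 1`` for compartment-A bins; self-contact is excluded and the
    index is computed within each chromosome.  Bins with zero contact to one
    class are reported NaN.
    """
    out = profile.copy()
    out["CI"] = np.nan
    for chrom, mat in cm.matrices.items():
        sub = out[out["chrom"] == chrom].sort_values("bin")
        labels = sub["label"].to_numpy()
        idx = sub["bin"].to_numpy()
        is_a = labels == "A"
        is_b = labels == "B"
        n_a, n_b = int(is_a.sum()), int(is_b.sum())
        if n_a == 0 or n_b == 0:
            continue
        m = mat.copy()
        np.fill_diagonal(m, 0.0)
        # average over actual partners: a bin's own class excludes itself
        div_a = np.where(is_a, max(n_a - 1, 1), n_a)
        div_b = np.where(is_b, max(n_b - 1, 1), n_b)
        to_a = m[:, idx[is_a]].sum(axis=1)[idx] / div_a
        to_b = m[:, idx[is_b]].sum(axis=1)[idx] / div_b
        with np.errstate(divide="ignore", invalid="ignore"):
            ci = np.log(to_a / to_b)
        ci[~np.isfinite(ci)] = np.nan
        ci[labels == "NA"] = np.nan
        out.loc[sub.index, "CI"] = ci
    return out


def compartment_composition(
    profile: pd.DataFrame, classes: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Fraction of each bin class falling in compartment A vs B.

    `classes` is a per-bin labelling aligned with `profile` (F/P domain
    labels, the CGI four-class, ...).  Rows sum to 1 per class over the
    bins with a called compartment.
    """
    df = profile.copy()
    df["cls"] = np.asarray(classes, dtype=object)
    df = df[df["label"].isin(["A", "B"])]
    tab = df.groupby(["cls", "label"]).size().unstack("label").fillna(0)
    tab = tab.reindex(columns=["A", "B"], fill_value=0)
    frac = tab.div(tab.sum(axis=1), axis=0)
    frac.columns.name = None
    return frac


def mean_eigenvector_by_class(
    profile: pd.DataFrame, classes: pd.Series | np.ndarray
) -> pd.Series:
    """Mean compartment-vector component V per bin class."""
    df = profile.copy()
    df["cls"] = np.asarray(classes, dtype=object)
    return df.groupby("cls")["V"].mean()


def classify_switch(
    profile_normal: pd.DataFrame, profile_cancer: pd.DataFrame
) -> pd.DataFrame:
    """Per-bin compartment-switch class AA/AB/BA/BB between two samples."""
    key = ["chrom", "bin"]
    a = profile_normal[key + ["label"]].rename(columns={"label": "l_n"})
    b = profile_cancer[key + ["label"]].rename(columns={"label": "l_c"})
    m = a.merge(b, on=key, how="outer")
    if len(m) != len(a) or len(m) != len(b):
        raise ValueError("binning mismatch between profiles")
    ok = m["l_n"].isin(["A", "B"]) & m["l_c"].isin(["A", "B"])
    m["switch"] = np.where(ok, m["l_n"].fillna("") + m["l_c"].fillna(""), "NA")
    return m[key + ["switch"]]


# ---------------------------------------------------------------------------
# distance decay, slopes, clustering


def log_distance_edges(
    s_min: float = 80_000,
    s_max: float = 100_000_000,
    bins_per_octave: int = 2,
) -> np.ndarray:
    n = int(np.ceil(np.log2(s_max / s_min) * bins_per_octave))
    return s_min * 2 ** (np.arange(n + 1) / bins_per_octave)


def distance_decay(
    cm: ContactMatrix,
    bins: BinAnnotation,
    s_min: float = 80_000,
    s_max: float = 100_000_000,
    bins_per_octave: int = 2,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Mean contact probability P(s) by pair type and segregation factors.

    Contacts are pooled genome-wide into log-spaced distance bins
    (`bins_per_octave` per factor 2, default 80 kb - 100 Mb) and averaged
    over unmasked pairs, split by the two bins' domain labels into FF, PP
    and FP.  The diagonal (s = 0) is excluded.  Segregation factors
    ``SF_F = P_FF / P_FP`` and ``SF_P = P_PP / P_FP`` are computed per
    diagonal and pair-weight averaged into the distance bins (so a pure
    decay law yields SF identically 1 regardless of binning); they are NaN
    where ``P_FP`` is unavailable.  Distance bins with fewer than
    `min_pairs` pairs for a pair type are NaN.
    """
    edges = log_distance_edges(s_min, s_max, bins_per_octave)
    nb = len(edges) - 1
    sums = {t: np.zeros(nb) for t in ("FF", "PP", "FP")}
    counts = {t: np.zeros(nb, dtype=np.int64) for t in ("FF", "PP", "FP")}
    s_sums = {t: np.zeros(nb) for t in ("FF", "PP", "FP")}
    # segregation factors are built from per-diagonal observed/expected
    # values pooled within each bin, so the decay law cannot leak into them
    # through uneven pair-type composition across a coarse log bin
    oe_sums = {t: np.zeros(nb) for t in ("FF", "PP", "FP")}
    oe_wts = {t: np.zeros(nb) for t in ("FF", "PP", "FP")}
    for chrom, mat in cm.matrices.items():
        labels = bins.chrom_labels(chrom, "domain")[: len(mat)]
        keep = ~cm.bin_mask[chrom]
        n = len(mat)
        is_f = labels == "F"
        for d in range(1, n):
            s = d * cm.resolution
            k = np.searchsorted(edges, s, side="right") - 1
            if k < 0 or k >= nb:
                continue
            i = np.arange(n - d)
            j = i + d
            ok = keep[i] & keep[j]
            if not np.any(ok):
                continue
            vals = mat[i[ok], j[ok]]
            fi, fj = is_f[i[ok]], is_f[j[ok]]
            m_d = vals.mean()
            for t, sel in (
                ("FF", fi & fj),
                ("PP", ~fi & ~fj),
                ("FP", fi ^ fj),
            ):
                nsel = int(sel.sum())
                sums[t][k] += vals[sel].sum()
                counts[t][k] += nsel
                s_sums[t][k] += s * nsel
                if nsel and m_d > 0:
                    oe_sums[t][k] += vals[sel].sum() / m_d
                    oe_wts[t][k] += nsel
    s_mid = np.sqrt(edges[:-1] * edges[1:])
    out = {"s": s_mid}
    total_counts = sum(counts.values())
    total_s = sum(s_sums.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        # pair-weighted mean separation per bin: the honest abscissa for
        # slope fits (the geometric midpoint biases coarse log bins)
        out["s_mean"] = np.where(total_counts > 0, total_s / total_counts, s_mid)
    for t in ("FF", "PP", "FP"):
        with np.errstate(invalid="ignore", divide="ignore"):
            p = sums[t] / counts[t]
        p[counts[t] < min_pairs] = np.nan
        out[f"P_{t}"] = p
        out[f"n_{t}"] = counts[t]
    df = pd.DataFrame(out)
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = {
            t: np.where(oe_wts[t] > 0, oe_sums[t] / oe_wts[t], np.nan)
            for t in ("FF", "PP", "FP")
        }
        df["SF_F"] = oe["FF"] / oe["FP"]
        df["SF_P"] = oe["PP"] / oe["FP"]
    df.loc[df["P_FP"].isna(), ["SF_F", "SF_P"]] = np.nan
    return df


def default_slope_windows(
    s_min: float = 200_000, s_max: float = 20_000_000
) -> list[tuple[float, float]]:
    """Half-decade windows sliding by quarter decades over [s_min, s_max]."""
    windows = []
    lo = s_min
    while lo * np.sqrt(10.0) <= s_max * 1.0001:
        windows.append((lo, lo * np.sqrt(10.0)))
        lo *= 10.0 ** 0.25
    return windows


def decay_slopes(
    profile: pd.DataFrame,
    windows: list[tuple[float, float]] | None = None,
    column: str = "P_PP",
    min_points: int = 3,
) -> pd.DataFrame:
    """Least-squares log10 P vs log10 s slope in each distance window."""
    if windows is None:
        windows = default_slope_windows()
    s_col = "s_mean" if "s_mean" in profile.columns else "s"
    s = profile[s_col].to_numpy(float)
    p = profile[column].to_numpy(float)
    rows = []
    for lo, hi in windows:
        sel = (s >= lo) & (s <= hi) & np.isfinite(p) & (p > 0)
        if sel.sum() < min_points:
            rows.append((lo, hi, np.nan, int(sel.sum())))
            continue
        slope = np.polyfit(np.log10(s[sel]), np.log10(p[sel]), 1)[0]
        rows.append((lo, hi, float(slope), int(sel.sum())))
    return pd.DataFrame(rows, columns=["s_lo", "s_hi", "slope", "n_points"])


def cluster_samples_by_slopes(
    slopes: pd.DataFrame, k: int = 2
) -> tuple[np.ndarray, pd.Series]:
    """Single-linkage (nearest point) clustering of samples by slope vectors.

    `slopes` is a samples x windows frame.  Missing slopes are imputed by
    the sample's row mean with a warning.  Returns the scipy linkage matrix
    and flat cluster labels at a cut of `k` clusters; ties at zero distance
    are stabilised by sorting samples by name first.
    """
    if len(slopes) < 2:
        raise ValueError("need at least 2 samples to cluster")
    x = slopes.sort_index().copy()
    if x.isna().any().any():
        warnings.warn("missing slopes imputed by row mean")
        x = x.apply(lambda r: r.fillna(r.mean()), axis=1)
    z = linkage(x.to_numpy(float), method="single", metric="euclidean")
    labels = pd.Series(fcluster(z, t=k, criterion="maxclust"), index=x.index)
    return z, labels


# ---------------------------------------------------------------------------
# interaction strength and CGI aggregation


def interaction_strength(cm: ContactMatrix, bins: BinAnnotation) -> pd.DataFrame:
    """Per-bin contact fractions to the four F/P x CGI classes.

    ``I(k, R_i) = C(k, R_i) / sum_i C(k, R_i)`` where ``C(k, R_i)`` sums the
    contacts of bin k with all unmasked bins of class ``R_i``, excluding the
    self-contact.  Rows sum to 1; bins with zero total contact are NaN.
    """
    rows = []
    for chrom, mat in cm.matrices.items():
        labels = bins.chrom_labels(chrom, "four_class")[: len(mat)]
        keep = ~cm.bin_mask[chrom]
        m = mat.copy()
        np.fill_diagonal(m, 0.0)
        m[:, ~keep] = 0.0
        class_sums = np.zeros((len(m), len(FOUR_CLASSES)))
        for ci, cls in enumerate(FOUR_CLASSES):
            sel = (labels == cls) & keep
            class_sums[:, ci] = m[:, sel].sum(axis=1)
        totals = class_sums.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = class_sums / totals[:, None]
        for i in range(len(m)):
            if not keep[i] or totals[i] == 0:
                continue
            rows.append((chrom, i, labels[i], *frac[i]))
    return pd.DataFrame(
        rows, columns=["chrom", "bin", "four_class", *FOUR_CLASSES]
    )


def same_type_strength(ist: pd.DataFrame) -> pd.Series:
    """Each bin's interaction strength with its own four-class type."""
    vals = np.array(
        [row[row["four_class"]] for _, row in ist.iterrows()], dtype=float
    )
    return pd.Series(vals, index=ist.set_index(["chrom", "bin"]).index)


def classify_cgi_aggregation(
    ist_normal: pd.DataFrame,
    ist_cancer_list: list[pd.DataFrame],
    eps: float = 0.0,
    query: int = 0,
) -> pd.DataFrame:
    """Label CGI bins as conservative / less_segregated / other.

    A CGI bin is *aggregated* in a cancer sample when its same-type
    interaction strength exceeds the normal value by more than `eps`;
    *conservative* when aggregated in every provided cancer sample;
    *less_segregated* when its same-type strength decreases in the queried
    sample (index `query`).  With a single cancer sample the conservative
    set degenerates to that sample's aggregated set (warned).
    """
    if len(ist_cancer_list) < 2:
        warnings.warn("fewer than 2 cancer samples: conservative == aggregated")
    base = ist_normal[ist_normal["four_class"].isin(["F-CGI", "P-CGI"])]
    key = ["chrom", "bin"]
    out = base[key + ["four_class"]].copy()
    s_norm = same_type_strength(base).to_numpy()
    agg_flags = []
    deltas_q = None
    for si, ist_c in enumerate(ist_cancer_list):
        m = base[key].merge(ist_c, on=key, how="left")
        same = np.array(
            [
                row[fc] if pd.notna(row.get(fc, np.nan)) else np.nan
                for (_, row), fc in zip(m.iterrows(), base["four_class"])
            ],
            dtype=float,
        )
        delta = same - s_norm
        agg_flags.append(delta > eps)
        out[f"aggregated_{si}"] = delta > eps
        if si == query:
            deltas_q = delta
    all_agg = np.logical_and.reduce(agg_flags)
    label = np.where(
        all_agg,
        "conservative",
        np.where(deltas_q < -eps, "less_segregated", "other"),
    )
    out["label"] = label
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# contact loss


def detect_contact_loss(
    cm_normal: ContactMatrix,
    cm_cancer: ContactMatrix,
    bins: BinAnnotation,
    s_range: tuple[float, float] = (600_000, 2_000_000),
    pair_type: str = "F",
) -> pd.DataFrame:
    """Bins losing mid-range contact in cancer.

    For every unmasked bin the mean contact with all unmasked bins at
    genomic separations within `s_range` (default 600 kb - 2 Mb) is
    computed in both samples.  A bin shows contact loss when that value
    exceeds the per-chromosome average over all bins in the normal sample
    but falls below the average in the cancer sample; forest bins sit
    structurally above that average, so the rule picks out forest regions
    whose forest contacts collapse.  Only `pair_type` (default F) bins are
    reported; bins masked in either sample are skipped.
    """
    if cm_normal.resolution != cm_cancer.resolution:
        raise ValueError("resolution mismatch")
    res = cm_normal.resolution
    d_lo = max(1, int(np.ceil(s_range[0] / res)))
    d_hi = int(np.floor(s_range[1] / res))
    rows = []
    for chrom in cm_normal.matrices:
        if chrom not in cm_cancer.matrices:
            continue
        labels = bins.chrom_labels(chrom, "domain")
        mat_n = cm_normal.matrices[chrom]
        mat_c = cm_cancer.matrices[chrom]
        n = len(mat_n)
        keep = ~cm_normal.bin_mask[chrom] & ~cm_cancer.bin_mask[chrom]

        def band_mean(mat):
            vals = np.zeros(n)
            cnt = np.zeros(n)
            for d in range(d_lo, d_hi + 1):
                i = np.arange(n - d)
                j = i + d
                ok = keep[i] & keep[j]
                v = mat[i[ok], j[ok]]
                np.add.at(vals, i[ok], v)
                np.add.at(vals, j[ok], v)
                np.add.at(cnt, i[ok], 1)
                np.add.at(cnt, j[ok], 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(cnt > 0, vals / cnt, np.nan)

        mean_n = band_mean(mat_n)
        mean_c = band_mean(mat_c)
        considered = keep & np.isfinite(mean_n) & np.isfinite(mean_c)
        if considered.sum() == 0:
            continue
        avg_n = mean_n[considered].mean()
        avg_c = mean_c[considered].mean()
        report = considered & (labels[:n] == pair_type)
        for i in np.flatnonzero(report):
            rows.append(
                (
                    chrom,
                    int(i),
                    float(mean_n[i]),
                    float(mean_c[i]),
                    bool(mean_n[i] > avg_n and mean_c[i] < avg_c),
                )
            )
    return pd.DataFrame(
        rows, columns=["chrom", "bin", "mean_normal", "mean_cancer", "contact_loss"]
    )


# ---------------------------------------------------------------------------
# insulation


def _region_means(mat: np.ndarray, keep: np.ndarray, a: slice, b: slice):
    """Within-region means (diagonal excluded) and the between-region mean."""

    def within(sl):
        idx = np.flatnonzero(keep[sl]) + sl.start
        if len(idx) < 2:
            return np.nan
        sub = mat[np.ix_(idx, idx)]
        n = len(idx)
        return (sub.sum() - np.trace(sub)) / (n * (n - 1))

    ia = np.flatnonzero(keep[a]) + a.start
    ib = np.flatnonzero(keep[b]) + b.start
    between = mat[np.ix_(ia, ib)].mean() if len(ia) and len(ib) else np.nan
    return within(a), within(b), between


def insulation_score(a1: float, a2: float, b: float) -> float:
    """``IS = ln(1 + a1/b + a2/b)``; NaN when b is zero or undefined."""
    if not np.isfinite(b) or b <= 0 or not np.isfinite(a1) or not np.isfinite(a2):
        return np.nan
    return float(np.log(1.0 + a1 / b + a2 / b))


def insulation_domain_pairs(cm: ContactMatrix, domains: DomainSet) -> pd.DataFrame:
    """Insulation score for every pair of adjacent forest/prairie domains."""
    rows = []
    res = cm.resolution
    for chrom, doms in domains.domains.items():
        if chrom not in cm.matrices:
            continue
        mat = cm.matrices[chrom]
        keep = ~cm.bin_mask[chrom]
        n = len(mat)

        def dom_bins(s, e):
            return slice(
                min(int(np.ceil(s / res)), n), min(max(int(e // res), 0), n)
            )

        for (s1, e1, l1), (s2, e2, l2) in zip(doms, doms[1:]):
            if {l1, l2} != {"F", "P"} or e1 != s2:
                continue
            sl1, sl2 = dom_bins(s1, e1), dom_bins(s2, e2)
            if keep[sl1].sum() < 2 or keep[sl2].sum() < 2:
                continue
            a1, a2, b = _region_means(mat, keep, sl1, sl2)
            rows.append(
                (chrom, s1, e1, l1, s2, e2, l2, a1, a2, b, insulation_score(a1, a2, b))
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start1",
            "end1",
            "label1",
            "start2",
            "end2",
            "label2",
            "a1",
            "a2",
            "b",
            "IS",
        ],
    )


def insulation_boundary_profile(
    cm: ContactMatrix,
    domains: DomainSet,
    window_sizes: list[int],
    flank: int = 1_000_000,
) -> pd.DataFrame:
    """Mean insulation score around F/P boundaries, forest oriented left.

    For each qualifying boundary, each bead position p within ``+/-flank``
    and each window size w, the score uses ``A1 = [p - w, p)`` and
    ``A2 = [p, p + w)``.  Boundaries need `max(window_sizes) + flank` of
    matrix on both sides; profiles from prairie-to-forest boundaries are
    mirrored so forests always sit at negative relative positions.
    """
    res = cm.resolution
    flank_bins = flank // res
    rel_positions = np.arange(-flank_bins, flank_bins + 1)
    acc = {
        w: np.zeros((2, len(rel_positions))) for w in window_sizes
    }  # sums, counts
    n_boundaries = 0
    for chrom, doms in domains.domains.items():
        if chrom not in cm.matrices:
            continue
        mat = cm.matrices[chrom]
        keep = ~cm.bin_mask[chrom]
        n = len(mat)
        max_w = max(window_sizes) // res
        for (s1, e1, l1), (s2, e2, l2) in zip(doms, doms[1:]):
            if {l1, l2} != {"F", "P"} or e1 != s2:
                continue
            bpos = int(round(e1 / res))
            if bpos - flank_bins - max_w < 0 or bpos + flank_bins + max_w > n:
                continue
            n_boundaries += 1
            forest_left = l1 == "F"
            for w in window_sizes:
                wb = max(1, w // res)
                for ridx, rel in enumerate(rel_positions):
                    p = bpos + (rel if forest_left else -rel)
                    a = slice(p - wb, p)
                    b = slice(p, p + wb)
                    if a.start < 0 or b.stop > n:
                        continue
                    a1, a2, bb = _region_means(mat, keep, a, b)
                    score = insulation_score(a1, a2, bb)
                    if np.isfinite(score):
                        acc[w][0, ridx] += score
                        acc[w][1, ridx] += 1
    if n_boundaries == 0:
        raise ValueError("no qualifying boundaries")
    rows = []
    for w in window_sizes:
        sums, cnts = acc[w]
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(cnts > 0, sums / cnts, np.nan)
        for rel, mval, c in zip(rel_positions, means, cnts):
            rows.append((w, int(rel * res), mval, int(c)))
    return pd.DataFrame(rows, columns=["window", "rel_pos", "mean_IS", "n"])
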