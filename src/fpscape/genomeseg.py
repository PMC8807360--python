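"""Sequence-derived annotation layers: CGI forests and prairies.

CpG islands (CGIs) cluster along mammalian chromosomes.  Megabase-scale
domains in which every neighbouring-CGI distance stays below a *critical
distance* — the gap length at which the observed spacing density falls below
the expectation for randomly placed CGIs — are called CGI **forests** (F);
the complementary CGI-poor regions are **prairies** (P).  This module builds
that segmentation and the derived per-bin annotation layers every other
module consumes:

* :func:`compute_critical_distance` — the data-driven spacing threshold,
* :func:`segment_forests_prairies` — the F/P tiling of the genome,
* :func:`annotate_bins` — fixed-resolution bin labels (F/P x CGI/non-CGI),
* :func:`define_open_sea` — genome beyond +/-`flank` bp of any CGI,
* :func:`cpg_density_groups` — the four CpG-density classes at 1 kb,
* :func:`element_density_domains` — high/low repeat-density bin labels.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as ivl

logger = logging.getLogger(__name__)

MIN_CGI_COUNT = 50

#: CpG-density group boundaries, in CpG dinucleotides per 100 bp expressed
#: as a percentage (so 2.0 % at 1 kb means 20 CpGs).  CGIs have a minimum
#: density of 2.4 % and therefore fall almost entirely in group I.
DENSITY_GROUP_EDGES = {
    "I": (2.0, 20.1),
    "II": (1.0, 2.0),
    "III": (0.5, 1.0),
    "IV": (0.0, 0.5),
}


class NoClusteringError(ValueError):
    """Observed CGI spacing never drops below the random expectation."""


class InsufficientCGIError(ValueError):
    """Too few CGIs to estimate a critical distance."""


@dataclass
class CGITrack:
    """CGI intervals plus per-CpG positions — the segmentation substrate.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp.
    cgi
        Per-chromosome sorted, non-overlapping ``(n, 2)`` CGI intervals.
    cpg_positions
        Per-chromosome strictly increasing positions of CpG dinucleotides
        (position of the C on the plus strand).
    arm_boundaries
        Per-chromosome centromere / unmappable spans as interval arrays.
    """

    chrom_sizes: dict[str, int]
    cgi: dict[str, np.ndarray] = field(default_factory=dict)
    cpg_positions: dict[str, np.ndarray] = field(default_factory=dict)
    arm_boundaries: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for chrom in list(self.cgi):
            self.cgi[chrom] = ivl.as_intervals(self.cgi[chrom])
            if len(self.cgi[chrom]) and np.any(
                self.cgi[chrom][1:, 0] < self.cgi[chrom][:-1, 1]
            ):
                raise ValueError(f"overlapping CGIs on {chrom}")
            size = self.chrom_sizes.get(chrom)
            if size is not None and len(self.cgi[chrom]):
                if self.cgi[chrom][-1, 1] > size:
                    raise ValueError(f"CGI beyond end of {chrom}")
        for chrom in list(self.cpg_positions):
            pos = np.asarray(self.cpg_positions[chrom], dtype=np.int64)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"cpg positions not strictly increasing on {chrom}")
            self.cpg_positions[chrom] = pos

    @property
    def n_cgi(self) -> int:
        return sum(len(v) for v in self.cgi.values())

    def chroms(self):
        return list(self.chrom_sizes)


@dataclass
class DomainSet:
    """Alternating forest/prairie tiling of the mappable genome.

    ``domains[chrom]`` is an ordered list of ``(start, end, label)`` with
    label in ``{"F", "P"}`` (or ``{"high", "low"}`` for element-density
    variants); ``excluded[chrom]`` holds the removed unmappable intervals.
    Adjacent domains carry different labels and, together with the excluded
    set, the domains tile each chromosome exactly.
    """

    domains: dict[str, list[tuple[int, int, str]]]
    excluded: dict[str, np.ndarray] = field(default_factory=dict)
    critical_distance: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (chrom, s, e, lab)
            for chrom, doms in self.domains.items()
            for s, e, lab in doms
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])

    def intervals(self, label: str) -> dict[str, np.ndarray]:
        out = {}
        for chrom, doms in self.domains.items():
            sel = [(s, e) for s, e, lab in doms if lab == label]
            out[chrom] = (
                np.asarray(sel, dtype=np.int64)
                if sel
                else np.empty((0, 2), dtype=np.int64)
            )
        return out

    def check_tiling(self, chrom_sizes: dict[str, int]) -> None:
        """Assert F + P + excluded lengths sum to the chromosome length."""
        for chrom, size in chrom_sizes.items():
            dom_len = sum(e - s for s, e, _ in self.domains.get(chrom, []))
            exc_len = ivl.total_length(self.excluded.get(chrom, []))
            if dom_len + exc_len != size:
                raise AssertionError(
                    f"{chrom}: domains ({dom_len}) + excluded ({exc_len}) "
                    f"!= size ({size})"
                )


@dataclass
class BinAnnotation:
    """Fixed-resolution per-bin labels: domain, CGI flag, CpG density."""

    resolution: int
    table: pd.DataFrame  # chrom, start, end, domain, cgi_flag, four_class,
    #                      cpg_density, masked

    def chrom_labels(self, chrom: str, column: str) -> np.ndarray:
        sub = self.table[self.table["chrom"] == chrom]
        return sub.sort_values("start")[column].to_numpy()


def _neighbor_gaps(track: CGITrack) -> np.ndarray:
    gaps = []
    for chrom, arr in track.cgi.items():
        if len(arr) > 1:
            gaps.append(arr[1:, 0] - arr[:-1, 1])
    if not gaps:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(gaps)


def compute_critical_distance(
    track: CGITrack,
    n_random: int = 20,
    seed: int = 0,
    n_bins: int = 50,
    method: str = "simulate",
    min_below: int = 3,
) -> float:
    """Spacing threshold separating clustered from random CGI gaps.

    Neighbouring-CGI gap lengths are histogrammed in log-spaced bins and
    compared with the gap-length density expected if the same number of CGIs
    (with their observed lengths) were placed uniformly at random on the same
    mappable length.  The critical distance ``d*`` is the first bin at which
    the observed/expected density ratio falls below 1 and stays below for at
    least `min_below` consecutive occupied bins: gaps shorter than ``d*`` are
    enriched over random, i.e. reflect CGI clustering.

    Parameters
    ----------
    track
        CGI annotation; needs at least 50 CGIs genome-wide.
    n_random
        Number of uniform placements used for the random expectation when
        ``method="simulate"``.
    seed
        Seed for the random placements.
    method
        ``"simulate"`` (default) or ``"closed_form"``, which uses the
        exponential gap density of a uniform point process with the same
        mean gap.
    min_below
        Number of consecutive occupied bins the ratio must stay below 1.

    Returns
    -------
    float
        ``d*`` in bp (geometric midpoint of the crossing bin).

    Raises
    ------
    InsufficientCGIError
        Fewer than 50 CGIs genome-wide.
    NoClusteringError
        The observed/expected ratio never crosses 1 from above.
    """
    if track.n_cgi < MIN_CGI_COUNT:
        raise InsufficientCGIError(
            f"insufficient CGIs: {track.n_cgi} < {MIN_CGI_COUNT}"
        )
    gaps = _neighbor_gaps(track).astype(float)
    gaps = gaps[gaps > 0]
    if len(gaps) < MIN_CGI_COUNT - 1:
        raise InsufficientCGIError("insufficient CGI gaps")

    lo = max(gaps.min(), 1.0)
    hi = gaps.max() * 1.001
    if hi <= lo:
        raise NoClusteringError("no clustering detected: degenerate gap range")
    edges = np.geomspace(lo, hi, n_bins + 1)
    obs, _ = np.histogram(gaps, bins=edges)

    if method == "closed_form":
        # Uniform placement of n points on mappable length L gives
        # exponential gaps with rate n/L (interval lengths subtracted).
        rate = 1.0 / gaps.mean()
        cdf = 1.0 - np.exp(-rate * edges)
        exp_counts = len(gaps) * np.diff(cdf)
    else:
        rng = np.random.default_rng(seed)
        exp_counts = np.zeros(n_bins)
        for _ in range(n_random):
            sim_gaps = []
            for chrom, arr in track.cgi.items():
                n = len(arr)
                if n < 2:
                    continue
                size = track.chrom_sizes[chrom]
                lengths = arr[:, 1] - arr[:, 0]
                free = size - lengths.sum()
                if free <= 0:
                    continue
                # n islands split the free space into n + 1 segments; the
                # inner n - 1 are the inter-island gaps
                cuts = np.sort(rng.uniform(0, free, n))
                g = np.diff(np.concatenate([[0], cuts, [free]]))[1:-1]
                sim_gaps.append(g)
            if sim_gaps:
                allg = np.concatenate(sim_gaps)
                h, _ = np.histogram(allg[allg > 0], bins=edges)
                exp_counts += h
        exp_counts /= n_random

    # only bins with a stable expectation can support a density comparison
    occupied = exp_counts >= 5.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(exp_counts > 0, obs / np.maximum(exp_counts, 1e-300), np.inf)
    occ_idx = np.flatnonzero(occupied)
    r = ratio[occ_idx]
    seen_above = False
    for k in range(len(occ_idx)):
        if r[k] >= 1:
            seen_above = True
            continue
        if not seen_above:
            continue
        run = r[k : k + min_below]
        if len(run) >= min_below and np.all(run < 1):
            # guard against sampling noise around ratio 1: the pooled
            # deficit over the run must exceed 3 Poisson sigmas
            bins_run = occ_idx[k : k + min_below]
            obs_run = obs[bins_run].sum()
            exp_run = exp_counts[bins_run].sum()
            if obs_run < exp_run - 3.0 * np.sqrt(exp_run):
                b = occ_idx[k]
                return float(np.sqrt(edges[b] * edges[b + 1]))
    raise NoClusteringError("no clustering detected")


def segment_forests_prairies(
    track: CGITrack,
    d_star: float,
    exclusion: dict[str, np.ndarray] | None = None,
) -> DomainSet:
    """Tile each chromosome into CGI forests and prairies.

    A forest is a maximal run of consecutive CGIs whose inter-CGI gaps are
    all shorter than `d_star` and whose span (first CGI start to last CGI
    end) exceeds `d_star`.  Each forest is extended outward by
    ``min(gap/2, d_star/2)`` into its flanking gaps so that domains tile the
    chromosome without holes; everything else is prairie.  Excluded
    (unmappable) intervals are removed from both and reported separately.
    """
    if d_star <= 0:
        raise ValueError("d_star must be positive")
    exclusion = exclusion or {}
    domains: dict[str, list[tuple[int, int, str]]] = {}
    excluded: dict[str, np.ndarray] = {}

    if track.n_cgi == 0:
        warnings.warn("empty CGI track: labelling entire mappable genome P")

    for chrom, size in track.chrom_sizes.items():
        arr = track.cgi.get(chrom)
        if arr is None:
            arr = np.empty((0, 2), dtype=np.int64)
        exc = ivl.merge(exclusion.get(chrom, np.empty((0, 2), dtype=np.int64)))
        forests: list[tuple[int, int]] = []
        if len(arr):
            gaps = arr[1:, 0] - arr[:-1, 1] if len(arr) > 1 else np.empty(0)
            breaks = np.flatnonzero(gaps >= d_star)
            run_starts = np.concatenate([[0], breaks + 1])
            run_ends = np.concatenate([breaks, [len(arr) - 1]])
            half = d_star / 2.0
            for a, b in zip(run_starts, run_ends):
                if b == a:
                    # a lone CGI has no sub-critical neighbour distance and
                    # cannot seed a forest
                    continue
                left_gap = arr[a, 0] - arr[a - 1, 1] if a > 0 else 2 * arr[a, 0]
                right_gap = (
                    arr[b + 1, 0] - arr[b, 1]
                    if b + 1 < len(arr)
                    else 2 * (size - arr[b, 1])
                )
                s = arr[a, 0] - int(min(left_gap / 2.0, half))
                e = arr[b, 1] + int(min(right_gap / 2.0, half))
                if e - s <= d_star:  # domain, including flanks, too short
                    continue
                forests.append((max(0, s), min(size, e)))
        forests_arr = ivl.merge(forests) if forests else np.empty((0, 2), np.int64)
        f_clean = ivl.subtract(forests_arr, exc)
        p_clean = ivl.subtract(ivl.complement(forests_arr, size), exc)
        labelled = [(int(s), int(e), "F") for s, e in f_clean] + [
            (int(s), int(e), "P") for s, e in p_clean
        ]
        labelled.sort()
        # merge contiguous same-label neighbours so labels alternate
        merged: list[tuple[int, int, str]] = []
        for s, e, lab in labelled:
            if merged and merged[-1][2] == lab and merged[-1][1] == s:
                merged[-1] = (merged[-1][0], e, lab)
            else:
                merged.append((s, e, lab))
        domains[chrom] = merged
        excluded[chrom] = exc

    ds = DomainSet(domains=domains, excluded=excluded, critical_distance=float(d_star))
    ds.check_tiling(track.chrom_sizes)
    return ds


def annotate_bins(
    track: CGITrack, domains: DomainSet, resolution: int
) -> BinAnnotation:
    """Label fixed-size bins with domain, CGI flag and CpG density.

    A bin is a CGI bin if it harbours at least one bp of CGI; its domain
    label follows the majority base-pair overlap (ties resolved to P); CpG
    density is CpGs per kb.  Bins overlapping an excluded interval are
    masked.
    """
    rows = []
    for chrom, size in track.chrom_sizes.items():
        n_bins = int(np.ceil(size / resolution))
        starts = np.arange(n_bins, dtype=np.int64) * resolution
        ends = np.minimum(starts + resolution, size)
        cgi = track.cgi.get(chrom, np.empty((0, 2), np.int64))
        cgi_cov = ivl.overlap_lengths(starts, ends, cgi)
        f_iv = [(s, e) for s, e, lab in domains.domains.get(chrom, []) if lab == "F"]
        f_cov = ivl.overlap_lengths(starts, ends, f_iv)
        exc = domains.excluded.get(chrom, np.empty((0, 2), np.int64))
        exc_cov = ivl.overlap_lengths(starts, ends, exc)
        pos = track.cpg_positions.get(chrom, np.empty(0, np.int64))
        counts = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)
        widths = ends - starts
        for i in range(n_bins):
            dom = "F" if f_cov[i] * 2 > widths[i] else "P"
            flag = "CGI" if cgi_cov[i] > 0 else "non-CGI"
            rows.append(
                (
                    chrom,
                    int(starts[i]),
                    int(ends[i]),
                    dom,
                    flag,
                    f"{dom}-{flag}",
                    counts[i] * 1000.0 / resolution,
                    bool(exc_cov[i] > 0),
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "domain",
            "cgi_flag",
            "four_class",
            "cpg_density",
            "masked",
        ],
    )
    return BinAnnotation(resolution=resolution, table=table)


def define_open_sea(track: CGITrack, flank: int = 4000) -> dict[str, np.ndarray]:
    """Open sea: the genome beyond ``flank`` bp up/downstream of every CGI."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = {}
    for chrom, size in track.chrom_sizes.items():
        cgi = track.cgi.get(chrom, np.empty((0, 2), np.int64))
        if len(cgi) == 0:
            out[chrom] = np.asarray([[0, size]], dtype=np.int64)
            continue
        ext = np.column_stack(
            [np.maximum(cgi[:, 0] - flank, 0), np.minimum(cgi[:, 1] + flank, size)]
        )
        out[chrom] = ivl.complement(ext, size)
    return out


def cpg_density_groups(track: CGITrack, resolution: int = 1000) -> pd.DataFrame:
    """Assign 1-kb bins to CpG-density groups I-IV.

    Density is expressed as CpG dinucleotides per 100 bp in percent; group
    boundaries are (2.0, 20.1], (1.0, 2.0], (0.5, 1.0] and (0, 0.5] for
    groups I-IV.  Bins with zero CpGs are unassigned (group ``NA``), as are
    bins above the group-I upper bound (with a warning).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    rows = []
    n_over = 0
    for chrom, size in track.chrom_sizes.items():
        pos = track.cpg_positions.get(chrom, np.empty(0, np.int64))
        n_bins = int(np.ceil(size / resolution))
        starts = np.arange(n_bins, dtype=np.int64) * resolution
        ends = np.minimum(starts + resolution, size)
        counts = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)
        dens = counts * 100.0 / (ends - starts)  # percent per 100 bp
        groups = np.full(n_bins, "NA", dtype=object)
        for name, (lo, hi) in DENSITY_GROUP_EDGES.items():
            groups[(dens > lo) & (dens <= hi)] = name
        over = dens > DENSITY_GROUP_EDGES["I"][1]
        n_over += int(over.sum())
        groups[over] = "NA"
        for i in range(n_bins):
            rows.append((chrom, int(starts[i]), int(ends[i]), dens[i], groups[i]))
    if n_over:
        warnings.warn(f"{n_over} bins above the group-I density bound left unassigned")
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "cpg_density_pct", "group"]
    )


def element_density_domains(
    elements: dict[str, np.ndarray],
    chrom_sizes: dict[str, int],
    resolution: int,
    quantiles: tuple[float, float] = (0.25, 0.75),
) -> pd.DataFrame:
    """Label bins high/mid/low by covered length of a repeat-element track.

    Covered length per bin is compared against the ``quantiles`` of the
    genome-wide covered-length distribution; an all-equal distribution
    (e.g. no elements) raises ``ValueError("degenerate quantiles")``.
    """
    q_low, q_high = quantiles
    if not (0 <= q_low < q_high <= 1):
        raise ValueError("need 0 <= q_low < q_high <= 1")
    rows = []
    for chrom, size in chrom_sizes.items():
        n_bins = int(np.ceil(size / resolution))
        starts = np.arange(n_bins, dtype=np.int64) * resolution
        ends = np.minimum(starts + resolution, size)
        cov = ivl.overlap_lengths(
            starts, ends, elements.get(chrom, np.empty((0, 2), np.int64))
        )
        for i in range(n_bins):
            rows.append((chrom, int(starts[i]), int(ends[i]), int(cov[i])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "covered"])
    vals = df["covered"].to_numpy(float)
    lo, hi = np.quantile(vals, [q_low, q_high])
    if lo == hi:
        raise ValueError("degenerate quantiles")
    df["label"] = np.where(vals > hi, "high", np.where(vals < lo, "low", "mid"))
    return df
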