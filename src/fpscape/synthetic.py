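"""Synthetic genomes, methylomes, contact matrices and counts with planted truth.

Every pipeline stage in this package has a no-download test because this
module emulates the relevant structure of the real inputs:

* **genome** — alternating forest/prairie domain plan; CGIs placed with
  exponential inter-CGI gaps (short mean inside forests, long in prairies);
  background CpGs at domain-specific rates, dense CpGs inside CGIs; genes
  partly anchored at CGIs.
* **methylome** — per-CpG binomial (M, U) counts around domain-level
  open-sea means, with a cancer-stage effect that preferentially
  demethylates prairies and an optional hypermethylated CGI subset.
* **contact matrix** — block model with power-law distance decay (optionally
  piecewise in the cancer condition), affinities A_FF > A_PP > A_FP, a
  TAD-scale forest contact enrichment that survives balancing, planted
  CGI-aggregation boosts and mid-range contact-loss attenuations;
  Poisson-sampled counts.
* **expression** — negative-binomial counts with group-dependent means and a
  planted cancer multiplier for F-CGI genes; a tissue-mean table with
  planted tissue-specific genes.

All draws descend from a single seed through per-component substreams, so
identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as ivl
from .genomeseg import CGITrack, DomainSet
from .hicstruct import ContactMatrix
from .expression import ExpressionTable, classify_genes
from .methylome import MethylomeTrack, load_methylome

_STREAMS = {"genome": 1, "methylome": 2, "hic": 3, "expression": 4}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generators.

    The defaults define the toy scale used throughout the test suite: one
    50-Mb chromosome with a 1-Mb centromere, 40-kb contact bins and 2,000
    genes.
    """

    chrom: str = "chr1"
    chrom_length: int = 50_000_000
    centromere: tuple[int, int] = (24_500_000, 25_500_000)

    # domain plan (bp)
    forest_len_range: tuple[int, int] = (1_500_000, 3_500_000)
    prairie_len_range: tuple[int, int] = (3_000_000, 6_000_000)

    # CGI spacing and geometry
    mu_forest: float = 10_000.0  # mean inter-CGI gap inside forests
    mu_prairie: float = 350_000.0  # mean inter-CGI gap inside prairies
    cgi_len_range: tuple[int, int] = (500, 1_500)
    cpg_spacing_cgi: float = 12.0  # mean CpG spacing inside CGIs (bp)
    cpg_spacing_forest: float = 100.0  # background, forest open sea
    cpg_spacing_prairie: float = 250.0  # background, prairie open sea

    # methylome
    q_forest: float = 0.85
    q_prairie: float = 0.70
    delta_prairie: float = 0.07  # extra prairie open-sea demethylation per stage
    delta_forest: float = 0.01  # mild forest demethylation per stage
    cgi_beta: float = 0.10
    cgi_hyper_fraction: float = 0.10  # CGIs hypermethylated in cancer
    cgi_hyper_beta: float = 0.60
    beta_jitter_sd: float = 0.05
    depth: int = 30

    # Hi-C; forests contact same-type more strongly than prairies at these
    # scales, so A_FF > A_PP > A_FP
    resolution: int = 40_000
    hic_depth: float = 60.0
    affinity_ff: float = 2.0
    affinity_pp: float = 1.6
    affinity_fp: float = 1.0
    gamma_normal: float = 0.7
    gamma_cancer: tuple[float, float, float] = (0.56, 1.38, 800_000.0)
    # forest contacts are enriched at TAD-scale separations (600 kb - 2 Mb)
    # relative to the genome-wide decay; this row-pattern survives matrix
    # balancing and is what places forest bins above the all-bin average
    ff_band_boost: float = 1.6
    n_loss_bins: int = 20
    loss_atten_cancer: float = 0.25
    loss_range: tuple[int, int] = (600_000, 2_000_000)
    # planted loss bins are kept ≥ 1 Mb apart so each null bin shares band
    # pairs with at most a couple of them (non-overlapping planted effects)
    loss_min_separation: int = 600_000
    n_conservative_cgi: int = 50
    n_sample_specific_cgi: int = 20
    aggregation_boost: float = 1.5

    # expression
    n_genes: int = 2000
    gene_len_range: tuple[int, int] = (2_000, 10_000)
    cgi_anchored_fraction: float = 0.3
    group_base_mean: dict = field(
        default_factory=lambda: {
            "F-CGI": 300.0,
            "F-non-CGI": 150.0,
            "P-CGI": 180.0,
            "P-non-CGI": 60.0,
        }
    )
    cancer_multiplier: dict = field(default_factory=lambda: {"F-CGI": 2.0})
    dispersion: float = 0.2
    n_samples_per_condition: int = 20
    n_tissues: int = 8
    n_specific_genes: int = 100
    specific_boost: float = 5.0


def isolated_contact_config(hic_depth: float = 400.0, **overrides) -> SyntheticConfig:
    """Config for controlled contact-change experiments.

    Both conditions share the normal decay exponent, so the planted
    CGI-aggregation boosts and contact-loss attenuations are the *only*
    differences between the two matrices.  The deep sampling keeps the
    band-mean standard error near 1%, well inside the structural margin
    separating forest bins from the all-bin average — the regime in which
    the above/below-average detection rules are cleanly decidable.
    """
    cfg = SyntheticConfig(hic_depth=hic_depth, **overrides)
    cfg.gamma_cancer = (cfg.gamma_normal, cfg.gamma_normal, 800_000.0)
    return cfg


@dataclass
class GroundTruth:
    """Planted parameters and labels paired with the emitted objects."""

    domains: DomainSet
    config: SyntheticConfig
    bin_types: np.ndarray | None = None  # F/P per 40-kb bin
    bin_four_class: np.ndarray | None = None
    q_by_condition: dict = field(default_factory=dict)
    loss_bins: np.ndarray | None = None
    band_mean_expected: dict = field(default_factory=dict)
    conservative_bins: np.ndarray | None = None
    sample_specific_bins: dict = field(default_factory=dict)
    hyper_cgis: np.ndarray | None = None
    gene_effects: dict = field(default_factory=dict)


def _rng(seed: int, component: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[component], extra])


def _stage_of(condition) -> int:
    if condition in (None, "normal", 0):
        return 0
    if isinstance(condition, str) and condition.startswith("stage"):
        return int(condition[5:])
    return int(condition)


def generate_genome(
    cfg: SyntheticConfig, seed: int = 0
) -> tuple[CGITrack, GroundTruth, pd.DataFrame]:
    """Plant alternating F/P domains and draw CGIs, CpGs and gene models.

    Returns the CGI track, the ground truth (planted domain coordinates)
    and a gene-model frame already classified against the planted
    segmentation.
    """
    if cfg.mu_forest >= cfg.mu_prairie:
        raise ValueError("regimes not separated: mu_forest must be < mu_prairie")
    rng = _rng(seed, "genome")
    L = cfg.chrom_length
    cen = cfg.centromere

    # alternating domain plan, excluding the centromere
    domains: list[tuple[int, int, str]] = []
    pos = 0
    label = "F" if rng.random() < 0.5 else "P"
    while pos < L:
        lo, hi = (
            cfg.forest_len_range if label == "F" else cfg.prairie_len_range
        )
        end = min(pos + int(rng.uniform(lo, hi)), L)
        domains.append((pos, end, label))
        pos = end
        label = "P" if label == "F" else "F"

    # CGIs: exponential gaps at the domain's regime
    cgi_list: list[tuple[int, int]] = []
    for s, e, lab in domains:
        mu = cfg.mu_forest if lab == "F" else cfg.mu_prairie
        p = s + rng.exponential(mu)
        while p < e:
            clen = int(rng.uniform(*cfg.cgi_len_range))
            if p + clen > e:
                break
            cgi_list.append((int(p), int(p + clen)))
            p = p + clen + rng.exponential(mu)
    cgi_arr = ivl.merge(cgi_list)
    cgi_arr = ivl.subtract(cgi_arr, [cen])

    # CpG positions: dense inside CGIs, background elsewhere
    cpg: list[np.ndarray] = []
    for s, e in cgi_arr:
        n = max(1, rng.poisson((e - s) / cfg.cpg_spacing_cgi))
        cpg.append(np.sort(rng.integers(s, e, n)))
    for s, e, lab in domains:
        spacing = (
            cfg.cpg_spacing_forest if lab == "F" else cfg.cpg_spacing_prairie
        )
        n = rng.poisson((e - s) / spacing)
        cpg.append(np.sort(rng.integers(s, e, n)))
    pos_all = np.unique(np.concatenate(cpg))
    inside_cen = (pos_all >= cen[0]) & (pos_all < cen[1])
    pos_all = pos_all[~inside_cen]

    track = CGITrack(
        chrom_sizes={cfg.chrom: L},
        cgi={cfg.chrom: cgi_arr},
        cpg_positions={cfg.chrom: pos_all},
        arm_boundaries={cfg.chrom: np.asarray([cen], dtype=np.int64)},
    )
    dom_clean: list[tuple[int, int, str]] = []
    for s, e, lab in domains:
        for cs, ce in ivl.subtract([(s, e)], [cen]):
            dom_clean.append((int(cs), int(ce), lab))
    truth_domains = DomainSet(
        domains={cfg.chrom: dom_clean},
        excluded={cfg.chrom: np.asarray([cen], dtype=np.int64)},
    )
    truth = GroundTruth(domains=truth_domains, config=cfg)

    # genes: a fraction anchored at CGIs, the rest uniform
    n_anchor = int(cfg.n_genes * cfg.cgi_anchored_fraction)
    tss_list = []
    if len(cgi_arr):
        anchors = rng.choice(len(cgi_arr), size=n_anchor)
        anchored = cgi_arr[anchors, 0] - rng.integers(0, 500, n_anchor)
        tss_list.append(np.clip(anchored, 0, None))
    tss_list.append(rng.integers(0, L, cfg.n_genes - n_anchor))
    tss = np.concatenate(tss_list)
    tss = tss[(tss < cen[0]) | (tss >= cen[1])]
    lens = rng.integers(*cfg.gene_len_range, len(tss))
    strands = np.where(rng.random(len(tss)) < 0.5, "+", "-")
    # the TSS is the first transcribed base: gene start on +, end - 1 on -
    starts = np.where(strands == "+", tss, tss - lens + 1)
    starts = np.clip(starts, 0, None)
    ends = np.minimum(np.where(strands == "+", tss + lens, tss + 1), L)
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(len(tss))],
            "chrom": cfg.chrom,
            "strand": strands,
            "start": starts.astype(int),
            "end": ends.astype(int),
            "tss": tss.astype(int),
        }
    ).sort_values("start", ignore_index=True)
    genes = classify_genes(genes, track, truth_domains)
    return track, truth, genes


def generate_methylome(
    track: CGITrack,
    truth: GroundTruth,
    condition="normal",
    seed: int = 0,
) -> MethylomeTrack:
    """Binomial (M, U) counts per CpG with stage-dependent prairie loss.

    Open-sea CpGs centre on ``q_F`` / ``q_P`` minus ``stage * delta`` (the
    prairie delta is the larger, the planted carcinogenesis effect); CGI
    CpGs sit at ``cgi_beta`` except for a fixed hypermethylated subset in
    cancer.  Per-CpG means are jittered (sd ``beta_jitter_sd``) and counts
    drawn as ``M ~ Binomial(depth, beta*)``.
    """
    cfg = truth.config
    if cfg.depth < 1:
        raise ValueError("depth must be >= 1")
    stage = _stage_of(condition)
    rng = _rng(seed, "methylome", (stage + 1) * 1000)
    chrom = cfg.chrom
    pos = track.cpg_positions[chrom]
    cgi = track.cgi[chrom]
    doms = truth.domains.domains[chrom]
    dom_iv = np.asarray([(s, e) for s, e, _ in doms])
    dom_lab = np.asarray([lab for _, _, lab in doms])

    q_f = np.clip(cfg.q_forest - stage * cfg.delta_forest, 0.0, 1.0)
    q_p = np.clip(cfg.q_prairie - stage * cfg.delta_prairie, 0.0, 1.0)
    truth.q_by_condition[str(condition)] = {"F": float(q_f), "P": float(q_p)}

    idx = ivl.locate(pos, dom_iv)
    base = np.where(dom_lab[np.clip(idx, 0, None)] == "F", q_f, q_p)
    base[idx < 0] = q_p

    in_cgi = ivl.locate(pos, cgi) >= 0
    base[in_cgi] = cfg.cgi_beta
    if truth.hyper_cgis is None:
        hyper_rng = _rng(seed, "methylome", 999)
        n_h = int(len(cgi) * cfg.cgi_hyper_fraction)
        truth.hyper_cgis = np.sort(
            hyper_rng.choice(len(cgi), size=n_h, replace=False)
        )
    if stage > 0 and len(truth.hyper_cgis):
        cgi_idx = ivl.locate(pos, cgi)
        hyper = np.isin(cgi_idx, truth.hyper_cgis)
        base[hyper] = cfg.cgi_hyper_beta

    beta_star = np.clip(base + rng.normal(0, cfg.beta_jitter_sd, len(pos)), 0, 1)
    m = rng.binomial(cfg.depth, beta_star)
    records = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "M": m, "U": cfg.depth - m}
    )
    return load_methylome(records, min_coverage=3)


def _decay_curve(d_bins: np.ndarray, res: int, gamma, stage: int) -> np.ndarray:
    """Power-law contact decay, single or piecewise exponent, C(1 bin) = 1."""
    s = np.maximum(d_bins, 1) * float(res)
    s0 = float(res)
    if np.isscalar(gamma):
        return (s / s0) ** (-float(gamma))
    g1, g2, sb = gamma
    c = np.where(
        s <= sb,
        (s / s0) ** (-g1),
        (sb / s0) ** (-g1) * (s / sb) ** (-g2),
    )
    return c


def generate_contact_matrix(
    track: CGITrack,
    truth: GroundTruth,
    condition="normal",
    seed: int = 0,
    sample: int = 0,
) -> ContactMatrix:
    """Block-model Hi-C counts with planted decay, aggregation and loss.

    Expected contacts are ``A[type_i, type_j] * C(s)`` with affinities
    ``A_FF > A_PP > A_FP`` and a power-law decay ``C`` (piecewise in the
    cancer condition).  In cancer, same-four-class contacts of the planted
    conservative CGI bins (and of `sample`-specific bins) are boosted, and
    all contacts of the planted loss bins to forest bins are attenuated
    within the 600 kb - 2 Mb band, so those bins fall from their
    structurally above-average forest contact level to below average.
    Counts are Poisson at ``hic_depth`` and symmetric; centromere bins are
    empty.
    """
    cfg = truth.config
    if min(cfg.affinity_ff, cfg.affinity_pp, cfg.affinity_fp) <= 0:
        raise ValueError("nonpositive affinity")
    stage = _stage_of(condition)
    rng = _rng(seed, "hic", (stage + 1) * 1000 + sample)
    res = cfg.resolution
    chrom = cfg.chrom
    n = int(np.ceil(cfg.chrom_length / res))
    starts = np.arange(n, dtype=np.int64) * res
    ends = np.minimum(starts + res, cfg.chrom_length)

    doms = truth.domains.domains[chrom]
    f_iv = [(s, e) for s, e, lab in doms if lab == "F"]
    f_cov = ivl.overlap_lengths(starts, ends, f_iv)
    types = np.where(f_cov * 2 > (ends - starts), "F", "P")
    cgi_cov = ivl.overlap_lengths(starts, ends, track.cgi[chrom])
    four = np.array(
        [f"{t}-{'CGI' if c > 0 else 'non-CGI'}" for t, c in zip(types, cgi_cov)],
        dtype=object,
    )
    truth.bin_types = types
    truth.bin_four_class = four

    cen_cov = ivl.overlap_lengths(starts, ends, [cfg.centromere])
    cen_mask = cen_cov > 0

    # persistent structural state, shared across conditions and samples
    struct_rng = _rng(seed, "hic", 0)
    if truth.loss_bins is None:
        # candidate loss bins sit inside forests (most band partners F), the
        # regime in which their band contact is structurally above average
        band_lo = max(1, int(np.ceil(cfg.loss_range[0] / res)))
        band_hi = int(cfg.loss_range[1] // res)
        f_share = np.zeros(n)
        is_f = types == "F"
        for i in np.flatnonzero(is_f & ~cen_mask):
            lo1, hi1 = max(0, i - band_hi), max(0, i - band_lo + 1)
            lo2, hi2 = min(n, i + band_lo), min(n, i + band_hi + 1)
            part = np.r_[is_f[lo1:hi1], is_f[lo2:hi2]]
            f_share[i] = part.mean() if len(part) else 0.0
        candidates = np.flatnonzero(is_f & ~cen_mask & (f_share >= 0.5))
        min_sep = max(1, cfg.loss_min_separation // res)
        # sorted first-fit yields the maximal separated packing; relax the
        # separation if a particular genome cannot host the full set
        packed: list[int] = []
        for sep in range(min_sep, 0, -1):
            packed = []
            for b in candidates:
                if not packed or b - packed[-1] >= sep:
                    packed.append(int(b))
            if len(packed) >= cfg.n_loss_bins:
                break
        if len(packed) < cfg.n_loss_bins:
            # very small genomes: fall back to the most forest-interior bins
            pool = np.flatnonzero(is_f & ~cen_mask)
            order = np.argsort(f_share[pool])[::-1]
            packed = [int(b) for b in pool[order][: cfg.n_loss_bins]]
        if len(packed) < cfg.n_loss_bins:
            raise ValueError("cannot place loss bins: too few forest bins")
        keep_idx = struct_rng.choice(
            len(packed), size=cfg.n_loss_bins, replace=False
        )
        truth.loss_bins = np.sort(np.asarray(packed)[np.sort(keep_idx)])
    if truth.conservative_bins is None:
        cgi_bins = np.flatnonzero(np.isin(four, ["F-CGI", "P-CGI"]) & ~cen_mask)
        truth.conservative_bins = np.sort(
            struct_rng.choice(
                cgi_bins, size=cfg.n_conservative_cgi, replace=False
            )
        )
        remaining = np.setdiff1d(cgi_bins, truth.conservative_bins)
        for s_idx in range(4):
            truth.sample_specific_bins[s_idx] = np.sort(
                struct_rng.choice(
                    remaining, size=cfg.n_sample_specific_cgi, replace=False
                )
            )

    gamma = cfg.gamma_normal if stage == 0 else cfg.gamma_cancer

    is_f = types == "F"
    ff = is_f[:, None] & is_f[None, :]
    pp = ~is_f[:, None] & ~is_f[None, :]
    aff = np.where(ff, cfg.affinity_ff, np.where(pp, cfg.affinity_pp, cfg.affinity_fp))
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    in_band = (d * res >= cfg.loss_range[0]) & (d * res <= cfg.loss_range[1])
    expected = aff * _decay_curve(d, res, gamma, stage)
    expected = np.where(ff & in_band, expected * cfg.ff_band_boost, expected)

    # planted CGI aggregation (cancer only): boost same-four-class contacts
    if stage > 0:
        boost_sets = [truth.conservative_bins]
        if sample in truth.sample_specific_bins:
            boost_sets.append(truth.sample_specific_bins[sample])
        boosted = np.zeros(n, dtype=bool)
        for bs in boost_sets:
            boosted[bs] = True
        same4 = four[:, None] == four[None, :]
        hit = same4 & (boosted[:, None] | boosted[None, :])
        expected = np.where(hit, expected * cfg.aggregation_boost, expected)

    # planted mid-range contact loss (cancer only): attenuate the loss bins'
    # forest contacts within the band
    if stage > 0:
        is_loss = np.zeros(n, dtype=bool)
        is_loss[truth.loss_bins] = True
        hit_loss = ff & in_band & (is_loss[:, None] | is_loss[None, :])
        expected = np.where(hit_loss, expected * cfg.loss_atten_cancer, expected)

    expected[cen_mask, :] = 0.0
    expected[:, cen_mask] = 0.0

    # noiseless per-bin band means over all partners: the detection oracle
    # for the contact-loss rule lives on the expected model
    band_ok = in_band & ~cen_mask[:, None] & ~cen_mask[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        bm = np.where(
            band_ok.sum(axis=1) > 0,
            (expected * band_ok).sum(axis=1) / band_ok.sum(axis=1),
            np.nan,
        )
    truth.band_mean_expected[f"{condition}:{sample}"] = bm

    iu = np.triu_indices(n)
    counts = np.zeros((n, n))
    counts[iu] = rng.poisson(cfg.hic_depth * expected[iu])
    counts = counts + np.triu(counts, 1).T
    arm_split = int(np.searchsorted(starts, cfg.centromere[0]))
    return ContactMatrix(
        resolution=res,
        matrices={chrom: counts},
        bin_mask={chrom: cen_mask.copy()},
        balanced=False,
        arm_split={chrom: arm_split},
    )


def generate_expression(
    genes: pd.DataFrame,
    truth: GroundTruth,
    seed: int = 0,
) -> tuple[ExpressionTable, pd.DataFrame]:
    """Negative-binomial counts with a planted F-CGI boost in cancer.

    Returns the counts/TPM table (with sample metadata) and a gene x tissue
    mean-expression table carrying planted tissue-specific genes.
    """
    cfg = truth.config
    if cfg.dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = _rng(seed, "expression")
    classes = genes["gene_class"].fillna("P-non-CGI")
    base = classes.map(cfg.group_base_mean).to_numpy(float)
    lengths = (genes["end"] - genes["start"]).to_numpy(float)
    # read counts scale with transcript length at fixed expression, so the
    # group means are planted on the TPM scale, not the count scale
    len_factor = lengths / lengths.mean()

    n_per = cfg.n_samples_per_condition
    names, conds, cols = [], [], []
    size = 1.0 / cfg.dispersion
    for cond, mult_map in (("normal", {}), ("cancer", cfg.cancer_multiplier)):
        mult = classes.map(lambda c: mult_map.get(c, 1.0)).to_numpy(float)
        for i in range(n_per):
            lib = rng.uniform(0.8, 1.2)
            mean = base * mult * lib * len_factor
            p = size / (size + mean)
            cols.append(rng.negative_binomial(size, p))
            names.append(f"{cond}_{i:02d}")
            conds.append(cond)
    counts = pd.DataFrame(
        np.column_stack(cols), index=genes["gene_id"], columns=names
    )
    samples = pd.DataFrame({"condition": conds}, index=names)
    from .expression import counts_to_tpm

    tpm = counts_to_tpm(counts, pd.Series(lengths, index=genes["gene_id"]))
    expr = ExpressionTable(counts=counts, samples=samples, tpm=tpm)
    truth.gene_effects = {"cancer_multiplier": dict(cfg.cancer_multiplier)}

    # tissue-mean table with planted specific genes
    tissues = [f"tissue_{t}" for t in range(cfg.n_tissues)]
    base_t = rng.uniform(5, 50, size=(len(genes), 1)) * np.ones(
        (1, cfg.n_tissues)
    )
    spec_idx = rng.choice(len(genes), size=cfg.n_specific_genes, replace=False)
    spec_tissue = rng.integers(0, cfg.n_tissues, size=cfg.n_specific_genes)
    base_t[spec_idx, spec_tissue] *= cfg.specific_boost
    tissue_means = pd.DataFrame(base_t, index=genes["gene_id"], columns=tissues)
    truth.gene_effects["specific_genes"] = {
        str(genes["gene_id"].iloc[i]): tissues[t]
        for i, t in zip(spec_idx, spec_tissue)
    }
    return expr, tissue_means
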