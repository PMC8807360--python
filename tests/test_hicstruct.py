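"""Contact-matrix statistics: balancing, compartments, decay, insulation."""

import numpy as np
import pandas as pd
import pytest

from fpscape import genomeseg as gs
from fpscape import hicstruct as hs
from fpscape import synthetic as syn
from conftest import toy_matrix


def _annotation_for(labels, resolution=40_000, cgi_flags=None):
    n = len(labels)
    cgi_flags = cgi_flags or ["non-CGI"] * n
    table = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * resolution,
            "end": (np.arange(n) + 1) * resolution,
            "domain": list(labels),
            "cgi_flag": cgi_flags,
            "four_class": [f"{d}-{c}" for d, c in zip(labels, cgi_flags)],
            "cpg_density": 1.0,
            "masked": False,
        }
    )
    return gs.BinAnnotation(resolution=resolution, table=table)


def _decay_matrix(n, gamma, resolution=40_000, amp=100.0):
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    return amp * np.maximum(d, 1.0) ** (-gamma)


class TestPreprocess:
    def test_sparse_bin_masked(self):
        n = 30
        rng = np.random.default_rng(0)
        mat = rng.poisson(20, (n, n)).astype(float)
        mat = (mat + mat.T) / 2
        mat[5, :] = 0.0
        mat[:, 5] = 0.0
        cm = hs.ContactMatrix(resolution=40_000, matrices={"chr1": mat})
        out = hs.preprocess(cm)
        assert out.bin_mask["chr1"][5]
        assert not out.bin_mask["chr1"][6]

    def test_balancing_is_idempotent(self):
        n = 40
        rng = np.random.default_rng(1)
        raw = rng.poisson(30, (n, n)).astype(float)
        raw = raw + raw.T
        cm = hs.ContactMatrix(resolution=40_000, matrices={"chr1": raw})
        once = hs.preprocess(cm)
        twice = hs.preprocess(once)
        a, b = once.matrices["chr1"], twice.matrices["chr1"]
        keep = ~once.bin_mask["chr1"]
        rel = np.abs(b[np.ix_(keep, keep)] - a[np.ix_(keep, keep)]) / (
            a[np.ix_(keep, keep)] + 1e-12
        )
        assert rel.max() < 1e-4
        sums = a[np.ix_(keep, keep)].sum(axis=1)
        assert np.ptp(sums) / sums.mean() < 1e-3

    def test_sv_regions_masked(self):
        n = 30
        mat = np.full((n, n), 10.0)
        cm = hs.ContactMatrix(resolution=40_000, matrices={"chr1": mat})
        out = hs.preprocess(cm, sv_regions={"chr1": np.array([[80_000, 200_000]])})
        assert out.bin_mask["chr1"][2:5].all()
        assert not out.bin_mask["chr1"][0]

    def test_short_chromosome_dropped(self):
        mat = np.full((5, 5), 3.0)
        cm = hs.ContactMatrix(resolution=40_000, matrices={"chr1": mat})
        with pytest.warns(UserWarning, match="dropped"):
            out = hs.preprocess(cm)
        assert "chr1" not in out.matrices

    def test_outputs_stay_symmetric(self, matrices):
        for cm in matrices:
            m = cm.matrices["chr1"]
            assert np.allclose(m, m.T, atol=1e-8)


class TestCompartments:
    def test_checkerboard_eigenvector_alternates_with_block_parity(self):
        # 5-bin alternating blocks: the leading eigenvector of the exact
        # block correlation matrix flips sign with block parity
        n = 60
        parity = (np.arange(n) // 5) % 2
        same = parity[:, None] == parity[None, :]
        mat = _decay_matrix(n, 0.8) * np.where(same, 2.0, 1.0)
        cm = toy_matrix(mat)
        prof = hs.call_compartments(
            cm, {"chr1": parity.astype(float)}, min_arm_bins=10
        )
        v = prof["V"].to_numpy()
        signs = np.sign(v)
        expected = np.where(parity == 1, 1, -1)
        assert np.array_equal(signs, expected) or np.array_equal(signs, -expected)

    def test_planted_two_state_blocks_recovered(self, cfg, study, matrices):
        track, truth, _ = study
        cm200 = hs.aggregate(matrices[0], 5)
        n = cm200.n_bins("chr1")
        starts = np.arange(n) * cm200.resolution
        pos = track.cpg_positions["chr1"]
        dens = np.searchsorted(pos, starts + cm200.resolution) - np.searchsorted(
            pos, starts
        )
        prof = hs.call_compartments(cm200, {"chr1": dens.astype(float)})
        from fpscape import intervals as ivl

        f_iv = [(s, e) for s, e, l in truth.domains.domains["chr1"] if l == "F"]
        f_cov = ivl.overlap_lengths(starts, starts + cm200.resolution, f_iv)
        truth_lab = np.where(f_cov * 2 > cm200.resolution, "A", "B")
        called = prof.sort_values("bin")["label"].to_numpy()
        ok = called != "NA"
        assert (called[ok] == truth_lab[ok]).mean() >= 0.99

    def test_constant_matrix_has_no_signal(self):
        cm = toy_matrix(np.full((50, 50), 7.0))
        with pytest.warns(UserWarning, match="no compartment signal"):
            prof = hs.call_compartments(cm, {"chr1": np.ones(50)}, min_arm_bins=10)
        assert (prof["label"] == "NA").all()


class TestCompartmentIndex:
    def _profile(self, labels):
        n = len(labels)
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "bin": range(n),
                "start": np.arange(n) * 200_000,
                "end": (np.arange(n) + 1) * 200_000,
                "arm": "q",
                "V": [1.0 if l == "A" else -1.0 for l in labels],
                "label": list(labels),
            }
        )

    def test_three_to_one_contrast_gives_ln3(self):
        # bin 0: mean contact 3.0 to the A bins, 1.0 to the B bins
        labels = ["B", "A", "A", "B", "B"]
        mat = np.ones((5, 5))
        mat[0, [1, 2]] = 3.0
        mat[[1, 2], 0] = 3.0
        prof = hs.compartment_index(toy_matrix(mat), self._profile(labels))
        assert prof.loc[0, "CI"] == pytest.approx(np.log(3.0))

    def test_equal_contact_gives_zero(self):
        labels = ["A", "A", "B", "B"]
        prof = hs.compartment_index(toy_matrix(np.ones((4, 4))), self._profile(labels))
        assert prof["CI"].abs().max() == pytest.approx(0.0)

    def test_relabel_negates_ci_when_classes_balanced(self):
        rng = np.random.default_rng(2)
        mat = rng.uniform(1, 5, (8, 8))
        mat = (mat + mat.T) / 2
        labels = ["A", "B"] * 4
        flipped = ["B", "A"] * 4
        ci = hs.compartment_index(toy_matrix(mat), self._profile(labels))["CI"]
        ci_f = hs.compartment_index(toy_matrix(mat), self._profile(flipped))["CI"]
        assert np.allclose(ci.to_numpy(), -ci_f.to_numpy())

    def test_planted_blocks_separate_ci_sign(self, study, matrices, annotation):
        track, truth, _ = study
        cm200 = hs.aggregate(matrices[0], 5)
        n = cm200.n_bins("chr1")
        pos = track.cpg_positions["chr1"]
        starts = np.arange(n) * cm200.resolution
        dens = np.searchsorted(pos, starts + cm200.resolution) - np.searchsorted(
            pos, starts
        )
        prof = hs.call_compartments(cm200, {"chr1": dens.astype(float)})
        prof = hs.compartment_index(cm200, prof)
        mean_a = prof.loc[prof["label"] == "A", "CI"].mean()
        mean_b = prof.loc[prof["label"] == "B", "CI"].mean()
        assert mean_a > 0 > mean_b


class TestCompositionAndSwitch:
    def test_uniform_class_composition(self):
        prof = pd.DataFrame(
            {"chrom": "chr1", "bin": range(4), "label": ["A", "A", "B", "A"]}
        )
        frac = hs.compartment_composition(prof, ["F", "F", "P", "F"])
        assert frac.loc["F", "A"] == pytest.approx(1.0)
        assert frac.loc["P", "B"] == pytest.approx(1.0)

    def test_mean_eigenvector_symmetric_is_zero(self):
        prof = pd.DataFrame(
            {"chrom": "chr1", "bin": range(4), "V": [1.0, -1.0, 0.5, -0.5]}
        )
        v = hs.mean_eigenvector_by_class(prof, ["x"] * 4)
        assert v["x"] == pytest.approx(0.0)

    def test_switch_classes(self):
        a = pd.DataFrame(
            {"chrom": "chr1", "bin": range(4), "label": ["A", "A", "B", "B"]}
        )
        b_same = a.copy()
        b_inv = a.copy()
        b_inv["label"] = ["B", "B", "A", "A"]
        assert set(hs.classify_switch(a, b_same)["switch"]) == {"AA", "BB"}
        assert set(hs.classify_switch(a, b_inv)["switch"]) == {"AB", "BA"}

    def test_switch_binning_mismatch(self):
        a = pd.DataFrame({"chrom": "chr1", "bin": range(4), "label": ["A"] * 4})
        b = pd.DataFrame({"chrom": "chr1", "bin": range(5), "label": ["A"] * 5})
        with pytest.raises(ValueError, match="binning"):
            hs.classify_switch(a, b)


class TestDistanceDecay:
    def test_label_independent_matrix_has_unit_segregation(self):
        # near-single-diagonal distance bins so pooling cannot mix the
        # pair-type composition across separations
        n = 120
        mat = _decay_matrix(n, 0.9)
        labels = np.array((["F"] * 3 + ["P"] * 3) * (n // 6))
        prof = hs.distance_decay(
            toy_matrix(mat),
            _annotation_for(labels),
            s_max=3e6,
            bins_per_octave=64,
            min_pairs=1,
        )
        ok = prof["P_FP"].notna() & prof["P_FF"].notna() & prof["P_PP"].notna()
        assert ok.sum() > 10
        assert np.allclose(prof.loc[ok, "SF_F"], 1.0, atol=1e-9)
        assert np.allclose(prof.loc[ok, "SF_P"], 1.0, atol=1e-9)
        # and P(s) equals the planted decay law for every pair type
        s = prof.loc[ok, "s_mean"].to_numpy() / 40_000
        assert np.allclose(
            prof.loc[ok, "P_FF"], 100.0 * s ** (-0.9), rtol=1e-6
        )

    def test_exact_power_law_slope_recovered_exactly(self):
        n = 300
        gamma = 0.7
        mat = _decay_matrix(n, gamma)
        labels = np.array(["F"] * n)
        prof = hs.distance_decay(
            toy_matrix(mat),
            _annotation_for(labels),
            s_min=79_000,
            s_max=4e6,
            bins_per_octave=64,
            min_pairs=1,
        )
        slopes = hs.decay_slopes(
            prof, windows=[(2e5, 2e6), (4e5, 3e6)], column="P_FF"
        )
        assert np.allclose(slopes["slope"], -gamma, atol=1e-6)

    def test_flat_profile_has_zero_slope(self):
        n = 200
        mat = np.full((n, n), 50.0)
        prof = hs.distance_decay(
            toy_matrix(mat), _annotation_for(["F"] * n), min_pairs=1
        )
        slopes = hs.decay_slopes(prof, windows=[(2e5, 2e6)], column="P_FF")
        assert slopes.loc[0, "slope"] == pytest.approx(0.0, abs=1e-9)

    def test_planted_affinity_ratio_appears_in_segregation(self, cfg):
        # affinities FF=2, PP=2, FP=1 at every distance -> SF = 2
        over = dict(affinity_ff=2.0, affinity_pp=2.0, affinity_fp=1.0,
                    ff_band_boost=1.0)
        cfg2 = syn.SyntheticConfig(**over)
        track, truth, _ = syn.generate_genome(cfg2, seed=3)
        cm = syn.generate_contact_matrix(track, truth, "normal", seed=3)
        ann = gs.annotate_bins(track, truth.domains, cfg2.resolution)
        prof = hs.distance_decay(cm, ann, s_max=10e6)
        ok = prof["n_FP"] > 1000
        assert np.nanmedian(prof.loc[ok, "SF_F"]) == pytest.approx(2.0, rel=0.1)
        assert np.nanmedian(prof.loc[ok, "SF_P"]) == pytest.approx(2.0, rel=0.1)

    def test_piecewise_regimes_recovered(self, cfg, study, matrices, annotation):
        _, cancer = matrices
        prof = hs.distance_decay(cancer, annotation)
        g1, g2, sb = cfg.gamma_cancer
        short = hs.decay_slopes(prof, windows=[(2e5, 6.3e5)], column="P_PP")
        long = hs.decay_slopes(prof, windows=[(2e6, 6.3e6)], column="P_PP")
        assert short.loc[0, "slope"] == pytest.approx(-g1, abs=0.05)
        assert long.loc[0, "slope"] == pytest.approx(-g2, abs=0.05)


class TestSlopeClustering:
    def test_planted_exponent_groups_separate(self):
        slopes = pd.DataFrame(
            {
                "w1": [-0.7, -0.71, -0.69, -1.2, -1.19, -1.21],
                "w2": [-0.7, -0.69, -0.7, -1.2, -1.21, -1.2],
            },
            index=[f"s{i}" for i in range(6)],
        )
        _, labels = hs.cluster_samples_by_slopes(slopes, k=2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels.iloc[0] != labels.iloc[3]

    def test_duplicate_samples_merge_first(self):
        slopes = pd.DataFrame(
            {"w1": [-0.7, -0.7, -1.0]}, index=["a", "b", "c"]
        )
        z, _ = hs.cluster_samples_by_slopes(slopes, k=2)
        assert z[0, 2] == pytest.approx(0.0)

    def test_single_sample_is_an_error(self):
        with pytest.raises(ValueError):
            hs.cluster_samples_by_slopes(pd.DataFrame({"w1": [-0.7]}), k=1)

    def test_missing_slopes_imputed_with_warning(self):
        slopes = pd.DataFrame(
            {"w1": [-0.7, np.nan], "w2": [-0.7, -1.0]}, index=["a", "b"]
        )
        with pytest.warns(UserWarning, match="imputed"):
            hs.cluster_samples_by_slopes(slopes, k=2)


class TestInteractionStrength:
    def test_hand_normalization(self):
        # bin 0 contacts summing (2, 3, 4, 1) to the four classes
        labels = ["F", "F", "P", "P"]
        flags = ["CGI", "non-CGI", "CGI", "non-CGI"]
        mat = np.zeros((5, 5))
        mat[0, 1:] = [2, 3, 4, 1]
        mat[1:, 0] = [2, 3, 4, 1]
        ann = _annotation_for(["F"] + labels, cgi_flags=["CGI"] + flags)
        ist = hs.interaction_strength(toy_matrix(mat), ann)
        row = ist[ist["bin"] == 0].iloc[0]
        assert [row[c] for c in hs.FOUR_CLASSES] == pytest.approx(
            [0.2, 0.3, 0.4, 0.1]
        )

    def test_rows_sum_to_one(self, matrices, annotation):
        ist = hs.interaction_strength(matrices[0], annotation)
        sums = ist[hs.FOUR_CLASSES].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestCgiAggregation:
    def _ist(self, same_vals):
        rows = []
        for i, v in enumerate(same_vals):
            rest = (1 - v) / 3
            rows.append(("chr1", i, "F-CGI", v, rest, rest, rest))
        return pd.DataFrame(
            rows, columns=["chrom", "bin", "four_class", *hs.FOUR_CLASSES]
        )

    def test_rise_in_all_samples_is_conservative(self):
        normal = self._ist([0.40, 0.40])
        cancer = self._ist([0.55, 0.35])
        out = hs.classify_cgi_aggregation(normal, [cancer, cancer, cancer])
        assert out.loc[out["bin"] == 0, "label"].iloc[0] == "conservative"
        assert out.loc[out["bin"] == 1, "label"].iloc[0] == "less_segregated"

    def test_rise_in_two_of_three_is_other(self):
        normal = self._ist([0.40])
        up, down = self._ist([0.55]), self._ist([0.40])
        out = hs.classify_cgi_aggregation(normal, [up, up, down], eps=0.01)
        assert out["label"].iloc[0] == "other"

    def test_single_cancer_sample_warns(self):
        normal = self._ist([0.4])
        with pytest.warns(UserWarning, match="conservative"):
            hs.classify_cgi_aggregation(normal, [self._ist([0.5])])


class TestContactLoss:
    def test_identical_matrices_detect_nothing(self, matrices, annotation):
        res = hs.detect_contact_loss(matrices[0], matrices[0], annotation)
        assert not res["contact_loss"].any()

    def test_bin_below_average_in_both_not_flagged(self):
        n = 120
        base = _decay_matrix(n, 0.7)
        weak = base.copy()
        weak[10, :] *= 0.5
        weak[:, 10] *= 0.5
        ann = _annotation_for(["F"] * n)
        res = hs.detect_contact_loss(toy_matrix(weak), toy_matrix(weak), ann)
        assert not res.loc[res["bin"] == 10, "contact_loss"].iloc[0]

    def test_planted_loss_bins_recovered(self):
        cfg = syn.isolated_contact_config()
        track, truth, _ = syn.generate_genome(cfg, seed=4)
        pn = hs.preprocess(syn.generate_contact_matrix(track, truth, "normal", seed=4))
        pc = hs.preprocess(syn.generate_contact_matrix(track, truth, "stage3", seed=4))
        ann = gs.annotate_bins(track, truth.domains, cfg.resolution)
        res = hs.detect_contact_loss(pn, pc, ann)
        pred = set(res.loc[res["contact_loss"], "bin"])
        planted = set(truth.loss_bins.tolist())
        assert len(pred & planted) / len(planted) >= 0.95


class TestInsulation:
    def test_symmetric_case_is_ln3(self):
        assert hs.insulation_score(2.0, 2.0, 2.0) == pytest.approx(np.log(3))

    def test_hand_case_is_ln4(self):
        assert hs.insulation_score(2.0, 4.0, 2.0) == pytest.approx(np.log(4))

    def test_zero_between_contact_is_missing(self):
        assert np.isnan(hs.insulation_score(2.0, 2.0, 0.0))

    def test_domain_pairs_on_block_matrix(self):
        n = 40
        res = 40_000
        within, between = 4.0, 2.0
        mat = np.full((n, n), between)
        mat[:20, :20] = within
        mat[20:, 20:] = within
        ds = gs.DomainSet(
            domains={"chr1": [(0, 20 * res, "F"), (20 * res, 40 * res, "P")]}
        )
        out = hs.insulation_domain_pairs(toy_matrix(mat), ds)
        assert len(out) == 1
        assert out.loc[0, "IS"] == pytest.approx(np.log(1 + 2 + 2))

    def test_boundary_attenuation_raises_is_by_ln2_shift(self):
        # halving the cross-boundary block doubles a/b, shifting IS by
        # ln((1+2r)/(1+r)) with r = a/b; at a=b the shift is ln(3/2)... use
        # exact closed form on noiseless blocks
        n = 40
        res = 40_000
        mat1 = np.full((n, n), 2.0)
        mat1[:20, :20] = 4.0
        mat1[20:, 20:] = 4.0
        mat2 = mat1.copy()
        mat2[:20, 20:] = 1.0
        mat2[20:, :20] = 1.0
        ds = gs.DomainSet(
            domains={"chr1": [(0, 20 * res, "F"), (20 * res, 40 * res, "P")]}
        )
        is1 = hs.insulation_domain_pairs(toy_matrix(mat1), ds).loc[0, "IS"]
        is2 = hs.insulation_domain_pairs(toy_matrix(mat2), ds).loc[0, "IS"]
        assert is1 == pytest.approx(np.log(5))
        assert is2 == pytest.approx(np.log(9))

    def test_translation_invariant_matrix_gives_flat_profile(self):
        n = 160
        res = 40_000
        mat = _decay_matrix(n, 0.6)
        ds = gs.DomainSet(
            domains={
                "chr1": [
                    (0, 80 * res, "F"),
                    (80 * res, 160 * res, "P"),
                ]
            }
        )
        prof = hs.insulation_boundary_profile(
            toy_matrix(mat), ds, window_sizes=[200_000], flank=400_000
        )
        vals = prof["mean_IS"].dropna().to_numpy()
        assert np.ptp(vals) < 1e-6

    def test_block_boundary_maximises_insulation(self):
        n = 160
        res = 40_000
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        decay = np.maximum(d, 1.0) ** -0.6
        half = np.arange(n) < 80
        same = half[:, None] == half[None, :]
        mat = 100 * decay * np.where(same, 2.0, 1.0)
        ds = gs.DomainSet(
            domains={"chr1": [(0, 80 * res, "F"), (80 * res, 160 * res, "P")]}
        )
        prof = hs.insulation_boundary_profile(
            toy_matrix(mat), ds, window_sizes=[200_000], flank=1_000_000
        )
        best = prof.loc[prof["mean_IS"].idxmax(), "rel_pos"]
        assert abs(best) <= res

    def test_no_qualifying_boundaries_is_an_error(self):
        mat = np.full((10, 10), 2.0)
        ds = gs.DomainSet(domains={"chr1": [(0, 400_000, "F")]})
        with pytest.raises(ValueError, match="no qualifying"):
            hs.insulation_boundary_profile(
                toy_matrix(mat), ds, window_sizes=[200_000]
            )
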