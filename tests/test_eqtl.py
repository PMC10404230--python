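"""Tests of the mapping engine: kinship, null LMM, scans, peaks,
cis/trans, founder effects, heritability and SNP association."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doeqtl import synthetic
from doeqtl.eqtl import (
    EqtlPeak,
    KinshipSet,
    LodCurve,
    classify_cis_trans,
    covariate_design,
    export_gene_sets,
    find_peaks,
    fit_null,
    founder_effects_at,
    heritability,
    interpolate_probs,
    kinship_from_probs,
    scan_haplotypes,
    snp_association,
)
from doeqtl.synthetic import FounderProbs, GeneArchitecture


def ols_lod_curve(y, probs, X):
    """Independent least-squares LOD oracle (no kinship)."""
    n = len(y)

    def rss(A):
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        r = y - A @ beta
        return r @ r

    rss0 = rss(X)
    lods = np.empty(probs.n_markers)
    for m in range(probs.n_markers):
        lods[m] = 0.5 * n * np.log10(rss0 / rss(np.hstack([X, probs.values[:, :7, m]])))
    return np.clip(lods, 0, None)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

class TestKinship:
    def test_identical_one_hot_samples_have_unit_kinship(self, marker_map):
        M = len(marker_map)
        v = np.zeros((2, 8, M))
        v[:, 2, :] = 1.0  # both samples founder C everywhere
        p = FounderProbs(v, ["a", "b"], marker_map)
        ks = kinship_from_probs(p, loco=False)
        assert ks.overall[0, 1] == pytest.approx(1.0)

    def test_disjoint_one_hot_samples_have_zero_kinship(self, marker_map):
        M = len(marker_map)
        v = np.zeros((2, 8, M))
        v[0, 0, :] = 1.0
        v[1, 5, :] = 1.0
        p = FounderProbs(v, ["a", "b"], marker_map)
        ks = kinship_from_probs(p, loco=False)
        assert ks.overall[0, 1] == pytest.approx(0.0)

    def test_matches_triple_loop_oracle(self, rng, marker_map):
        p = synthetic.simulate_founder_mosaics(marker_map.iloc[:20], 4, seed=5)
        ks = kinship_from_probs(p, loco=False)
        n, _, M = p.values.shape
        for a in range(n):
            for b in range(n):
                expected = sum(
                    p.values[a, j, m] * p.values[b, j, m]
                    for j in range(8) for m in range(M)
                ) / M
                assert ks.overall[a, b] == pytest.approx(expected)

    def test_loco_excludes_scanned_chromosome(self, probs):
        ks = kinship_from_probs(probs, loco=True)
        ks.validate()
        assert set(ks.loco) == set(probs.chromosomes)
        # LOCO for chrom c equals kinship from the other chromosomes only
        others = probs.values[:, :, probs.markers["chromosome"] != "1"]
        n = probs.n_samples
        flat = others.reshape(n, -1)
        expected = flat @ flat.T / others.shape[2]
        np.testing.assert_allclose(ks.loco["1"], expected, atol=1e-10)

    def test_single_chromosome_loco_rejected(self, marker_map):
        p = synthetic.simulate_founder_mosaics(
            marker_map[marker_map.chromosome == "1"], 3, seed=1
        )
        with pytest.raises(ValueError):
            kinship_from_probs(p, loco=True)


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

class TestNullFit:
    def test_identity_kinship_matches_ols_coefficients(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 2.0] + rng.normal(size=n)
        fit = fit_null(y, X, K=np.eye(n))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients, ols, atol=1e-6)

    def test_hsq_zero_traits_estimated_near_zero(self, probs, design, kinship):
        rng = np.random.default_rng(21)
        ests = []
        eig = kinship.eig(None)
        for _ in range(100):
            y = rng.normal(size=probs.n_samples)
            ests.append(fit_null(y, design, eig=eig).hsq)
        assert np.median(ests) <= 0.1

    def test_profile_maximum_beats_grid(self, probs, design, kinship, rng):
        from doeqtl.eqtl import _neg_profile_loglik, _rotate
        y = rng.normal(size=probs.n_samples) + probs.values[:, 0, 10]
        eig = kinship.eig(None)
        fit = fit_null(y, design, eig=eig)
        lam, U = eig
        yt, Xt = _rotate(y, design, eig)
        grid = np.linspace(0, 1 - 1e-6, 1000)
        grid_best = min(_neg_profile_loglik(h, lam, yt, Xt) for h in grid)
        assert -fit.loglik <= grid_best + 1e-6

    def test_rank_deficient_design_names_columns(self, rng):
        n = 30
        c = rng.normal(size=n)
        X = np.column_stack([np.ones(n), c, 2 * c])
        with pytest.raises(ValueError, match="collinear"):
            fit_null(rng.normal(size=n), X, K=np.eye(n), names=["i", "c", "c2"])


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

class TestScan:
    def test_matches_ols_oracle_without_kinship(self, probs, design, rng):
        y = rng.normal(size=probs.n_samples)
        curve = scan_haplotypes(y, probs, design, kinship=None)
        np.testing.assert_allclose(
            curve.lod, ols_lod_curve(y, probs, design), atol=1e-8
        )

    def test_identity_kinship_degeneracy(self, probs, design, rng):
        y = rng.normal(size=probs.n_samples)
        n = probs.n_samples
        ks = KinshipSet(np.eye(n), {c: np.eye(n) for c in probs.chromosomes})
        curve_eye = scan_haplotypes(y, probs, design, ks)
        curve_none = scan_haplotypes(y, probs, design, None)
        np.testing.assert_allclose(curve_eye.lod, curve_none.lod, atol=1e-6)

    def test_null_gene_lods_small_on_average(self, probs, design, rng):
        mean_lods = []
        for _ in range(20):
            y = rng.normal(size=probs.n_samples)
            mean_lods.append(scan_haplotypes(y, probs, design, None).lod.mean())
        # per-marker expected LOD under the null is ~(7/2)log10(e) ~ 1.5
        assert np.mean(mean_lods) < 3.0

    def test_cis_gene_peaks_at_causal_marker(self, probs, covariates, design, kinship):
        rng = np.random.default_rng(31)
        marker = "m2_25"
        arch = GeneArchitecture(
            "g", "2", 0, causal_marker_id=marker,
            founder_effects=rng.normal(size=8),
            qtl_var_frac=0.4, h2_polygenic=0.1,
        )
        expr, _ = synthetic.simulate_expression(
            probs, [arch], covariates, seed=32
        )
        curve = scan_haplotypes(expr["g"].to_numpy(), probs, design, kinship)
        top = curve.markers.iloc[int(np.argmax(curve.lod))]
        pos = curve.markers.set_index("marker_id").loc[marker, "position_bp"]
        assert top["chromosome"] == "2"
        assert abs(top["position_bp"] - pos) <= 2_100_000  # causal or adjacent

    def test_degenerate_marker_scores_zero(self, design, marker_map, rng):
        p = synthetic.simulate_founder_mosaics(marker_map, len(design), seed=3)
        values = p.values.copy()
        values[:, :, 5] = 1.0 / 8  # identical simplex in every sample
        p = FounderProbs(values, p.sample_ids, p.markers)
        y = rng.normal(size=p.n_samples)
        curve = scan_haplotypes(y, p, design, None)
        assert curve.lod[5] == 0.0


@settings(max_examples=10, deadline=None)
@given(a=st.floats(0.1, 5.0), b=st.floats(-3.0, 3.0), sign=st.sampled_from([-1, 1]))
def test_lod_affine_invariance(a, b, sign, probs, design):
    """LOD curves are invariant under y -> a*y + b, a != 0."""
    rng = np.random.default_rng(77)
    y = rng.normal(size=probs.n_samples)
    base = scan_haplotypes(y, probs, design, None).lod
    scaled = scan_haplotypes(sign * a * y + b, probs, design, None).lod
    np.testing.assert_allclose(base, scaled, atol=1e-7)


# ---------------------------------------------------------------------------
# peaks / classification
# ---------------------------------------------------------------------------

class TestPeaks:
    def _curve(self, marker_map, lods):
        return LodCurve("g", np.asarray(lods, float), marker_map)

    def test_all_zero_curve_gives_no_peaks(self, marker_map):
        assert find_peaks(self._curve(marker_map, np.zeros(len(marker_map)))) == []

    def test_threshold_is_strict(self, marker_map):
        lods = np.zeros(len(marker_map))
        lods[10] = 7.0
        assert find_peaks(self._curve(marker_map, lods), threshold=7.0) == []
        lods[10] = 7.0001
        peaks = find_peaks(self._curve(marker_map, lods), threshold=7.0)
        assert len(peaks) == 1 and peaks[0].peak_marker_id == "m1_11"

    def test_one_peak_per_chromosome_matches_bruteforce(self, marker_map, rng):
        lods = rng.uniform(0, 12, size=len(marker_map))
        peaks = find_peaks(self._curve(marker_map, lods), threshold=7.0)
        mm = marker_map.reset_index(drop=True)
        expected = {}
        for chrom, sub in mm.groupby("chromosome"):
            sub_lods = lods[sub.index]
            if sub_lods.max() > 7.0:
                expected[chrom] = sub.iloc[int(np.argmax(sub_lods))]["marker_id"]
        assert {p.chromosome: p.peak_marker_id for p in peaks} == expected

    def test_tie_broken_by_smallest_bp(self, marker_map):
        lods = np.zeros(len(marker_map))
        lods[[3, 7]] = 9.0
        peaks = find_peaks(self._curve(marker_map, lods))
        assert peaks[0].peak_marker_id == "m1_4"


class TestCisTrans:
    def _peak(self, chrom, bp):
        return EqtlPeak("g", chrom, "m", bp, 10.0)

    def test_same_chromosome_near_tss_is_cis(self):
        assert classify_cis_trans(self._peak("4", 1_000_000), "4", 500_000) == "cis"

    def test_boundary_inclusive_at_two_megabases(self):
        assert classify_cis_trans(self._peak("1", 2_000_000), "1", 0) == "cis"
        assert classify_cis_trans(self._peak("1", 2_000_001), "1", 0) == "trans"

    def test_chromosome_rule_dominates_distance(self):
        assert classify_cis_trans(self._peak("2", 0), "1", 0) == "trans"


# ---------------------------------------------------------------------------
# founder effects / heritability
# ---------------------------------------------------------------------------

class TestFounderEffects:
    def test_recovers_simulated_allele_series(self, probs, covariates, design, kinship):
        rng = np.random.default_rng(41)
        marker = "m1_30"
        rs = []
        for rep in range(10):
            arch = GeneArchitecture(
                "g", "1", 0, causal_marker_id=marker,
                founder_effects=rng.normal(size=8),
                qtl_var_frac=0.4, h2_polygenic=0.1,
            )
            expr, truth = synthetic.simulate_expression(
                probs, [arch], covariates, seed=100 + rep
            )
            est = founder_effects_at(
                marker, expr["g"].to_numpy(), probs, design, kinship
            )
            rs.append(np.corrcoef(est, truth.realized_effects["g"])[0, 1])
        assert np.median(rs) > 0.9

    def test_null_gene_effects_near_zero(self, probs, design, rng):
        y = rng.normal(size=probs.n_samples)
        est = founder_effects_at("m1_10", y, probs, design, None)
        assert np.abs(est).max() < 1.0
        assert abs(est.sum()) < 1e-10  # mean-centered

    def test_founder_permutation_equivariance(self, probs, design, rng):
        y = rng.normal(size=probs.n_samples) + probs.values[:, 3, 20]
        est = founder_effects_at("m1_21", y, probs, design, None)
        perm = np.array([3, 1, 4, 0, 7, 2, 6, 5])
        permuted = FounderProbs(
            probs.values[:, perm, :], probs.sample_ids, probs.markers
        )
        est_p = founder_effects_at("m1_21", y, permuted, design, None)
        np.testing.assert_allclose(est[perm], est_p, atol=1e-8)


class TestHeritability:
    def test_recovery_and_monotonicity(self, probs, covariates, design, kinship):
        medians = []
        for h2, seed in ((0.15, 51), (0.5, 52)):
            archs = [
                GeneArchitecture(f"g{i}", "1", 0, h2_polygenic=h2)
                for i in range(40)
            ]
            expr, _ = synthetic.simulate_expression(
                probs, archs, covariates, seed=seed
            )
            medians.append(
                np.median(
                    [heritability(expr[a.gene_id].to_numpy(), design, kinship)
                     for a in archs]
                )
            )
        assert medians[1] > medians[0]

    def test_pure_noise_heritability_near_zero(self, probs, design, kinship):
        rng = np.random.default_rng(53)
        ests = [
            heritability(rng.normal(size=probs.n_samples), design, kinship)
            for _ in range(30)
        ]
        assert np.median(ests) <= 0.1


# ---------------------------------------------------------------------------
# SNP association
# ---------------------------------------------------------------------------

class TestSnpAssociation:
    def test_one_hot_dosage_equals_founder_allele(self, marker_map):
        M = len(marker_map)
        v = np.zeros((1, 8, M))
        v[0, 6, :] = 1.0  # founder G everywhere
        p = FounderProbs(v, ["a"], marker_map)
        dose_has = interpolate_probs(p, "1", 1_000_000) @ np.array(
            [(64 >> j) & 1 for j in range(8)], float
        )
        assert dose_has[0] == pytest.approx(1.0)  # SDP bit 6 set
        dose_not = interpolate_probs(p, "1", 1_000_000) @ np.array(
            [(1 >> j) & 1 for j in range(8)], float
        )
        assert dose_not[0] == pytest.approx(0.0)

    def test_biallelic_effect_recovered_at_causal_position(
        self, probs, covariates, design, kinship
    ):
        # a biallelic SNP splitting founders {0..3} vs {4..7}
        causal_bits = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
        causal_marker = 25  # on chromosome 1
        rng = np.random.default_rng(61)
        dose = probs.values[:, :, causal_marker] @ causal_bits
        y = dose * 1.5 + rng.normal(size=probs.n_samples)
        pos = int(probs.markers.iloc[causal_marker]["position_bp"])
        sdp_rows = []
        sdp_causal = int(sum(int(b) << j for j, b in enumerate(causal_bits)))
        rng2 = np.random.default_rng(62)
        for i, p_bp in enumerate(range(pos - 8_000_000, pos + 8_000_001, 1_000_000)):
            sdp = sdp_causal if p_bp == pos else int(rng2.integers(1, 254))
            sdp_rows.append((f"s{i}", "1", p_bp, sdp))
        sdp_table = pd.DataFrame(
            sdp_rows, columns=["snp_id", "chromosome", "position_bp", "sdp"]
        )
        res = snp_association(
            y, probs, sdp_table, ("1", pos - 9_000_000, pos + 9_000_000),
            design, kinship,
        )
        top = res.iloc[int(np.argmax(res["lod"]))]
        assert abs(top["position_bp"] - pos) <= 1_000_000

    def test_uncorrelated_sdp_scores_near_zero(self, probs, design, rng):
        y = rng.normal(size=probs.n_samples)
        sdp_table = pd.DataFrame(
            {"snp_id": ["s1"], "chromosome": ["1"], "position_bp": [10_000_000],
             "sdp": [15]}
        )
        res = snp_association(
            y, probs, sdp_table, ("1", 0, 50_000_000), design, None
        )
        assert res["lod"].iloc[0] < 3.0

    def test_monomorphic_sdp_rejected(self, probs, design, rng):
        bad = pd.DataFrame(
            {"snp_id": ["s"], "chromosome": ["1"], "position_bp": [1], "sdp": [255]}
        )
        with pytest.raises(ValueError, match="monomorphic"):
            snp_association(
                rng.normal(size=probs.n_samples), probs, bad, ("1", 0, 10),
                design, None,
            )


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

class TestGeneSets:
    def test_empty_and_single_peak(self):
        empty = export_gene_sets(
            pd.DataFrame(columns=["gene_id", "chromosome", "cis_trans"])
        )
        assert empty == {"eqtl-cis": [], "eqtl-trans": []}
        one = export_gene_sets(
            pd.DataFrame(
                [["g1", "1", "cis"]],
                columns=["gene_id", "chromosome", "cis_trans"],
            )
        )
        assert one["eqtl-cis"] == ["g1"]
        assert one["eqtl-chr1-cis"] == ["g1"]
        assert one["eqtl-trans"] == []

    def test_set_sizes_match_group_counts(self, rng):
        genes = [f"g{i}" for i in range(40)]
        peaks = pd.DataFrame(
            {
                "gene_id": genes,
                "chromosome": rng.choice(["1", "2", "3"], 40),
                "cis_trans": rng.choice(["cis", "trans"], 40),
            }
        )
        sets = export_gene_sets(peaks)
        for kind in ("cis", "trans"):
            assert len(sets[f"eqtl-{kind}"]) == (peaks["cis_trans"] == kind).sum()
            for chrom in "123":
                key = f"eqtl-chr{chrom}-{kind}"
                expected = (
                    (peaks["cis_trans"] == kind) & (peaks["chromosome"] == chrom)
                ).sum()
                assert len(sets.get(key, [])) == expected
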