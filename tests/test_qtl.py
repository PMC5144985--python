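"""LOD scans, permutation thresholds, stepwise selection, refinement, merging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ionqtl as iq
from ionqtl.core import IonQTLError
from ionqtl.qtl import Locus, QTLModel


def make_cross(genmap, geno, y, trait="t", env="E"):
    traits = pd.DataFrame({trait: np.asarray(y, dtype=float)}, index=geno.index)
    return iq.Cross(genmap, geno, traits, env_id=env)


class TestMarkerScan:
    def test_constant_trait_gives_zero_lod_everywhere(self, small_map, geno300):
        cross = make_cross(small_map, geno300, np.ones(300))
        prof = iq.marker_lod_scan(cross, "t")
        assert (prof["lod"] == 0).all()

    def test_two_group_hand_oracle(self):
        # 8 lines split AAAA/BBBB at one marker; direct two-group least squares
        gm = iq.GeneticMap(np.array(["m1"]), np.array([1]), np.array([0.0]))
        geno = pd.DataFrame(
            {"m1": [0.5] * 4 + [-0.5] * 4}, index=[f"L{i}" for i in range(8)]
        )
        y = np.array([1.0, 1.2, 0.8, 1.0, 2.0, 2.2, 1.8, 2.0])
        cross = make_cross(gm, geno, y)
        prof = iq.marker_lod_scan(cross, "t")
        rss0 = float(((y - y.mean()) ** 2).sum())
        fit1 = np.concatenate([y[:4] - y[:4].mean(), y[4:] - y[4:].mean()])
        rss1 = float((fit1**2).sum())
        expected = (8 / 2) * np.log10(rss0 / rss1)
        assert prof["lod"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_lod_equals_r2_identity_on_random_data(self):
        # LOD = (n/2) log10(1 / (1 - R^2)) with R^2 from an independent
        # regression routine (scipy.stats.linregress)
        rng = np.random.default_rng(12)
        gm = iq.make_map(1, 5, 100.0)
        for _ in range(30):
            n = int(rng.integers(10, 60))
            geno = iq.simulate_ril_genotypes(gm, n, int(rng.integers(1 << 30)))
            y = rng.normal(0, 1, n) + 0.5 * geno.to_numpy()[:, 2]
            cross = make_cross(gm, geno, y)
            prof = iq.marker_lod_scan(cross, "t")
            for j, marker in enumerate(gm.marker_id):
                g = geno.to_numpy()[:, j]
                if np.ptp(g) == 0:
                    continue
                r2 = stats.linregress(g, y).rvalue ** 2
                expected = (n / 2) * np.log10(1 / (1 - r2))
                assert prof["lod"].iloc[j] == pytest.approx(expected, abs=1e-10)

    def test_lod_invariant_under_affine_trait_transform(self, toy_cross):
        base = iq.marker_lod_scan(toy_cross, "t")["lod"]
        shifted = toy_cross.traits.assign(t=lambda d: 3.0 * d["t"] - 17.0)
        cross2 = iq.Cross(toy_cross.genmap, toy_cross.geno, shifted, "E")
        again = iq.marker_lod_scan(cross2, "t")["lod"]
        np.testing.assert_allclose(base, again, atol=1e-9)

    def test_missing_genotypes_dropped_per_marker(self, small_map, geno300):
        geno = geno300.copy()
        geno.iloc[:150, 0] = np.nan
        rng = np.random.default_rng(0)
        cross = make_cross(small_map, geno, rng.normal(0, 1, 300))
        prof = iq.marker_lod_scan(cross, "t")
        assert np.isfinite(prof["lod"]).all()

    def test_all_missing_marker_skipped(self, small_map, geno300):
        geno = geno300.copy()
        geno.iloc[:, 3] = np.nan
        cross = make_cross(small_map, geno, np.random.default_rng(1).normal(size=300))
        prof = iq.marker_lod_scan(cross, "t")
        assert np.isnan(prof["lod"].iloc[3])
        assert np.isfinite(prof["lod"].drop(index=3)).all()

    def test_lod_nonnegative(self, toy_cross):
        prof = iq.marker_lod_scan(toy_cross, "t")
        assert (prof["lod"].dropna() >= 0).all()


class TestPermutationThreshold:
    def test_same_seed_same_threshold(self, toy_cross):
        a = iq.permutation_threshold(toy_cross, "t", n_perm=50, seed=5)
        b = iq.permutation_threshold(toy_cross, "t", n_perm=50, seed=5)
        assert a == b

    def test_quantile_monotone_in_alpha(self, toy_cross):
        null = iq.permutation_null(toy_cross, "t", n_perm=100, seed=3)
        t95 = float(np.quantile(null, 0.95))
        t99 = float(np.quantile(null, 0.99))
        assert t99 >= t95 > 0

    def test_threshold_calibration_under_null(self, small_map):
        # fresh null scans exceed a permutation threshold at ~alpha rate
        rng = np.random.default_rng(77)
        geno = iq.simulate_ril_genotypes(small_map, 100, 7)
        hits = 0
        n_data = 120
        for _ in range(n_data):
            y = rng.normal(0, 1, 100)
            cross = make_cross(small_map, geno, y)
            thr = iq.permutation_threshold(
                cross, "t", n_perm=100, alpha=0.05, seed=int(rng.integers(1 << 30))
            )
            prof = iq.marker_lod_scan(cross, "t")
            hits += float(np.nanmax(prof["lod"])) > thr
        lo, hi = stats.binom.interval(0.999, n_data, 0.05)
        assert lo <= hits <= hi


class TestStepwise:
    def test_noise_trait_rarely_yields_loci(self, small_map):
        rng = np.random.default_rng(9)
        geno = iq.simulate_ril_genotypes(small_map, 120, 2)
        nonempty = 0
        for _ in range(20):
            y = rng.normal(0, 1, 120)
            cross = make_cross(small_map, geno, y)
            thr = iq.permutation_threshold(
                cross, "t", n_perm=100, alpha=0.05, seed=int(rng.integers(1 << 30))
            )
            model = iq.stepwise_qtl(cross, "t", thr)
            nonempty += bool(model.loci)
        lo, hi = stats.binom.interval(0.999, 20, 0.05)
        assert lo <= nonempty <= hi

    def test_two_unlinked_qtl_recovered(self):
        gm = iq.make_map(10, 30, 150.0)
        hits = 0
        for rep in range(10):
            geno = iq.simulate_ril_genotypes(gm, 300, 500 + rep)
            G = geno.to_numpy()
            rng = np.random.default_rng(600 + rep)
            q1, q2 = gm.nearest_marker(2, 40.0), gm.nearest_marker(7, 100.0)
            y = G[:, q1] + G[:, q2] + rng.normal(0, 1, 300)
            cross = make_cross(gm, geno, y)
            thr = iq.permutation_threshold(cross, "t", n_perm=100, seed=700 + rep)
            pos = iq.stepwise_qtl(cross, "t", thr).positions()
            ok1 = any(c == 2 and abs(p - gm.position_cm[q1]) <= 10 for c, p in pos)
            ok2 = any(c == 7 and abs(p - gm.position_cm[q2]) <= 10 for c, p in pos)
            hits += ok1 and ok2
        assert hits >= 8

    def test_model_capped_at_max_qtl(self):
        # 12 strong unlinked QTL but the model may keep at most 10
        gm = iq.make_map(12, 15, 100.0)
        geno = iq.simulate_ril_genotypes(gm, 400, 31)
        G = geno.to_numpy()
        rng = np.random.default_rng(32)
        idx = [gm.nearest_marker(c, 50.0) for c in range(1, 13)]
        y = G[:, idx].sum(axis=1) * 2.0 + rng.normal(0, 1, 400)
        cross = make_cross(gm, geno, y)
        model = iq.stepwise_qtl(cross, "t", penalty=3.0, max_qtl=10)
        assert len(model.loci) == 10

    def test_penalized_lod_nonnegative_and_loci_sorted(self, toy_cross):
        thr = iq.permutation_threshold(toy_cross, "t", n_perm=100, seed=1)
        model = iq.stepwise_qtl(toy_cross, "t", thr)
        assert model.penalized_lod >= 0
        keys = [(l.chromosome, l.position_cm) for l in model.loci]
        assert keys == sorted(keys)

    def test_effect_sign_matches_simulated_allele_difference(self, toy_cross):
        thr = iq.permutation_threshold(toy_cross, "t", n_perm=100, seed=2)
        model = iq.stepwise_qtl(toy_cross, "t", thr)
        assert model.loci and model.loci[0].effect == pytest.approx(1.0, abs=0.4)

    def test_nonpositive_penalty_rejected(self, toy_cross):
        with pytest.raises(IonQTLError):
            iq.stepwise_qtl(toy_cross, "t", penalty=0.0)

    def test_estimator_predicts_from_selected_loci(self, small_map, geno300):
        rng = np.random.default_rng(3)
        q = small_map.nearest_marker(1, 50.0)
        y = 2.0 * geno300.to_numpy()[:, q] + rng.normal(0, 0.5, 300)
        est = iq.StepwiseQTLMapper(genmap=small_map, penalty=3.0).fit(
            geno300.to_numpy(), y
        )
        assert len(est.loci_) >= 1
        pred = est.predict(geno300.to_numpy())
        assert np.corrcoef(pred, y)[0, 1] > 0.8


class TestRefine:
    def _offset_model(self, cross, true_idx, off_idx, penalty=2.5):
        loci = (
            Locus(
                marker_id=str(cross.genmap.marker_id[off_idx]),
                chromosome=int(cross.genmap.chromosome[off_idx]),
                position_cm=float(cross.genmap.position_cm[off_idx]),
                effect=0.0,
                lod_drop=0.0,
                marker_index=off_idx,
            ),
        )
        return QTLModel("t", loci, 0.0, penalty)

    def test_model_lod_never_decreases(self, toy_cross):
        gm = toy_cross.genmap
        q = gm.nearest_marker(1, 50.0)
        start = self._offset_model(toy_cross, q, gm.nearest_marker(1, 85.0))
        refined = iq.refine_positions(toy_cross, start, seed=4)
        base = iq.refine_positions(toy_cross, refined, seed=5)
        assert base.model_lod >= refined.model_lod - 1e-9

    def test_offset_locus_moves_toward_truth(self, small_map):
        gm = small_map
        q = gm.nearest_marker(1, 50.0)
        moved_closer = 0
        for rep in range(20):
            geno = iq.simulate_ril_genotypes(gm, 250, 800 + rep)
            rng = np.random.default_rng(900 + rep)
            y = geno.to_numpy()[:, q] + rng.normal(0, 1, 250)
            cross = make_cross(gm, geno, y)
            start_idx = gm.nearest_marker(1, 65.0)  # 15 cM off
            model = self._offset_model(cross, q, start_idx)
            refined = iq.refine_positions(cross, model, seed=rep)
            d0 = abs(gm.position_cm[start_idx] - gm.position_cm[q])
            d1 = abs(refined.loci[0].position_cm - gm.position_cm[q])
            moved_closer += d1 <= d0
        assert moved_closer >= 18  # >= 90% of replicates

    def test_fixed_point_when_already_optimal(self, toy_cross):
        thr = iq.permutation_threshold(toy_cross, "t", n_perm=100, seed=6)
        model = iq.stepwise_qtl(toy_cross, "t", thr)
        refined = iq.refine_positions(toy_cross, model, seed=7)
        again = iq.refine_positions(toy_cross, refined, seed=8)
        assert [l.marker_id for l in again.loci] == [l.marker_id for l in refined.loci]

    def test_empty_model_rejected(self, toy_cross):
        with pytest.raises(IonQTLError):
            iq.refine_positions(toy_cross, QTLModel("t", (), 0.0, 1.0), seed=0)


class TestMerge:
    def _model(self, trait, positions, chrom=1):
        loci = tuple(
            Locus(f"m{i}", chrom, float(p), 1.0, 3.0, -1)
            for i, p in enumerate(positions)
        )
        return QTLModel(trait, loci, 10.0, 2.0)

    def test_five_cm_window_boundary(self):
        merged = iq.merge_qtl(
            [("E1", self._model("Mo", [40.0])), ("E2", self._model("Mo", [44.9]))]
        )
        assert len(merged) == 1
        merged = iq.merge_qtl(
            [("E1", self._model("Mo", [40.0])), ("E2", self._model("Mo", [45.1]))]
        )
        assert len(merged) == 2

    def test_identical_position_many_environments(self):
        models = [(f"E{i}", self._model("Mo", [120.0])) for i in range(9)]
        merged = iq.merge_qtl(models)
        assert len(merged) == 1
        assert merged.loc[0, "n_envs"] == 9

    def test_single_linkage_chains_clusters(self):
        models = [
            ("E1", self._model("Mo", [0.0])),
            ("E2", self._model("Mo", [4.0])),
            ("E3", self._model("Mo", [8.0])),
        ]
        merged = iq.merge_qtl(models)
        assert len(merged) == 1  # 0-4 and 4-8 each within 5 cM

    def test_traits_and_chromosomes_not_mixed(self):
        models = [
            ("E1", self._model("Mo", [40.0], chrom=1)),
            ("E1", self._model("Cd", [40.0], chrom=1)),
            ("E2", self._model("Mo", [40.0], chrom=2)),
        ]
        merged = iq.merge_qtl(models)
        assert len(merged) == 3
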