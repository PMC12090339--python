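"""Ground-truth landscapes and the simulated FRET plate reader."""

import numpy as np
import pytest

from fretlearn import (KineticParams, fixture_bundle, load_landscape,
                       make_landscape, ratio_trajectory, save_landscape,
                       score_plate, simulate_plate, true_fitness)
from fretlearn.fret_scoring import read_plate
from fretlearn.sequence_space import (REGION_A, REGION_B, Variant,
                                      enumerate_space, random_library)


class TestMakeLandscape:
    def test_wildtype_fitness_exactly_one(self):
        for kind in ("sparse", "dense", "additive"):
            land = make_landscape(REGION_B, kind, seed=0)
            assert true_fitness(land, REGION_B.wildtype) == 1.0

    def test_additive_matches_brute_force(self):
        """With zero couplings, fitness is the per-position field sum —
        recomputed independently letter by letter over all 8000 variants."""
        land = make_landscape(REGION_B, "additive", seed=4)
        assert np.all(land.couplings == 0)
        space = enumerate_space(REGION_B)
        # independent recomputation from the stored field terms
        wt_ident = REGION_B.wildtype
        def raw(ident):
            return sum(land.fields[p, REGION_B.alphabet.index(a)]
                       for p, a in enumerate(ident))
        raws = np.array([raw(v.identities) for v in space])
        shifted = raws - raws.min() + 0.05 * raws.std()
        wt_idx = next(i for i, v in enumerate(space)
                      if v.identities == wt_ident)
        shifted[wt_idx] = np.quantile(shifted, 0.95)
        expected = shifted / shifted[wt_idx]
        assert np.allclose(land.fitness_table, expected)

    def test_sparse_gating_fraction(self):
        for seed in range(20):
            land = make_landscape(REGION_A, "sparse", seed=seed)
            assert (land.fitness_table == 0).mean() >= 0.75
            assert true_fitness(land, REGION_A.wildtype) == 1.0

    def test_dense_all_active_and_beats_wt(self):
        for seed in range(10):
            land = make_landscape(REGION_B, "dense", seed=seed)
            assert land.fitness_table.min() > 0
            assert land.max_fitness > 1.0
            assert (land.fitness_table > 1.0).mean() >= 0.01

    def test_unknown_kind_errors(self):
        with pytest.raises(ValueError, match="kind"):
            make_landscape(REGION_B, "rugged", seed=0)

    def test_true_fitness_deterministic(self, dense_landscape):
        v = Variant("B", "KRC", "x")
        vals = {true_fitness(dense_landscape, v) for _ in range(5)}
        assert len(vals) == 1


class TestKinetics:
    def test_threshold_bracketing_enforced(self):
        with pytest.raises(ValueError):
            KineticParams(r0=0.6)
        with pytest.raises(ValueError):
            KineticParams(rmax=0.5)
        with pytest.raises(ValueError):
            KineticParams(noise_sd=-1)

    def test_noiseless_ratio_monotone_single_crossing(self):
        kin = KineticParams(noise_sd=0.0)
        for f in (0.2, 1.0, 3.0):
            r = ratio_trajectory(kin, f)
            assert np.all(np.diff(r) > 0)
            crossings = np.diff((r >= 0.55).astype(int))
            assert (crossings == 1).sum() <= 1 and (crossings == -1).sum() == 0

    def test_zero_fitness_flat_at_r0(self):
        kin = KineticParams(noise_sd=0.0)
        assert np.allclose(ratio_trajectory(kin, 0.0), kin.r0)

    def test_negative_fitness_errors(self):
        with pytest.raises(ValueError):
            ratio_trajectory(KineticParams(), -0.5)


class TestSimulatePlate:
    def test_zero_fitness_scores_zero(self, noiseless_kinetics):
        land = make_landscape(REGION_A, "sparse", seed=0)
        dead_idx = int(np.argmin(land.fitness_table))
        dead = enumerate_space(REGION_A)[dead_idx]
        assert true_fitness(land, dead) == 0.0
        plate = simulate_plate([Variant("A", dead.identities, "dead")], land,
                               noiseless_kinetics, seed=0)
        row = score_plate(plate).set_index("variant_id").loc["dead"]
        assert row.fitness == pytest.approx(0.0, abs=1e-9)

    def test_fourfold_fitness_ratio_recovered(self, noiseless_kinetics,
                                              dense_landscape):
        """Noiseless f=1 vs f=4: scored fitness ratio within 10% of 4 (the
        residual comes from curvature below the truncation threshold)."""
        space = enumerate_space(REGION_B)
        f1 = REGION_B.wildtype_variant()
        kin = noiseless_kinetics
        t = kin.timepoints()
        # use the kinetic model directly at f=4 via a synthetic landscape hit
        from fretlearn.fret_scoring import (FretSeries, fit_initial_slope,
                                            truncate_series)
        s1 = fit_initial_slope(truncate_series(
            FretSeries(t, ratio_trajectory(kin, 1.0, t))))
        s4 = fit_initial_slope(truncate_series(
            FretSeries(t, ratio_trajectory(kin, 4.0, t))))
        assert s4 / s1 == pytest.approx(4.0, rel=0.10)

    def test_noiseless_end_to_end_recovery_within_5pct(self,
                                                       noiseless_kinetics,
                                                       dense_landscape):
        lib = random_library(REGION_B, 20, seed=8)
        plate = simulate_plate(lib, dense_landscape, noiseless_kinetics, 0)
        scores = score_plate(plate).set_index("variant_id")
        for v in lib:
            truth = true_fitness(dense_landscape, v)
            got = scores.loc[v.variant_id, "fitness"]
            assert got == pytest.approx(truth, rel=0.05, abs=1e-6)

    def test_seed_changes_noise_not_backbone(self, dense_landscape):
        lib = [Variant("B", "AAA", "v")]
        kin = KineticParams()
        p1 = simulate_plate(lib, dense_landscape, kin, seed=1)
        p2 = simulate_plate(lib, dense_landscape, kin, seed=2)
        assert not np.allclose(p1.wells["W001"], p2.wells["W001"])
        noiseless = KineticParams(noise_sd=0.0)
        q1 = simulate_plate(lib, dense_landscape, noiseless, seed=1)
        q2 = simulate_plate(lib, dense_landscape, noiseless, seed=2)
        assert np.allclose(q1.wells["W001"], q2.wells["W001"])

    def test_wt_added_automatically(self, dense_landscape):
        plate = simulate_plate([Variant("B", "AAA", "v")], dense_landscape,
                               seed=0)
        assert "WT" in {vid for vid, _ in plate.layout.values()}

    def test_noiseless_ranking_identical_to_truth(self, noiseless_kinetics,
                                                  dense_landscape):
        lib = random_library(REGION_B, 15, seed=9)
        plate = simulate_plate(lib, dense_landscape, noiseless_kinetics, 0)
        scores = score_plate(plate).set_index("variant_id")
        got = scores.loc[[v.variant_id for v in lib], "fitness"].to_numpy()
        truth = np.array([true_fitness(dense_landscape, v) for v in lib])
        assert np.array_equal(np.argsort(got), np.argsort(truth))


class TestSerialization:
    def test_landscape_round_trip(self, tmp_path, dense_landscape):
        save_landscape(dense_landscape, tmp_path / "land.json")
        back = load_landscape(tmp_path / "land.json")
        assert np.allclose(back.fitness_table, dense_landscape.fitness_table)
        assert back.region == dense_landscape.region
        assert back.kind == dense_landscape.kind


class TestFixtureBundle:
    def test_bundle_scores_end_to_end(self, tmp_path):
        manifest = fixture_bundle(seed=1, outdir=tmp_path, n_variants=12)
        assert set(manifest) == {"sparse", "dense", "additive"}
        for kind, files in manifest.items():
            plate = read_plate(tmp_path / files["plate"],
                               tmp_path / files["layout"])
            scores = score_plate(plate)
            assert "WT" in set(scores.variant_id)

    def test_regeneration_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        fixture_bundle(seed=7, outdir=d1, n_variants=6)
        fixture_bundle(seed=7, outdir=d2, n_variants=6)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_dense_bundle_spearman(self, tmp_path):
        """Default-noise dense plates rank variants close to truth
        (Spearman rho >= 0.9, 5 seeds)."""
        from scipy.stats import spearmanr
        for seed in range(5):
            d = tmp_path / str(seed)
            files = fixture_bundle(seed=seed, outdir=d)["dense"]
            plate = read_plate(d / files["plate"], d / files["layout"])
            land = load_landscape(d / files["landscape"])
            scores = score_plate(plate)
            scores = scores[scores.variant_id != "WT"]
            # identities come from the layout's variant ids via the landscape
            # bundle libraries are regenerable from the recorded seed
            from fretlearn.sequence_space import random_library as rl
            lib = {v.variant_id: v
                   for v in rl(land.region, 48, seed=files["lib_seed"])}
            truth = [true_fitness(land, lib[vid])
                     for vid in scores.variant_id]
            rho = spearmanr(scores.fitness, truth).statistic
            assert rho >= 0.9
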