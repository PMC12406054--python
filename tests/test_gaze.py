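"""Memory scoring, fixation density maps, Fisher-z similarity, control
correction, and per-subject behavior differences."""

import numpy as np
import pandas as pd
import pytest

from gazedcm.gaze import (CORR_CLIP, behavior_differences,
                          control_similarity, density_map,
                          memory_strength_score, reinstatement_score,
                          reinstatement_table, similarity_fisher_z)


def fix_df(xy, durations=None):
    xy = np.atleast_2d(xy)
    return pd.DataFrame({
        "x": xy[:, 0], "y": xy[:, 1],
        "duration": durations if durations is not None
        else np.full(len(xy), 250.0)})


class TestMemoryScoring:
    @pytest.mark.parametrize("response,confidence,points", [
        ("old", "high", 2), ("old", "low", 1),
        ("new", "low", 0), ("new", "high", -1)])
    def test_confidence_graded_mapping(self, response, confidence, points):
        assert memory_strength_score("old", response, confidence) == points

    def test_lures_not_scoreable(self):
        with pytest.raises(ValueError):
            memory_strength_score("new", "new", "high")

    def test_unknown_levels_rejected(self):
        with pytest.raises(ValueError):
            memory_strength_score("old", "old", "medium")


class TestDensityMap:
    def test_single_fixation_peak_location(self):
        m = density_map(fix_df([(250, 250)]), 500, 500, sigma=30)
        iy, ix = np.unravel_index(np.argmax(m.grid), m.grid.shape)
        assert (ix, iy) == (250, 250)

    def test_duration_weighting(self):
        m = density_map(fix_df([(100, 100), (400, 400)], [200.0, 400.0]),
                        500, 500, sigma=15)
        near = m.grid[:250, :250].sum()
        far = m.grid[250:, 250:].sum()
        assert far / near == pytest.approx(2.0, rel=0.01)

    def test_mirror_symmetry(self):
        xy = np.array([(120, 80), (300, 400), (410, 250)], float)
        m1 = density_map(fix_df(xy), 500, 500, sigma=20)
        xy_m = xy.copy()
        xy_m[:, 0] = 499 - xy_m[:, 0]
        m2 = density_map(fix_df(xy_m), 500, 500, sigma=20)
        assert np.allclose(m1.grid, m2.grid[:, ::-1], atol=1e-12)

    def test_no_fixations_errors(self):
        with pytest.raises(ValueError):
            density_map(fix_df(np.zeros((0, 2))), 500, 500)


class TestSimilarity:
    def test_identity_hits_the_clip(self):
        m = density_map(fix_df([(100, 200), (300, 150)]), 500, 500, 30)
        z = similarity_fisher_z(m, m)
        assert z == pytest.approx(np.arctanh(CORR_CLIP))
        assert z == pytest.approx(3.8002, abs=1e-3)

    def test_positive_affine_invariance(self):
        m = density_map(fix_df([(100, 200), (300, 150)]), 500, 500, 30)
        scaled = 3.5 * m.grid + 0.7
        assert similarity_fisher_z(m, scaled) == pytest.approx(
            np.arctanh(CORR_CLIP))

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            similarity_fisher_z(np.zeros((10, 10)), np.ones((10, 10)))

    def test_independent_maps_center_on_zero(self):
        """Monte-Carlo null: unrelated 8-fixation maps have mean Fisher z
        within +-0.05 of 0 over 200 seeded pairs."""
        rng = np.random.default_rng(12)
        zs = []
        for _ in range(200):
            a = density_map(fix_df(rng.uniform(20, 480, (8, 2))),
                            500, 500, 63)
            b = density_map(fix_df(rng.uniform(20, 480, (8, 2))),
                            500, 500, 63)
            zs.append(similarity_fisher_z(a, b))
        assert abs(np.mean(zs)) < 0.05


class TestControlSimilarity:
    def _maps(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return {f"img{i}": density_map(
            fix_df(rng.uniform(20, 480, (6, 2))), 500, 500, 40)
            for i in range(n)}

    def test_identical_pool_gives_clip(self):
        m = self._maps(1)["img0"]
        pool = {f"c{i}": m for i in range(5)}
        z = control_similarity(m, pool, k=3, seed=0)
        assert z == pytest.approx(np.arctanh(CORR_CLIP))

    def test_small_pool_flagged_and_used(self):
        maps = self._maps(4)
        with pytest.warns(UserWarning, match="pool"):
            z = control_similarity(maps["img0"], maps, exclude_image="img0",
                                   k=50, seed=0)
        assert np.isfinite(z)

    def test_seeded_draws_reproduce(self):
        maps = self._maps(60)
        z1 = control_similarity(maps["img0"], maps, "img0", k=50, seed=7)
        z2 = control_similarity(maps["img0"], maps, "img0", k=50, seed=7)
        assert z1 == z2

    def test_empty_pool_errors(self):
        maps = self._maps(1)
        with pytest.raises(ValueError):
            control_similarity(maps["img0"], maps, exclude_image="img0")


class TestReinstatement:
    def test_equal_inputs_zero(self):
        assert reinstatement_score(1.3, 1.3) == 0.0

    def test_jittered_replay_scores_positive(self):
        """Retrieval = encoding + 20 px jitter: mean reinstatement over
        synthetic images is clearly positive."""
        rng = np.random.default_rng(3)
        scores = []
        enc_maps = {}
        enc_xy = {}
        for i in range(40):
            xy = rng.uniform(40, 460, (8, 2))
            enc_xy[f"i{i}"] = xy
            enc_maps[f"i{i}"] = density_map(fix_df(xy), 500, 500, 63)
        for i in range(40):
            xy = enc_xy[f"i{i}"] + rng.normal(0, 20, (8, 2))
            ret = density_map(fix_df(np.clip(xy, 1, 498)), 500, 500, 63)
            matched = similarity_fisher_z(ret, enc_maps[f"i{i}"])
            control = control_similarity(ret, enc_maps, f"i{i}", k=30,
                                         seed=rng)
            scores.append(reinstatement_score(matched, control))
        assert np.mean(scores) > 0.3

    def test_overlap_monotonicity(self):
        """Tighter replay jitter (80 -> 40 -> 20 px) strictly increases the
        mean reinstatement score."""
        rng = np.random.default_rng(4)
        enc_xy = {f"i{i}": rng.uniform(40, 460, (8, 2)) for i in range(30)}
        enc_maps = {k: density_map(fix_df(v), 500, 500, 63)
                    for k, v in enc_xy.items()}
        means = []
        for jitter in (80.0, 40.0, 20.0):
            scores = []
            for k, xy in enc_xy.items():
                ret = density_map(
                    fix_df(np.clip(xy + rng.normal(0, jitter, xy.shape),
                                   1, 498)), 500, 500, 63)
                matched = similarity_fisher_z(ret, enc_maps[k])
                control = control_similarity(ret, enc_maps, k, k=29,
                                             seed=rng)
                scores.append(matched - control)
            means.append(np.mean(scores))
        assert means[0] < means[1] < means[2]


class TestBehaviorDifferences:
    def _tables(self):
        mem = pd.DataFrame({
            "subject": ["s1"] * 4 + ["s2"] * 4,
            "condition": ["free", "free", "fixed", "fixed"] * 2,
            "score": [2, 1, 1, 0, 1, 1, 1, 1]})
        gz = pd.DataFrame({
            "subject": ["s1"] * 4 + ["s2"] * 4,
            "condition": ["free", "free", "fixed", "fixed"] * 2,
            "reinstatement": [0.5, 0.7, 0.1, 0.1, 0.2, 0.2, 0.2, 0.2]})
        return mem, gz

    def test_free_minus_fixed_and_centering(self):
        mem, gz = self._tables()
        tab = behavior_differences(mem, gz)
        # raw deltas: s1 -> 1.0, s2 -> 0.0; centered -> +-0.5
        assert tab.loc["s1", "d_memory"] == pytest.approx(0.5)
        assert tab.loc["s2", "d_memory"] == pytest.approx(-0.5)
        assert abs(tab["d_memory"].mean()) < 1e-9
        assert abs(tab["d_gaze"].mean()) < 1e-9

    def test_point_shift_is_linear(self):
        # +1 point on every free trial of s1 raises s1's uncentered delta
        # by exactly 1; after centering over N=2 subjects that is 1 - 1/2
        mem, gz = self._tables()
        mem2 = mem.copy()
        sel = (mem2["subject"] == "s1") & (mem2["condition"] == "free")
        mem2.loc[sel, "score"] += 1
        t1 = behavior_differences(mem, gz)
        t2 = behavior_differences(mem2, gz)
        assert (t2.loc["s1", "d_memory"] - t1.loc["s1", "d_memory"]) \
            == pytest.approx(0.5)
        assert (t2.loc["s2", "d_memory"] - t1.loc["s2", "d_memory"]) \
            == pytest.approx(-0.5)

    def test_missing_condition_drops_subject(self):
        mem, gz = self._tables()
        mem_missing = mem[~((mem["subject"] == "s2")
                            & (mem["condition"] == "fixed"))]
        with pytest.warns(UserWarning, match="missing"):
            tab = behavior_differences(mem_missing, gz)
        assert list(tab.index) == ["s1"]


class TestReinstatementTable:
    def test_planted_replay_detected_per_condition(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(12):
            enc = rng.uniform(30, 170, (6, 2))
            ret = np.clip(enc + rng.normal(0, 8, enc.shape), 1, 198)
            for phase, xy in (("encoding", enc), ("retrieval", ret)):
                for x, y in xy:
                    rows.append({"subject": "s1", "image": f"i{i}",
                                 "phase": phase, "condition": "free",
                                 "x": x, "y": y, "duration": 250.0})
        fix = pd.DataFrame(rows)
        tab = reinstatement_table(fix, 200, 200, sigma=25, k=11, seed=0)
        assert len(tab) == 12
        assert tab["reinstatement"].mean() > 0.2
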