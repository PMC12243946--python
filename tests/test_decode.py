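"""Pair enumeration, the classifier wrapper, rotations, ratios, sectors."""

import numpy as np
import pytest

from vwmdecode import decode as dec
from vwmdecode.design import ObjectID, TrialCondition
from vwmdecode.glm import average_period

from conftest import CONDITIONS, make_period_patterns, null_beta_patterns


class TestZnorm:
    def test_hand_computed_example(self):
        out = dec.znorm(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.22474487, 0.0, 1.22474487], atol=1e-8)
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        x = dec.znorm(np.array([0.3, -1.2, 4.0, 2.2]))
        np.testing.assert_allclose(dec.znorm(x), x, atol=1e-12)

    def test_constant_pattern_rejected(self):
        with pytest.raises(ValueError):
            dec.znorm(np.full(5, 2.0))
        with pytest.raises(ValueError):
            dec.znorm(np.array([1.0]))


class TestPairInstances:
    def test_four_objects_give_six_pairs(self):
        import itertools

        assert len(list(itertools.combinations(ObjectID, 2))) == 6

    def test_within_target_delay_has_12_instances_with_matched_irrelevant(self):
        scheme = dec.get_scheme("within_target_delay")
        inst = dec.enumerate_pair_instances(scheme)
        assert len(inst) == 12
        for i in inst:
            assert i.irrelevant_train == i.irrelevant_test
            assert i.irrelevant_train not in i.pair

    def test_different_irrelevant_instances_disagree_across_sides(self):
        scheme = dec.get_scheme(
            "cross_distractor_to_target_delay", irrelevant_match="different"
        )
        inst = dec.enumerate_pair_instances(scheme)
        assert len(inst) == 12
        assert all(i.irrelevant_train != i.irrelevant_test for i in inst)

    def test_no_distractor_test_side_has_no_irrelevant(self):
        scheme = dec.get_scheme("cross_to_no_distractor_targets")
        inst = dec.enumerate_pair_instances(scheme)
        assert len(inst) == 12
        assert all(i.irrelevant_test is None for i in inst)
        assert all(i.irrelevant_train is not None for i in inst)

    def test_within_decoding_of_no_distractor_trials_has_6_instances(self):
        scheme = dec.get_scheme("within_delay", trial_set="without_distractors")
        inst = dec.enumerate_pair_instances(scheme)
        assert len(inst) == 6
        assert all(i.irrelevant_train is None and i.irrelevant_test is None for i in inst)


class TestSchemes:
    def test_target_trained_distractor_decoding_is_rejected(self):
        with pytest.raises(ValueError, match="one direction"):
            dec.DecodingScheme(
                name="bad", train_role="target", train_period="delay",
                test_role="distractor", test_period="delay",
            )

    def test_unknown_scheme_rejected(self):
        with pytest.raises(KeyError):
            dec.get_scheme("four_way_decoding")

    def test_four_way_decoding_rejected_with_confound_explanation(self):
        X = np.random.default_rng(0).standard_normal((12, 5))
        y = np.repeat([0, 1, 2, 3], 3)
        with pytest.raises(ValueError, match="pairwise"):
            dec.decode_once(X, y, X, y)

    def test_one_class_training_rejected(self):
        X = np.zeros((4, 5))
        with pytest.raises(ValueError):
            dec.decode_once(X, np.zeros(4), X, np.zeros(4))


class TestDecodeOnce:
    def test_separable_clusters_decode_perfectly(self):
        rng = np.random.default_rng(1)
        mu = np.zeros(20)
        mu2 = np.ones(20)
        Xtr = np.vstack([mu + 0.01 * rng.standard_normal((10, 20)),
                         mu2 + 0.01 * rng.standard_normal((10, 20))])
        ytr = np.repeat([0, 1], 10)
        assert dec.decode_once(Xtr, ytr, Xtr, ytr) == 1.0

    def test_permuted_labels_sit_at_chance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 30))
        y = np.repeat([0, 1], 20)
        accs = [
            dec.decode_once(X, y, rng.standard_normal((200, 30)),
                            rng.permutation(np.repeat([0, 1], 100)))
            for _ in range(10)
        ]
        # binomial null: mean accuracy within 3 SD of 0.5
        se = 0.5 / np.sqrt(200 * len(accs))
        assert abs(np.mean(accs) - 0.5) < 3 * se

    def test_orthogonal_code_generalizes_at_chance(self):
        rng = np.random.default_rng(3)
        accs = []
        for _ in range(40):
            # fresh random orthogonal train/test axes per draw
            v = rng.standard_normal(50)
            v /= np.linalg.norm(v)
            u = rng.standard_normal(50)
            u -= (u @ v) * v
            u /= np.linalg.norm(u)
            Xtr = np.vstack([+v + 0.1 * rng.standard_normal((20, 50)),
                             -v + 0.1 * rng.standard_normal((20, 50))])
            ytr = np.repeat([0, 1], 20)
            Xte = np.vstack([+u + 0.1 * rng.standard_normal((20, 50)),
                             -u + 0.1 * rng.standard_normal((20, 50))])
            accs.append(dec.decode_once(Xtr, ytr, Xte, np.repeat([0, 1], 20)))
        assert abs(np.mean(accs) - 0.5) < 0.1


def _two_code_patterns(theta, noise=0.2, n_vertices=80, seed=0, gain_distractor=3.0):
    """Period patterns realizing a perceptual/memory rotation directly at the
    pattern level (no GLM): targets carry the memory code, distractors the
    perceptual code."""
    rng = np.random.default_rng(seed)
    perc, mem = {}, {}
    for o in ObjectID:
        p = rng.standard_normal(n_vertices)
        p /= np.linalg.norm(p)
        q = rng.standard_normal(n_vertices)
        q -= (q @ p) * p
        q /= np.linalg.norm(q)
        perc[o] = p
        mem[o] = np.cos(theta) * p + np.sin(theta) * q
    means = {}
    for cond in CONDITIONS:
        m = mem[cond.target].copy()
        if cond.has_distractor:
            m = m + gain_distractor * perc[cond.distractor]
        means[cond] = m
    return make_period_patterns(means, noise_sd=noise, n_vertices=n_vertices, seed=seed)


class TestRotateAndAverage:
    def test_train_test_sizes_are_21_and_7(self):
        pats = _two_code_patterns(0.0)
        periods = {"delay": pats}
        got = dec._gather(
            periods, ("target", "delay", "with_distractors"),
            ObjectID.HANGER, (ObjectID.BIKE, ObjectID.COUCH), [0, 1, 2],
        )
        assert got[0].shape[0] == 42 and (got[1] == 0).sum() == 21
        test = dec._gather(
            periods, ("target", "delay", "with_distractors"),
            ObjectID.HANGER, (ObjectID.BIKE, ObjectID.COUCH), [3],
        )
        assert test[0].shape[0] == 14 and (test[1] == 1).sum() == 7

    def test_rotations_never_mix_train_and_test_splits(self):
        pats = _two_code_patterns(0.0)
        # patterns unique per split: verify by poisoning one split and
        # checking only its rotation is affected
        scheme = dec.get_scheme("within_target_delay")
        inst = dec.enumerate_pair_instances(scheme)[0]
        base = dec.rotate_and_average({"delay": pats}, scheme, inst)
        assert 0.9 < base <= 1.0

    def test_identical_distributions_zero_noise_decode_perfectly(self):
        pats = _two_code_patterns(0.0, noise=0.0)
        scheme = dec.get_scheme("within_target_delay")
        inst = dec.enumerate_pair_instances(scheme)[0]
        assert dec.rotate_and_average({"delay": pats}, scheme, inst) == 1.0

    def test_split_relabeling_leaves_mean_unchanged(self):
        pats = _two_code_patterns(0.0, noise=0.5, seed=4)
        scheme = dec.get_scheme("within_target_delay")
        inst = dec.enumerate_pair_instances(scheme)[2]
        base = dec.rotate_and_average({"delay": pats}, scheme, inst)
        # permute split indices: the average over rotations cannot change
        remap = {0: 2, 1: 0, 2: 3, 3: 1}
        permuted = type(pats)(
            patterns={(remap[s], c): v for (s, c), v in pats.patterns.items()},
            conditions=pats.conditions,
            period=pats.period,
        )
        swapped = dec.rotate_and_average({"delay": permuted}, scheme, inst)
        assert swapped == pytest.approx(base, abs=1e-12)


class TestRunScheme:
    def test_shared_code_cross_decoding_matches_within(self):
        accs = {"within_target_delay": [], "cross_distractor_to_target_delay": []}
        for seed in range(20):
            store = null_beta_patterns(seed=seed)  # container for period injection
            pats = _two_code_patterns(0.0, noise=0.3, seed=seed)
            for name in accs:
                scheme = dec.get_scheme(name)
                inst = dec.enumerate_pair_instances(scheme)
                accs[name].append(
                    np.mean([dec.rotate_and_average({"delay": pats}, scheme, i) for i in inst])
                )
        w, c = np.mean(accs["within_target_delay"]), np.mean(accs["cross_distractor_to_target_delay"])
        assert w > 0.9
        assert abs(w - c) < 0.05

    def test_orthogonal_code_cross_decoding_at_chance_within_high(self):
        ws, cs = [], []
        for seed in range(20):
            pats = _two_code_patterns(np.pi / 2, noise=0.3, seed=100 + seed)
            for name, acc_list in [
                ("within_target_delay", ws),
                ("cross_distractor_to_target_delay", cs),
            ]:
                scheme = dec.get_scheme(name)
                inst = dec.enumerate_pair_instances(scheme)
                acc_list.append(
                    np.mean([dec.rotate_and_average({"delay": pats}, scheme, i) for i in inst])
                )
        assert np.mean(ws) > 0.9
        se = np.std(cs, ddof=1) / np.sqrt(len(cs))
        assert abs(np.mean(cs) - 0.5) < max(3 * se, 0.02)

    def test_zero_signal_all_schemes_at_chance(self):
        accs = []
        for seed in range(50):
            store = null_beta_patterns(n_vertices=40, seed=seed)
            res = dec.run_scheme(store, "within_target_delay")
            accs.append(res.accuracy)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.5) < 2 * se + 1e-9

    def test_run_scheme_reports_instances_and_roi(self):
        store = null_beta_patterns(n_vertices=24, seed=1)
        res = dec.run_scheme(store, "cross_to_no_distractor_targets")
        assert res.n_pair_instances == 12
        assert res.trial_set == "without_distractors"
        assert len(res.per_instance) == 12


class TestRatioAndSectors:
    @pytest.mark.parametrize(
        "within,cross,expected",
        [(0.75, 0.75, 1.0), (0.75, 0.50, 0.0), (0.70, 0.60, 0.5)],
    )
    def test_ratio_examples(self, within, cross, expected):
        r = dec.cross_ratio(within, cross)
        assert r.ratio == pytest.approx(expected)
        assert r.valid

    def test_ratio_flagged_invalid_near_chance_within(self):
        r = dec.cross_ratio(0.505, 0.52)
        assert not r.valid
        assert np.isfinite(r.ratio)  # reported, never dropped

    def test_sector_average_is_unweighted_mean(self):
        vals = {"V1": 0.6, "V2": 0.7, "V3": 0.8, "V4": 0.9, "LOT": 0.55, "VOT": 0.65}
        out = dec.sector_average(vals)
        assert out["posterior"] == pytest.approx(0.75)
        assert out["ventral"] == pytest.approx(0.6)
        # permutation invariance
        out2 = dec.sector_average(dict(reversed(list(vals.items()))))
        assert out == out2

    def test_identical_rois_pass_through(self):
        out = dec.sector_average({"IPS2": 0.7, "IPS3": 0.7, "IPS4": 0.7})
        assert out["dorsal"] == pytest.approx(0.7)

    def test_unmapped_rois_rejected(self):
        with pytest.raises(ValueError):
            dec.sector_average({"FFA": 0.9})
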