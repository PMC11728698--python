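import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from skbio.diversity.beta import weighted_unifrac as skbio_wuf
from skbio.stats.composition import clr as skbio_clr, multi_replace as skbio_multi_replace

from profspace import (
    AbundanceTable,
    ConfusionCounts,
    ValidationError,
    aitchison,
    bray_curtis,
    confusion_counts,
    evaluate_sample_set,
    fpra_fnra,
    richness_shannon,
    sensitivity_precision,
    tpra,
    tree_from_newick,
    weighted_unifrac,
)
from profspace.metrics import multiplicative_replacement
from profspace.synthetic import generate_tree
from conftest import random_table
import oracles


def series(vals, feats=None):
    feats = feats or [f"F{i}" for i in range(len(vals))]
    return pd.Series(list(vals), index=feats, dtype=float)


class TestConfusionCounts:
    def test_mixed_sample(self):
        c = confusion_counts(series([0.5, 0.5, 0]), series([0.4, 0, 0.6]))
        assert (c.TP, c.FN, c.FP) == (1, 1, 1)

    def test_perfect_estimate(self):
        r = series([0.2, 0.3, 0.5])
        c = confusion_counts(r, r)
        assert (c.FP, c.FN) == (0, 0)

    def test_empty_estimate(self):
        c = confusion_counts(series([0.2, 0.3, 0.5]), series([0, 0, 0]))
        assert (c.TP, c.FN, c.FP) == (0, 3, 0)

    def test_mismatched_indices_error(self):
        with pytest.raises(ValidationError):
            confusion_counts(series([1.0], ["A"]), series([1.0], ["B"]))


class TestSensitivityPrecision:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(TP=3, FP=0, FN=1), (0.75, 1.0)),
            (ConfusionCounts(TP=1, FP=1, FN=1), (0.5, 0.5)),
        ],
    )
    def test_defined(self, counts, expected):
        assert sensitivity_precision(counts) == pytest.approx(expected)

    def test_zero_denominator_is_undefined_not_error(self):
        sens, prec = sensitivity_precision(ConfusionCounts(TP=0, FP=2, FN=0))
        assert math.isnan(sens) and prec == 0.0

    def test_support_only_invariance(self, rng):
        # sensitivity/precision depend only on support sets, not magnitudes
        r = series([0.5, 0.5, 0])
        e = series([0.4, 0, 0.6])
        scale = series([0.25, 0, 0.75])
        a = sensitivity_precision(confusion_counts(r, e))
        b = sensitivity_precision(confusion_counts(r, scale))
        assert a == b


class TestFpraFnra:
    def test_mixed_sample(self):
        fpra, fnra = fpra_fnra(series([0.5, 0.5, 0]), series([0.4, 0, 0.6]))
        assert (fpra, fnra) == pytest.approx((0.6, 0.5))

    def test_perfect_estimate(self):
        r = series([0.2, 0.8])
        assert fpra_fnra(r, r) == (0.0, 0.0)

    def test_everything_on_false_positives(self):
        fpra, _ = fpra_fnra(series([1, 0, 0]), series([0, 0.5, 0.5]))
        assert fpra == pytest.approx(1.0)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValidationError):
            fpra_fnra(series([0.4, 0.4]), series([0.5, 0.5]))

    def test_fpra_plus_tp_mass_is_one(self, rng):
        for _ in range(20):
            t = random_table(rng, 12, 2)
            r, e = t.data["S000"], t.data["S001"]
            fpra, _ = fpra_fnra(r, e)
            tp_mass = e[(r > 0) & (e > 0)].sum()
            assert fpra + tp_mass == pytest.approx(1.0, abs=1e-12)
            assert tpra(fpra) == pytest.approx(tp_mass, abs=1e-12)


class TestRichnessShannon:
    def test_uniform_closed_form(self):
        rich, shan = richness_shannon(series([0.25] * 4))
        assert rich == 4
        assert shan == pytest.approx(math.log(4), abs=1e-9)

    def test_single_feature(self):
        assert richness_shannon(series([1.0, 0.0])) == (1, 0.0)

    def test_half_quarter_quarter(self):
        _, shan = richness_shannon(series([0.5, 0.25, 0.25]))
        assert shan == pytest.approx(1.5 * math.log(2), abs=1e-12)


class TestBrayCurtis:
    def test_identical_is_zero(self):
        u = series([0.7, 0.3])
        assert bray_curtis(u, u) == 0.0

    def test_disjoint_support_is_one(self):
        assert bray_curtis(series([1, 0]), series([0, 1])) == pytest.approx(1.0)

    def test_hand_value(self):
        assert bray_curtis(series([0.7, 0.3]), series([0.5, 0.5])) == pytest.approx(0.2)

    def test_both_zero_undefined(self):
        assert math.isnan(bray_curtis(series([0, 0]), series([0, 0])))

    def test_matches_scipy(self, rng):
        for _ in range(20):
            u, v = rng.random(10), rng.random(10)
            assert bray_curtis(u, v) == pytest.approx(
                scipy_braycurtis(u, v), abs=1e-12
            )


class TestWeightedUnifrac:
    def test_identical_is_zero(self):
        t = tree_from_newick("((A:1,B:2):1,C:3);")
        u = series([0.5, 0.2, 0.3], ["A", "B", "C"])
        assert weighted_unifrac(u, u, t) == 0.0

    def test_two_leaf_star_disjoint(self):
        t = tree_from_newick("(A:1,B:1);")
        d = weighted_unifrac(series([1, 0], ["A", "B"]), series([0, 1], ["A", "B"]), t)
        assert d == pytest.approx(1.0)

    def test_star_tree_equals_bray_curtis(self, rng):
        feats = [f"L{i}" for i in range(8)]
        t = tree_from_newick("(" + ",".join(f"{f}:1" for f in feats) + ");")
        for _ in range(100):
            u = rng.random(8) * (rng.random(8) < 0.7)
            v = rng.random(8) * (rng.random(8) < 0.7)
            if u.sum() == 0 or v.sum() == 0:
                continue
            u, v = u / u.sum(), v / v.sum()
            d = weighted_unifrac(series(u, feats), series(v, feats), t)
            assert d == pytest.approx(bray_curtis(u, v), abs=1e-12)

    def test_missing_features_dropped_with_warning(self):
        t = tree_from_newick("(A:1,B:1);")
        u = series([0.5, 0.25, 0.25], ["A", "B", "Q"])
        v = series([0.25, 0.5, 0.25], ["A", "B", "Q"])
        with pytest.warns(UserWarning, match="absent from tree"):
            d = weighted_unifrac(u, v, t)
        # after dropping Q both re-close to (2/3, 1/3) vs (1/3, 2/3)
        assert d == pytest.approx(1 / 3)
        with pytest.raises(ValidationError):
            weighted_unifrac(u, v, t, strict=True)

    def test_zero_length_tree_rejected(self):
        t = tree_from_newick("(A:0,B:0);")
        with pytest.raises(ValidationError, match="branch length"):
            weighted_unifrac(series([1, 0], ["A", "B"]), series([0, 1], ["A", "B"]), t)

    def test_matches_skbio_on_integer_counts(self, rng):
        feats = [f"L{i}" for i in range(9)]
        tree = generate_tree(feats, seed=5)
        for _ in range(10):
            u = rng.integers(0, 50, size=9).astype(float)
            v = rng.integers(0, 50, size=9).astype(float)
            if u.sum() == 0 or v.sum() == 0:
                continue
            ours = weighted_unifrac(series(u, feats), series(v, feats), tree)
            theirs = skbio_wuf(u, v, taxa=feats, tree=tree.tree, normalized=True)
            assert ours == pytest.approx(theirs, abs=1e-10)


class TestAitchison:
    def test_identical_no_zeros(self):
        u = series([0.4, 0.6])
        assert aitchison(u, u) == 0.0

    def test_closed_form_two_parts(self):
        d = aitchison(series([0.4, 0.6]), series([0.6, 0.4]))
        assert d == pytest.approx(math.sqrt(2) * abs(math.log(0.4 / 0.6)), abs=1e-9)

    def test_scale_invariance_after_reclosure(self):
        u = np.array([0.2, 0.3, 0.5])
        v = np.array([0.5, 0.3, 0.2])
        scaled_u = (u * 3) / (u * 3).sum()
        scaled_v = (v * 3) / (v * 3).sum()
        assert aitchison(series(u), series(v)) == pytest.approx(
            aitchison(series(scaled_u), series(scaled_v)), abs=1e-12
        )

    def test_replacement_exceeding_unit_mass_rejected(self):
        with pytest.raises(ValidationError, match="unit mass"):
            aitchison(series([1, 0, 0]), series([0, 0.5, 0.5]), delta=0.6)

    def test_replacement_matches_skbio(self, rng):
        for _ in range(10):
            x = rng.random(8) * (rng.random(8) < 0.6)
            if x.sum() == 0:
                continue
            x = x / x.sum()
            ours = multiplicative_replacement(x, 1 / 64)
            theirs = skbio_multi_replace(x, delta=1 / 64)
            np.testing.assert_allclose(ours, theirs, rtol=1e-12)

    def test_clr_distance_matches_skbio(self, rng):
        u = rng.dirichlet(np.ones(6))
        v = rng.dirichlet(np.ones(6))
        ours = aitchison(series(u), series(v))
        theirs = np.linalg.norm(skbio_clr(u) - skbio_clr(v))
        assert ours == pytest.approx(theirs, abs=1e-10)


class TestOracleEquivalence:
    """Brute-force (loops + per-edge leaf-set enumeration) agreement."""

    def test_distances_match_brute_force(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 13))
            feats = [f"L{i}" for i in range(n)]
            tree = generate_tree(feats, seed=int(rng.integers(1, 10_000)))
            u = rng.random(n) * (rng.random(n) < 0.7)
            v = rng.random(n) * (rng.random(n) < 0.7)
            if u.sum() == 0 or v.sum() == 0:
                continue
            u, v = u / u.sum(), v / v.sum()
            su, sv = series(u, feats), series(v, feats)
            assert bray_curtis(su, sv) == pytest.approx(
                oracles.bray_curtis_brute(u, v), abs=1e-9
            )
            assert weighted_unifrac(su, sv, tree) == pytest.approx(
                oracles.weighted_unifrac_brute(u, v, tree.tree, feats), abs=1e-9
            )
            assert aitchison(su, sv) == pytest.approx(
                oracles.aitchison_brute(u, v, 1 / n**2), abs=1e-9
            )

    def test_metric_axioms(self, rng):
        feats = [f"L{i}" for i in range(6)]
        tree = generate_tree(feats, seed=11)
        for _ in range(20):
            u = rng.dirichlet(np.ones(6))
            v = rng.dirichlet(np.ones(6))
            su, sv = series(u, feats), series(v, feats)
            for metric in (
                bray_curtis,
                lambda a, b: weighted_unifrac(a, b, tree),
                aitchison,
            ):
                d_uv, d_vu = metric(su, sv), metric(sv, su)
                assert d_uv == pytest.approx(d_vu, abs=1e-12)
                assert d_uv >= 0
                assert metric(su, su) == pytest.approx(0.0, abs=1e-12)


class TestEvaluateSampleSet:
    def test_perfect_profiler(self, rng):
        t = random_table(rng, 20, 4)
        tree = generate_tree(t.feature_ids, seed=3)
        rep = evaluate_sample_set(t, t, tree=tree)
        assert rep.medians["sensitivity"] == 1.0
        assert rep.medians["precision"] == 1.0
        for metric in ("bray_curtis", "unifrac", "aitchison", "richness_diff",
                       "fpra", "fnra", "shannon_diff"):
            assert rep.medians[metric] == 0.0

    def test_single_sample_medians_equal_values(self, rng):
        t = random_table(rng, 10, 1)
        e = random_table(np.random.default_rng(1), 10, 1)
        rep = evaluate_sample_set(t, e)
        assert rep.medians["bray_curtis"] == rep.per_sample["bray_curtis"].iloc[0]

    def test_median_of_three(self):
        df_r = pd.DataFrame(np.array([[0.5, 0.5, 0.5], [0.5, 0.5, 0.5]]),
                            index=["A", "B"], columns=["S1", "S2", "S3"])
        df_e = pd.DataFrame(np.array([[0.55, 0.6, 0.95], [0.45, 0.4, 0.05]]),
                            index=["A", "B"], columns=["S1", "S2", "S3"])
        rep = evaluate_sample_set(AbundanceTable(df_r), AbundanceTable(df_e))
        vals = sorted(rep.per_sample["bray_curtis"])
        assert rep.medians["bray_curtis"] == pytest.approx(vals[1])

    def test_no_shared_samples_error(self, rng):
        a = random_table(rng, 5, 2)
        b = AbundanceTable(a.data.rename(columns={"S000": "X0", "S001": "X1"}))
        with pytest.raises(ValidationError, match="share no samples"):
            evaluate_sample_set(a, b)

    def test_undefined_values_excluded_with_count(self):
        # estimate column all-zero: precision undefined there
        df_r = pd.DataFrame({"S1": {"A": 1.0}, "S2": {"A": 1.0}})
        df_e = pd.DataFrame({"S1": {"A": 1.0}, "S2": {"A": 0.0}})
        rep = evaluate_sample_set(AbundanceTable(df_r), AbundanceTable(df_e))
        assert rep.n_undefined["precision"] == 1
        assert rep.medians["precision"] == 1.0

    def test_feature_union_imputes_zeros(self):
        df_r = pd.DataFrame({"S1": {"A": 1.0}})
        df_e = pd.DataFrame({"S1": {"B": 1.0}})
        rep = evaluate_sample_set(AbundanceTable(df_r), AbundanceTable(df_e))
        assert rep.per_sample["bray_curtis"].iloc[0] == pytest.approx(1.0)
        assert rep.per_sample["fpra"].iloc[0] == pytest.approx(1.0)
        assert rep.per_sample["fnra"].iloc[0] == pytest.approx(1.0)
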