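import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import exponential_cohort, make_expression, make_survival
from cupronet.io import GeneSet
from cupronet.signature import (aggregate_pan_cancer, assign_direction,
                                assign_signature_subtype, intersect_critical,
                                logrank, median_dichotomize, spectral_stratify,
                                univariate_cox)


class TestCatalog:
    def test_intersection(self):
        class FakeControl:
            critical = frozenset({"A", "B", "C"})
        assert intersect_critical(FakeControl, GeneSet("cu", {"B", "D"})) == {"B"}
        assert intersect_critical(FakeControl, GeneSet("cu", {"X"})) == frozenset()
        assert intersect_critical(FakeControl, GeneSet("cu", {"A", "B", "C"})) \
            == {"A", "B", "C"}

    def test_aggregate_counts(self):
        cat = aggregate_pan_cancer({"A": ["g1", "g2"], "B": ["g2", "g3"]})
        assert cat.pan_cancer == frozenset({"g1", "g2", "g3"})
        assert cat.multi_cancer == frozenset({"g2"})
        assert aggregate_pan_cancer({"A": ["g1"]}).multi_cancer == frozenset()

    def test_constructed_pan_cancer_catalog(self):
        # 23 cancer types; 57 unique genes of which 40 recur in >= 2 types
        shared = [f"m{i:02d}" for i in range(40)]
        unique = [f"u{i:02d}" for i in range(17)]
        per_cancer = {}
        for c in range(23):
            genes = {shared[(c * 2 + k) % 40] for k in range(4)}
            per_cancer[f"C{c:02d}"] = genes
        # force every shared gene into >= 2 cancers via a second pass
        for i, g in enumerate(shared):
            per_cancer[f"C{i % 23:02d}"] = per_cancer[f"C{i % 23:02d}"] | {g}
            per_cancer[f"C{(i + 1) % 23:02d}"] = per_cancer[f"C{(i + 1) % 23:02d}"] | {g}
        for i, g in enumerate(unique):
            per_cancer[f"C{i % 23:02d}"] = per_cancer[f"C{i % 23:02d}"] | {g}
        cat = aggregate_pan_cancer(per_cancer)
        assert len(cat.pan_cancer) == 57
        assert len(cat.multi_cancer) == 40


class TestUnivariateCox:
    def test_constant_covariate_convention(self):
        surv = make_survival([10, 20, 30, 40], [1, 1, 0, 1])
        x = pd.Series(2.0, index=surv.sample_ids)
        fit = univariate_cox(x, surv)
        assert fit.hazard_ratio == 1.0 and fit.p_value == 1.0

    def test_no_events_rejected(self):
        surv = make_survival([10, 20], [0, 0])
        with pytest.raises(ValueError, match="event"):
            univariate_cox(pd.Series([1.0, 2.0], index=surv.sample_ids), surv)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 2000)
        surv = exponential_cohort(rng, x, beta=0.7)
        fit = univariate_cox(pd.Series(x, index=surv.sample_ids), surv)
        assert fit.coef == pytest.approx(0.7, abs=0.1)


class TestAssignDirection:
    @pytest.mark.parametrize("statuses, expected", [
        (["up", "up", "down"], "up"),
        (["up", "down"], "unclassified"),
        (["ns", "ns", "down"], "down"),     # ns abstains from the vote
        (["ns", "ns"], "unclassified"),
        (["down", "down", "up", "ns"], "down"),
    ])
    def test_vote(self, statuses, expected):
        assert assign_direction(statuses) == expected


class TestMedianDichotomize:
    @pytest.mark.parametrize("values, expected", [
        ([1, 2, 3], ["low", "low", "high"]),   # median tie goes low
        ([5, 5, 5], ["low", "low", "low"]),
        ([1, 4], ["low", "high"]),
    ])
    def test_examples(self, values, expected):
        out = median_dichotomize(pd.Series(values, index=list("abc"[:len(values)])))
        assert list(out) == expected


UP8 = ["CDK1", "AP1S1", "CASP3", "TMPRSS6", "GSK3B"]
DOWN8 = ["MAP1LC3A", "SNCA", "MAPT"]


class TestSubtypeRule:
    def _assign(self, pattern):
        hl = pd.DataFrame({g: [v] for g, v in pattern.items()}, index=["p1"])
        return assign_signature_subtype(
            hl, GeneSet("up", set(UP8)), GeneSet("down", set(DOWN8))).labels["p1"]

    def test_good_prognosis_pattern_is_subtype2(self):
        pattern = {g: "high" for g in DOWN8} | {g: "low" for g in UP8}
        assert self._assign(pattern) == 2

    def test_mirror_pattern_is_subtype1(self):
        pattern = {g: "low" for g in DOWN8} | {g: "high" for g in UP8}
        assert self._assign(pattern) == 1

    def test_one_mismatch_is_subtype3(self):
        pattern = {g: "high" for g in DOWN8} | {g: "low" for g in UP8}
        pattern["CDK1"] = "high"
        assert self._assign(pattern) == 3

    def test_overlapping_sets_rejected(self):
        hl = pd.DataFrame({"A": ["high"], "B": ["low"]}, index=["p1"])
        with pytest.raises(ValueError, match="overlap"):
            assign_signature_subtype(hl, GeneSet("u", {"A"}), GeneSet("d", {"A", "B"}))

    def test_partition(self):
        rng = np.random.default_rng(5)
        genes = UP8 + DOWN8
        hl = pd.DataFrame(rng.choice(["high", "low"], size=(50, 8)),
                          columns=genes, index=[f"p{i}" for i in range(50)])
        labels = assign_signature_subtype(
            hl, GeneSet("up", set(UP8)), GeneSet("down", set(DOWN8))).labels
        assert set(labels.unique()) <= {1, 2, 3}
        assert labels.notna().all() and len(labels) == 50


class TestSpectralStratify:
    def _blob_matrix(self, rng, sep=10.0, n=100, p=5):
        x = np.vstack([rng.normal(0, 1, (n // 2, p)),
                       rng.normal(sep, 1, (n // 2, p))])
        return make_expression(x.T, scale="log2", condition=["tumour"] * n), \
            [0] * (n // 2) + [1] * (n // 2)

    def test_separated_blobs_ari_one(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            m, truth = self._blob_matrix(rng)
            labels = spectral_stratify(m, k=2, seed=seed).labels
            assert adjusted_rand_score(truth, labels) == 1.0

    def test_duplicated_samples_share_label(self):
        rng = np.random.default_rng(1)
        m, _ = self._blob_matrix(rng, n=40)
        dup = pd.concat([m.values, m.values.add_suffix("_d")], axis=1)
        md = make_expression(dup.to_numpy(), scale="log2",
                             condition=["tumour"] * dup.shape[1],
                             genes=list(m.values.index), samples=list(dup.columns))
        labels = spectral_stratify(md, k=2, seed=2).labels
        for s in m.sample_ids:
            assert labels[s] == labels[s + "_d"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        m, _ = self._blob_matrix(rng)
        perm = rng.permutation(m.n_samples)
        mp = make_expression(m.values.iloc[:, perm].to_numpy(), scale="log2",
                             condition=["tumour"] * m.n_samples,
                             genes=list(m.values.index),
                             samples=[m.sample_ids[i] for i in perm])
        a = spectral_stratify(m, k=2, seed=4).labels
        b = spectral_stratify(mp, k=2, seed=4).labels
        assert adjusted_rand_score(a.loc[b.index], b) == 1.0

    def test_too_many_clusters_rejected(self):
        m = make_expression([[1.0, 2.0]], scale="log2", condition=["tumour"] * 2)
        with pytest.raises(ValueError):
            spectral_stratify(m, k=3)


def hand_logrank_chi2(time, event, group):
    """Two-group log-rank chi-square from the textbook O-E formula."""
    time, event, group = map(np.asarray, (time, event, group))
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n, n1 = at_risk.sum(), (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_exchangeable_groups_null(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(100, 30)
        surv = make_survival(np.concatenate([t, t]), np.ones(60))
        labels = pd.Series([1] * 30 + [2] * 30, index=surv.sample_ids)
        res = logrank(labels, surv)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_six_patient_hand_example(self):
        time = [1, 2, 3, 4, 5, 6]
        event = [1] * 6
        group = [1, 2, 1, 2, 1, 2]
        surv = make_survival(time, event)
        labels = pd.Series(group, index=surv.sample_ids)
        res = logrank(labels, surv)
        expected = hand_logrank_chi2(time, event, group)
        assert res.chi2 == pytest.approx(expected, rel=1e-6)
        assert res.dof == 1

    def test_km_matches_product_limit_hand_example(self):
        # times 1,2,3,4,5; events 1,1,0,1,1 -> S = 4/5, 3/5, 3/5, 3/10, 0
        surv = make_survival([1, 2, 3, 4, 5, 10, 20], [1, 1, 0, 1, 1, 1, 1])
        labels = pd.Series([1, 1, 1, 1, 1, 2, 2], index=surv.sample_ids)
        res = logrank(labels, surv)
        km = res.km[1]
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[1.0] == pytest.approx(4 / 5)
        assert lookup[2.0] == pytest.approx(3 / 5)
        assert lookup[4.0] == pytest.approx(3 / 10)
        assert lookup[5.0] == pytest.approx(0.0)
        # curves start at 1 and never increase
        vals = km["survival"].to_numpy()
        assert np.all(np.diff(vals) <= 1e-12)

    def test_power_at_hazard_ratio_three(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            x = np.array([0] * 200 + [1] * 200)
            surv = exponential_cohort(rng, x, beta=np.log(3.0), horizon=1e9)
            labels = pd.Series(x + 1, index=surv.sample_ids)
            if logrank(labels, surv).p_value < 0.001:
                hits += 1
        assert hits == 5

    def test_single_group_rejected(self):
        surv = make_survival([1, 2], [1, 1])
        with pytest.raises(ValueError, match="2 non-empty"):
            logrank(pd.Series([1, 1], index=surv.sample_ids), surv)
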