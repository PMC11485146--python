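import numpy as np
import pandas as pd
import pytest

from conftest import exponential_cohort, make_survival
from cupronet.io import GeneSet
from cupronet.mutation import (DELETERIOUS_CLASSES, RevelCutpoints, filter_snvs,
                               mutant_status, mutation_survival, revel_category)


def call(**kw):
    base = dict(Hugo_Symbol="CASP3", Tumor_Sample_Barcode="p1",
                Variant_Classification="Missense_Mutation",
                t_alt_count=5, t_depth=40, FILTER="PASS", REVEL=0.95)
    base.update(kw)
    return base


def maf(rows):
    return pd.DataFrame(rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode",
                                       "Variant_Classification", "t_alt_count",
                                       "t_depth", "FILTER", "REVEL"])


class TestRevelCategory:
    @pytest.mark.parametrize("score, expected", [
        (0.95, "strong_pathogenic"),
        (0.932, "strong_pathogenic"),      # boundary closed on pathogenic side
        (0.80, "moderate_pathogenic"),
        (0.644, "supporting_pathogenic"),
        (0.50, "uncertain"),
        (0.290, "supporting_benign"),
        (0.10, "moderate_benign"),
        (0.016, "strong_benign"),
        (0.01, "strong_benign"),
    ])
    def test_default_bands(self, score, expected):
        assert revel_category(score) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            revel_category(1.2)
        with pytest.raises(ValueError):
            revel_category(float("nan"))

    def test_configurable_cutpoints(self):
        cuts = RevelCutpoints(supporting_pathogenic=0.4, moderate_pathogenic=0.6,
                              strong_pathogenic=0.9)
        assert revel_category(0.5, cuts) == "supporting_pathogenic"


class TestFilterSnvs:
    def test_compliant_call_kept(self):
        out = filter_snvs(maf([call()]))   # VAF 5/40 = 0.125 > 0.1
        assert len(out) == 1

    @pytest.mark.parametrize("violation", [
        dict(Variant_Classification="Silent"),
        dict(t_alt_count=3),                       # VAF 0.075 <= 0.1
        dict(FILTER="germline_risk"),
        dict(REVEL=0.5),                           # uncertain band
        dict(REVEL=np.nan),                        # missing annotation
    ])
    def test_single_rule_violations_rejected(self, violation):
        out = filter_snvs(maf([call(**violation)]))
        assert len(out) == 0

    def test_vaf_comparison_is_strict_and_exact(self):
        exactly_point_one = call(t_alt_count=4, t_depth=40)   # VAF = 0.1
        just_above = call(t_alt_count=41, t_depth=400)        # VAF = 0.1025
        out = filter_snvs(maf([exactly_point_one, just_above]))
        assert len(out) == 1 and out.iloc[0]["t_alt_count"] == 41

    def test_all_deleterious_classes_accepted(self):
        rows = [call(Variant_Classification=c) for c in sorted(DELETERIOUS_CLASSES)]
        assert len(filter_snvs(maf(rows))) == len(DELETERIOUS_CLASSES)

    def test_pure_filter_and_idempotent(self):
        rows = [call(), call(FILTER="fail"), call(t_alt_count=1)]
        df = maf(rows)
        once = filter_snvs(df)
        assert len(once) <= len(df)
        pd.testing.assert_frame_equal(filter_snvs(once), once)


class TestMutantStatus:
    def test_homozygous_deletion_is_mutant(self):
        cnv = pd.DataFrame([{"gene": "CASP3", "sample_id": "p1",
                             "cnv_class": "homo_del"}])
        st = mutant_status(maf([]), cnv, GeneSet("t", {"CASP3"}), samples=["p1", "p2"])
        assert st.pooled["p1"] == "mutant" and st.pooled["p2"] == "WT"

    def test_heterozygous_amplification_is_wt(self):
        cnv = pd.DataFrame([{"gene": "CASP3", "sample_id": "p1",
                             "cnv_class": "hete_amp"}])
        st = mutant_status(maf([]), cnv, GeneSet("t", {"CASP3"}), samples=["p1"])
        assert st.pooled["p1"] == "WT"

    def test_no_events_pooled_wt(self):
        st = mutant_status(maf([]), pd.DataFrame(columns=["gene", "sample_id",
                                                          "cnv_class"]),
                           GeneSet("t", {"CASP3"}), samples=["p1"])
        assert (st.pooled == "WT").all()

    def test_multiple_hits_count_once(self):
        snvs = filter_snvs(maf([call(), call()]))
        st = mutant_status(snvs, pd.DataFrame(columns=["gene", "sample_id",
                                                       "cnv_class"]),
                           GeneSet("t", {"CASP3"}), samples=["p1"])
        assert st.pooled["p1"] == "mutant"
        assert st.per_gene[("CASP3", "p1")] == "mutant"

    def test_gene_outside_tested_set_ignored(self):
        snvs = filter_snvs(maf([call(Hugo_Symbol="OTHER")]))
        st = mutant_status(snvs, pd.DataFrame(columns=["gene", "sample_id",
                                                       "cnv_class"]),
                           GeneSet("t", {"CASP3"}), samples=["p1"])
        assert st.pooled["p1"] == "WT"


class TestMutationSurvival:
    def _status(self, samples, mutants):
        snvs = maf([call(Tumor_Sample_Barcode=s) for s in mutants])
        return mutant_status(snvs, pd.DataFrame(columns=["gene", "sample_id",
                                                         "cnv_class"]),
                             GeneSet("t", {"CASP3"}), samples=samples)

    def test_all_wt_rejected(self):
        surv = make_survival([10, 20], [1, 1], samples=["p1", "p2"])
        with pytest.raises(ValueError, match="mutant"):
            mutation_survival(self._status(["p1", "p2"], []), surv)

    def test_planted_hazard_detected(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            x = np.array([0] * 300 + [1] * 300)   # 1 = mutant, HR 2
            surv = exponential_cohort(rng, x, beta=np.log(2.0))
            mutants = [s for s, xi in zip(surv.sample_ids, x) if xi == 1]
            st = self._status(surv.sample_ids, mutants)
            res = mutation_survival(st, surv)
            if res.p_value < 0.01:
                hits += 1
        assert hits >= 4

    def test_per_gene_results(self):
        rng = np.random.default_rng(1)
        surv = exponential_cohort(rng, np.zeros(40), beta=0.0)
        mutants = surv.sample_ids[:10]
        st = self._status(surv.sample_ids, mutants)
        pooled, per_gene = mutation_survival(st, surv, per_gene=True)
        assert "CASP3" in per_gene
        assert pooled.dof == 1
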