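"""Genomics module: consequence parsing, CN bands, double-hit calls,
exposure-association models."""

import numpy as np
import pandas as pd
import pytest

from pdxscreen import genomics, synthetic
from pdxscreen.exceptions import DegenerateOutcomeError, InvalidInputError


class TestParseProteinChange:
    @pytest.mark.parametrize(
        "text,term",
        [
            ("p.M695Nfs*26", "frameshift_variant"),
            ("p.K810*", "stop_gained"),
            ("p.X180_splice", "splice_variant"),
            ("p.H1047R", "missense_variant"),
            ("p.E545K", "missense_variant"),
            ("p.M1?", "start_lost"),
            ("", "unknown"),
            ("garbage", "unknown"),
            (None, "unknown"),
        ],
    )
    def test_printed_styles(self, text, term):
        assert genomics.parse_protein_change(text) == term

    def test_never_raises_on_junk(self):
        for junk in ("p.", "fs", "p.**", "12345", " "):
            assert isinstance(genomics.parse_protein_change(junk), str)


class TestConsequenceRuleSets:
    @pytest.mark.parametrize(
        "pc,deleterious",
        [("p.M695Nfs*26", True), ("p.K810*", True), ("p.X180_splice", True),
         ("p.H1047R", False)],
    )
    def test_deleterious_truncating(self, pc, deleterious):
        assert (
            genomics.classify_consequence(
                protein_change=pc, rule_set="deleterious_truncating"
            )
            == deleterious
        )
        # every deleterious variant is also coding
        if deleterious:
            assert genomics.classify_consequence(protein_change=pc)

    def test_missense_term_coding_not_deleterious(self):
        assert genomics.classify_consequence(consequence="missense variant")
        assert not genomics.classify_consequence(
            consequence="missense variant", rule_set="deleterious_truncating"
        )

    def test_vocabulary_containment(self):
        """The truncating subset is contained in the coding vocabulary."""
        assert genomics.DELETERIOUS_TRUNCATING_TERMS < genomics.HMF_CODING_TERMS

    def test_all_nine_coding_terms_qualify(self):
        for term in genomics.HMF_CODING_TERMS:
            assert genomics.classify_consequence(consequence=term)

    def test_unknown_term_never_qualifies(self):
        assert not genomics.classify_consequence(consequence="synonymous_variant")
        assert not genomics.classify_consequence(consequence=None)

    def test_unknown_rule_set(self):
        with pytest.raises(InvalidInputError):
            genomics.classify_consequence(consequence="stop_gained", rule_set="x")


def _cn_band_oracle(x):
    return "deep_del" if x < -1 else ("shallow_del" if x < -0.4 else "unaltered")


class TestCopyNumberBands:
    @pytest.mark.parametrize(
        "lr,band",
        [(-0.9, "shallow_del"), (-1.5, "deep_del"), (-2.0, "deep_del"),
         (0.0, "unaltered"), (-0.4, "unaltered"), (-0.41, "shallow_del"),
         (-1.0, "shallow_del"),
         (-4.2, "deep_del"), (2.0, "unaltered")],
    )
    def test_printed_bands(self, lr, band):
        assert genomics.classify_cn_logratio(lr) == band

    def test_grid_matches_oracle(self):
        for x in np.linspace(-5, 3, 3201):
            assert genomics.classify_cn_logratio(x) == _cn_band_oracle(x)

    @pytest.mark.parametrize(
        "minor,major,state",
        [(0.0, 0.0, "hom_del"), (0.0, 1.0, "het_del"), (1.0, 1.0, "unaltered"),
         (0.009, 0.009, "hom_del"), (0.009, 0.01, "het_del")],
    )
    def test_allele_cn(self, minor, major, state):
        assert genomics.classify_allele_cn(minor, major) == state

    def test_negative_allele_cn_rejected(self):
        with pytest.raises(InvalidInputError):
            genomics.classify_allele_cn(-0.1, 1.0)


class TestDoubleHit:
    @pytest.fixture
    def tables(self):
        variants = pd.DataFrame(
            [
                {"sample_id": "A", "gene": "RB1", "protein_change": "p.K810*"},
                {"sample_id": "C", "gene": "RB1", "protein_change": "p.H1047R"},
                {"sample_id": "D", "gene": "TP53", "protein_change": "p.R175H"},
            ]
        )
        cn = pd.DataFrame(
            [
                {"sample_id": "A", "gene": "RB1", "minor_cn": 0.0, "major_cn": 1.0},
                {"sample_id": "B", "gene": "RB1", "minor_cn": 0.0, "major_cn": 1.1},
                {"sample_id": "C", "gene": "RB1", "minor_cn": 1.0, "major_cn": 1.0},
                {"sample_id": "E", "gene": "RB1", "minor_cn": 0.0, "major_cn": 0.0},
            ]
        )
        return variants, cn

    def test_categories(self, tables):
        out = genomics.call_double_hit(*tables, gene="RB1").set_index("sample_id")
        assert out.loc["A", "category"] == "double_hit"
        assert out.loc["B", "category"] == "deletion_only"
        assert out.loc["C", "category"] == "mutation_only"
        assert out.loc["E", "category"] == "homozygous_deletion"
        assert "D" not in out.index  # other gene

    def test_order_independence_and_idempotence(self, tables):
        variants, cn = tables
        a = genomics.call_double_hit(variants, cn, "RB1")
        b = genomics.call_double_hit(
            variants.iloc[::-1].reset_index(drop=True),
            cn.sample(frac=1, random_state=0).reset_index(drop=True),
            "RB1",
        )
        pd.testing.assert_frame_equal(a, b)

    def test_allele_cn_precedence_over_logratio(self):
        cn = pd.DataFrame(
            [{"sample_id": "A", "gene": "RB1", "log_ratio": -2.0,
              "minor_cn": 0.0, "major_cn": 1.0}]
        )
        out = genomics.call_double_hit(pd.DataFrame(columns=["sample_id", "gene"]), cn, "RB1")
        assert out.iloc[0]["category"] == "deletion_only"  # het by allele CN

    def test_logratio_dialect(self):
        cn = pd.DataFrame(
            [{"sample_id": "A", "gene": "RB1", "log_ratio": -0.9},
             {"sample_id": "B", "gene": "RB1", "log_ratio": -1.5}]
        )
        out = genomics.call_double_hit(
            pd.DataFrame(columns=["sample_id", "gene"]), cn, "RB1"
        ).set_index("sample_id")
        assert out.loc["A", "category"] == "deletion_only"
        assert out.loc["B", "category"] == "homozygous_deletion"

    def test_any_qualifying_variant_sets_flag_once(self):
        variants = pd.DataFrame(
            [{"sample_id": "A", "gene": "RB1", "protein_change": "p.K810*"},
             {"sample_id": "A", "gene": "RB1", "protein_change": "p.M695Nfs*26"}]
        )
        cn = pd.DataFrame(
            [{"sample_id": "A", "gene": "RB1", "minor_cn": 0.0, "major_cn": 1.0}]
        )
        out = genomics.call_double_hit(variants, cn, "RB1")
        assert len(out) == 1 and out.iloc[0]["category"] == "double_hit"


class TestAssociationModels:
    def test_interaction_recovered_on_synthetic_cohort(self):
        g = synthetic.GenomicConfig(n_patients=4000, double_hit_log_or=1.2)
        cfg = synthetic.SyntheticConfig(seed=11, genomic=g)
        cohort, _, _ = synthetic.gen_genomic_cohort(cfg)
        fits = genomics.association_models(cohort)
        m1 = fits["M1"]
        est = m1.params["mutation_x_deletion"]
        lo, hi = m1.conf_int.loc["mutation_x_deletion"]
        assert lo <= 1.2 <= hi
        assert est == pytest.approx(1.2, abs=0.5)

    def test_m1_m2_agree_in_sign_without_marginal_effects(self):
        g = synthetic.GenomicConfig(n_patients=3000, double_hit_log_or=1.0)
        cfg = synthetic.SyntheticConfig(seed=3, genomic=g)
        cohort, _, _ = synthetic.gen_genomic_cohort(cfg)
        fits = genomics.association_models(cohort)
        s1 = np.sign(fits["M1"].params["mutation_x_deletion"])
        s2 = np.sign(fits["M2"].params["double_hit"])
        assert s1 == s2 == 1.0

    def test_all_unexposed_cohort_degenerate(self):
        cohort = pd.DataFrame(
            {"exposed": [0] * 20, "mutation": [0, 1] * 10, "deletion": [1, 0] * 10}
        )
        with pytest.raises(DegenerateOutcomeError):
            genomics.association_models(cohort)

    def test_missing_columns_rejected(self):
        with pytest.raises(InvalidInputError):
            genomics.association_models(pd.DataFrame({"exposed": [0, 1]}))

    def test_realized_tables_reproduce_cohort_flags(self, config):
        from dataclasses import replace

        cfg = synthetic.SyntheticConfig(
            seed=config.seed,
            genomic=replace(config.genomic, n_patients=400, double_hit_log_or=1.0),
        )
        cohort, variants, cn = synthetic.gen_genomic_cohort(cfg, realize_tables=True)
        calls = genomics.call_double_hit(variants, cn, cfg.genomic.gene)
        merged = cohort.merge(
            calls, left_on="patient_id", right_on="sample_id", how="left"
        )
        mut = merged["mutation_flag"].eq(True)
        det = merged["deletion_flag"].eq(True)
        assert (mut == merged["mutation"].astype(bool)).all()
        assert (det == merged["deletion"].astype(bool)).all()
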