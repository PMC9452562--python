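"""Biomarker module: Allred scoring, composite rule, Youden search,
concordance, KI67 rules, per-SD odds ratios."""

import numpy as np
import pandas as pd
import pytest

from pdxscreen import biomarkers
from pdxscreen.biomarkers import BiomarkerPanel, CutoffSet
from pdxscreen.exceptions import (
    DegenerateLabelsError,
    InvalidInputError,
    UnclassifiableError,
)


class TestAllred:
    @pytest.mark.parametrize(
        "pct,intensity,expected",
        [
            (0, 0, 0),
            (80, 3, 8),
            (20, 2, 5),  # bin 3 (11-33%) + 2
            (0.5, 1, 2),  # <1% bin
            (1, 1, 3),
            (10, 0, 2),
            (34, 1, 5),
            (66, 3, 7),
            (67, 0, 5),
        ],
    )
    def test_bin_table(self, pct, intensity, expected):
        assert biomarkers.allred_score(pct, intensity) == expected

    @pytest.mark.parametrize("pct,intensity", [(-1, 0), (101, 2), (50, 4)])
    def test_out_of_range(self, pct, intensity):
        with pytest.raises(InvalidInputError):
            biomarkers.allred_score(pct, intensity)


class TestCompositeRule:
    def test_p16_high_fires_despite_normal_prb(self):
        call = biomarkers.classify_composite(
            BiomarkerPanel("s", p16=4, prb=3, cyclin_e1=2, cyclin_d1=2,
                           intrinsic_subtype="LumB")
        )
        assert (call.predicted, call.fired_rule) == ("resistant", "p16_high")

    def test_no_rule_fires_sensitive(self):
        call = biomarkers.classify_composite(
            BiomarkerPanel("s", p16=0, prb=4, cyclin_e1=0, cyclin_d1=0,
                           intrinsic_subtype="LumB")
        )
        assert (call.predicted, call.fired_rule) == ("sensitive", "none")

    def test_cyclin_rule_order(self):
        call = biomarkers.classify_composite(
            BiomarkerPanel("s", p16=1, prb=3, cyclin_e1=6, cyclin_d1=2,
                           intrinsic_subtype="LumB")
        )
        assert (call.predicted, call.fired_rule) == ("resistant", "cyclin_high")

    def test_rule_precedence_subtype_first(self):
        call = biomarkers.classify_composite(
            BiomarkerPanel("s", p16=4, prb=0, cyclin_e1=8, cyclin_d1=8,
                           intrinsic_subtype="Basal")
        )
        assert call.fired_rule == "basal_subtype"

    @pytest.mark.parametrize(
        "e1,d1,resistant",
        [(4, 6, False), (5, 6, True), (4, 7, True), (5, 7, True)],
    )
    def test_cyclin_cutoffs_strict(self, e1, d1, resistant):
        call = biomarkers.classify_composite(
            BiomarkerPanel("s", p16=0, prb=4, cyclin_e1=e1, cyclin_d1=d1,
                           intrinsic_subtype="LumB")
        )
        assert (call.predicted == "resistant") == resistant

    def test_missing_score_cannot_fire(self):
        call = biomarkers.classify_composite(
            BiomarkerPanel("s", p16=None, prb=4, cyclin_e1=0, cyclin_d1=0,
                           intrinsic_subtype="LumB")
        )
        assert call.predicted == "sensitive"

    def test_all_inputs_missing_unclassifiable(self):
        with pytest.raises(UnclassifiableError):
            biomarkers.classify_composite(BiomarkerPanel("s"))

    def test_normal_like_subtype_does_not_fire_basal_rule(self):
        call = biomarkers.classify_composite(
            BiomarkerPanel("s", p16=0, prb=4, cyclin_e1=0, cyclin_d1=0,
                           intrinsic_subtype="Normal")
        )
        assert call.predicted == "sensitive"

    def test_cyclin_role_swap_with_matched_cutoffs(self, rng):
        """Swapping E1/D1 values together with their cutoffs leaves the
        binary call unchanged."""
        for _ in range(200):
            e1, d1 = int(rng.integers(0, 9)), int(rng.integers(0, 9))
            a = biomarkers.classify_composite(
                BiomarkerPanel("s", p16=0, prb=4, cyclin_e1=e1, cyclin_d1=d1,
                               intrinsic_subtype="LumB")
            )
            b = biomarkers.classify_composite(
                BiomarkerPanel("s", p16=0, prb=4, cyclin_e1=d1, cyclin_d1=e1,
                               intrinsic_subtype="LumB"),
                CutoffSet(e1_high_gt=6, d1_high_gt=4),
            )
            assert a.predicted == b.predicted

    def test_table_classification_matches_scalar(self):
        df = pd.DataFrame(
            [
                {"sample_id": "a", "p16": 4, "prb": 3, "cyclin_e1": 2,
                 "cyclin_d1": 2, "subtype": "LumB"},
                {"sample_id": "b", "p16": 0, "prb": 4, "cyclin_e1": 0,
                 "cyclin_d1": 0, "subtype": "LumB"},
            ]
        )
        out = biomarkers.classify_panel_table(df)
        assert list(out["predicted"]) == ["resistant", "sensitive"]


def _youden_oracle(scores, labels, direction, positive="resistant"):
    """Naive exhaustive enumeration with the documented tie rules."""
    s = np.asarray(scores, float)
    y = np.asarray([1 if l == positive else 0 for l in labels])
    best = None
    for t in sorted(set(s.tolist())):
        pred = s >= t if direction == "high_is_positive" else s <= t
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        key = (round(sens + spec - 1, 12), round(sens, 12), -t)
        if best is None or key > best[0]:
            best = (key, t, sens + spec - 1, sens, spec)
    return best[1], best[2], best[3], best[4]


class TestYouden:
    def test_perfect_separation_small_set(self):
        res = biomarkers.youden_cutoff(
            [1, 2, 3, 4], ["sensitive", "sensitive", "resistant", "resistant"]
        )
        assert res.threshold == 3
        assert res.j == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 51))
            scores = rng.integers(0, 9, n).astype(float)
            labels = np.where(rng.random(n) < 0.5, "resistant", "sensitive")
            if len(set(labels)) < 2:
                continue
            for direction in ("high_is_positive", "low_is_positive"):
                res = biomarkers.youden_cutoff(scores, labels, direction)
                t, j, sens, spec = _youden_oracle(scores, labels, direction)
                assert res.threshold == t
                assert res.j == pytest.approx(j)
                assert res.sensitivity == pytest.approx(sens)
                assert res.specificity == pytest.approx(spec)

    def test_independent_labels_give_near_zero_j(self, rng):
        n = 4000
        scores = rng.normal(size=n)
        labels = np.where(rng.random(n) < 0.5, "resistant", "sensitive")
        res = biomarkers.youden_cutoff(scores, labels)
        assert res.j < 0.1

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            biomarkers.youden_cutoff([1, 2], ["resistant", "resistant"])


class TestConcordance:
    def test_perfect_agreement(self):
        labels = ["resistant", "sensitive", "resistant"]
        rep = biomarkers.concordance(labels, labels)
        assert rep.sensitivity == rep.specificity == rep.accuracy == 1.0

    def test_two_by_two_arithmetic(self):
        pred = ["resistant"] * 13 + ["sensitive"] * 2 + ["resistant"] * 1 + ["sensitive"] * 7
        obs = ["resistant"] * 15 + ["sensitive"] * 8
        rep = biomarkers.concordance(pred, obs)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (13, 2, 1, 7)
        assert rep.sensitivity == pytest.approx(13 / 15)
        assert rep.accuracy == pytest.approx(20 / 23)
        assert rep.ppv == pytest.approx(13 / 14)
        assert rep.npv == pytest.approx(7 / 9)

    def test_all_predicted_positive(self):
        rep = biomarkers.concordance(
            ["resistant"] * 4, ["resistant", "resistant", "sensitive", "sensitive"]
        )
        assert (rep.sensitivity, rep.specificity) == (1.0, 0.0)

    def test_metrics_reproduce_from_counts(self, rng):
        pred = np.where(rng.random(40) < 0.6, "resistant", "sensitive")
        obs = np.where(rng.random(40) < 0.5, "resistant", "sensitive")
        rep = biomarkers.concordance(pred, obs)
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / rep.n)

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            biomarkers.concordance(["resistant"], ["resistant", "sensitive"])


class TestKi67Rules:
    @pytest.mark.parametrize("pct,cls", [(14.9, "LumA"), (15, "LumB"), (0, "LumA")])
    def test_luminal_split(self, pct, cls):
        assert biomarkers.ki67_luminal_split(pct) == cls

    def test_luminal_split_range(self):
        with pytest.raises(InvalidInputError):
            biomarkers.ki67_luminal_split(101)

    @pytest.mark.parametrize(
        "pct,cls",
        [(2.0, "sensitive"), (np.e, "resistant"), (20, "resistant"),
         (0.0, "sensitive")],
    )
    def test_ln_ki67_response(self, pct, cls):
        assert biomarkers.ki67_response(pct) == cls


class TestOrPerSd:
    def test_independent_marker_gives_or_near_one(self, rng):
        n = 3000
        x = rng.normal(100, 30, n)
        y = np.where(rng.random(n) < 0.5, "resistant", "sensitive")
        res = biomarkers.or_per_sd(x, y)
        assert res.ci_low < 1.0 < res.ci_high

    def test_recovers_generating_log_or(self, rng):
        """OR per SD generated at log-OR 0.8 is recovered within the CI in
        most replicates."""
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            n = 500
            z = rng.standard_normal(n)
            p = 1 / (1 + np.exp(-(-0.3 + 0.8 * z)))
            y = np.where(rng.random(n) < p, "resistant", "sensitive")
            res = biomarkers.or_per_sd(z, y)
            if res.separation:
                continue
            if res.ci_low <= np.exp(0.8) <= res.ci_high:
                hits += 1
        assert hits / n_rep >= 0.90

    def test_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = ["sensitive"] * 10 + ["resistant"] * 10
        res = biomarkers.or_per_sd(x, y)
        assert res.separation
        assert res.odds_ratio is None
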