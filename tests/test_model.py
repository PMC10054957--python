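"""The positive-only naive Bayes scorer: fitting, smoothing, scoring,
probabilities, ranking, and the white-box prediction report."""

import math

import numpy as np
import pytest

from pepnb.errors import DegenerateDataError
from pepnb.features import build_feature_set, PAIR_KEYS, select_pan_features, select_allele_features
from pepnb.model import (
    DEFAULT_PRIOR_ODDS,
    BackgroundModel,
    NBModel,
    fit,
)
from pepnb.peptides import AMINO_ACIDS, POSITION_LABELS, label_indices
from pepnb.simulate import anchor_generator, sample_allele


def background_equal_model(feature_set, prior_odds=DEFAULT_PRIOR_ODDS):
    """Model whose conditionals equal the background: log odds 0 everywhere."""
    bg = BackgroundModel.natural()
    conditionals = {}
    for key in feature_set.features:
        conditionals[key] = bg.freqs.copy() if isinstance(key, int) else bg.pair_freqs()
    return NBModel(allele="NULL", feature_set=feature_set, conditionals=conditionals,
                   background=bg, prior_odds=prior_odds)


def oracle_linear_log_odds(model, peptide):
    """Linear-space product of the 29 ratios, logged at the end."""
    idx = label_indices(len(peptide))
    prod = 1.0
    for key in model.feature_set.features:
        if isinstance(key, int):
            a = AMINO_ACIDS.index(peptide[idx[key]])
            prod *= model.conditionals[key][a] / model.background.freqs[a]
        else:
            a = AMINO_ACIDS.index(peptide[idx[key[0]]])
            b = AMINO_ACIDS.index(peptide[idx[key[1]]])
            prod *= model.conditionals[key][a, b] / (
                model.background.freqs[a] * model.background.freqs[b]
            )
    return math.log(prod)


class TestFit:
    def test_laplace_closed_form_on_repeated_peptide(self, any_feature_set):
        n = 17
        m = fit(["ACDEFGHIK"] * n, any_feature_set, alpha=1.0)
        tbl = m.conditionals[2]  # label 2 -> residue 'C'
        c = AMINO_ACIDS.index("C")
        assert tbl[c] == pytest.approx((n + 1) / (n + 20), abs=1e-12)
        assert tbl[(c + 1) % 20] == pytest.approx(1 / (n + 20), abs=1e-12)
        pair_tbl = m.conditionals[any_feature_set.pan_pairs[0]]
        assert pair_tbl.max() == pytest.approx((n + 1) / (n + 400), abs=1e-12)

    @pytest.mark.parametrize("smoothing", ["laplace", "blosum62"])
    def test_tables_are_proper_positive_distributions(self, smoothing, any_feature_set,
                                                      planted_pool):
        m = fit(planted_pool[:300], any_feature_set, smoothing=smoothing)
        for key, tbl in m.conditionals.items():
            assert tbl.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(tbl > 0)

    def test_blosum_differs_from_laplace(self, any_feature_set, planted_pool):
        ml = fit(planted_pool[:300], any_feature_set, smoothing="laplace")
        mb = fit(planted_pool[:300], any_feature_set, smoothing="blosum62")
        assert not np.allclose(ml.conditionals[2], mb.conditionals[2])

    def test_empty_training_set_rejected(self, any_feature_set):
        with pytest.raises(DegenerateDataError):
            fit([], any_feature_set)

    def test_single_position_pwm_recovery(self, any_feature_set):
        """Fitted single-feature conditionals recover the generator's
        per-label marginals within total variation 0.03 at n = 5000."""
        gen = anchor_generator("REC", seed=5)
        peps = sample_allele(gen, 5000, seed=6)
        m = fit(peps, any_feature_set, alpha=1.0)
        p8 = gen.length_probs[8]
        for lab in POSITION_LABELS:
            target = gen.pwm[lab]
            if lab == 7:  # 8-mers read their shared residue from the label-5 column
                target = p8 * gen.pwm[5] + (1 - p8) * gen.pwm[7]
            tv = 0.5 * np.abs(m.conditionals[lab] - target).sum()
            assert tv <= 0.03, f"label {lab}: TV {tv:.4f}"


class TestScoring:
    def test_background_equal_model_scores_zero(self, any_feature_set, tiny_peptides):
        m = background_equal_model(any_feature_set)
        for pep in tiny_peptides:
            assert m.log_odds(pep) == pytest.approx(0.0, abs=1e-9)

    def test_log_space_matches_linear_space_oracle(self, any_feature_set, planted_pool):
        m = fit(planted_pool[:400], any_feature_set)
        for pep in planted_pool[400:450]:
            assert m.log_odds(pep) == pytest.approx(
                oracle_linear_log_odds(m, pep), abs=1e-9
            )

    def test_additive_shift_of_one_feature(self, any_feature_set, tiny_peptides):
        m = fit(tiny_peptides, any_feature_set)
        before = m.score_many(tiny_peptides).copy()
        c = math.log(2.0)
        shifted = {k: v.copy() for k, v in m.conditionals.items()}
        shifted[3] = shifted[3] * 2.0  # unnormalized on purpose: adds ln 2 per peptide
        m2 = NBModel(allele=m.allele, feature_set=m.feature_set, conditionals=shifted,
                     background=m.background, prior_odds=m.prior_odds)
        after = m2.score_many(tiny_peptides)
        assert np.allclose(after - before, c, atol=1e-9)


class TestProbability:
    def test_neutral_evidence_default_prior_gives_1e_minus_5(self, any_feature_set):
        m = background_equal_model(any_feature_set, prior_odds=1e5 - 1)
        assert m.predict_proba("ACDEFGHIK") == 1e-5

    def test_unit_prior_neutral_evidence_gives_half(self, any_feature_set):
        m = background_equal_model(any_feature_set, prior_odds=1.0)
        assert m.predict_proba("ACDEFGHIK") == pytest.approx(0.5, abs=1e-12)

    def test_monotone_in_log_odds_and_prior(self, any_feature_set, planted_pool):
        m = fit(planted_pool[:300], any_feature_set)
        peps = planted_pool[300:340]
        scores = m.score_many(peps)
        probas = np.array([m.predict_proba(p) for p in peps])
        order = np.argsort(scores)
        assert np.all(np.diff(probas[order]) >= 0)
        for r1, r2 in [(1.0, 10.0), (10.0, 1e5 - 1)]:
            assert m.predict_proba(peps[0], prior_odds=r1) > m.predict_proba(
                peps[0], prior_odds=r2
            )

    def test_probability_strictly_inside_unit_interval(self, any_feature_set, planted_pool):
        m = fit(planted_pool[:300], any_feature_set)
        for pep in planted_pool[:50]:
            assert 0.0 < m.predict_proba(pep) < 1.0


class TestRanking:
    def test_prior_invariance_of_ordering(self, any_feature_set, planted_pool):
        m = fit(planted_pool[:500], any_feature_set)
        peps = planted_pool[500:1500]
        m.prior_odds = 1.0
        order_unit = [p for p, _ in m.rank_peptides(peps)]
        m.prior_odds = 1e5 - 1
        order_big = [p for p, _ in m.rank_peptides(peps)]
        assert order_unit == order_big
        # probability is a non-decreasing function of the log odds, so
        # ordering by probability can never contradict the score ordering
        probas = np.array([m.predict_proba(p) for p in peps])
        scores = m.score_many(peps)
        by_score = np.argsort(scores, kind="stable")
        assert np.all(np.diff(probas[by_score]) >= 0)

    def test_ties_preserve_input_order(self, any_feature_set):
        m = background_equal_model(any_feature_set)
        peps = ["ACDEFGHIK", "KIHGFEDCA", "AAAAAAAAA"]
        assert [p for p, _ in m.rank_peptides(peps)] == peps


class TestReport:
    def test_rows_sum_to_total(self, any_feature_set, planted_pool):
        m = fit(planted_pool[:300], any_feature_set)
        for pep in planted_pool[:20]:
            rep = m.prediction_report(pep)
            assert len(rep.rows) == 29
            assert sum(r.log_odds for r in rep.rows) == pytest.approx(
                rep.total_log_odds, abs=1e-9
            )
            assert rep.probability == pytest.approx(
                1 / (1 + rep.prior_odds * math.exp(-rep.total_log_odds)), abs=1e-12
            )

    def test_background_equal_model_reports_all_zero_rows(self, any_feature_set):
        rep = background_equal_model(any_feature_set).prediction_report("ACDEFGHIK")
        assert all(abs(r.log_odds) < 1e-9 for r in rep.rows)
        assert rep.probability == pytest.approx(1 / (1 + rep.prior_odds), rel=1e-12)

    def test_planted_anchors_dominate_matching_peptides(self):
        """On an anchor-dominated synthetic allele, the anchor position
        rows carry the largest positive evidence for a matching peptide."""
        gen = anchor_generator("ANCH", anchors={2: "L", 0: "V"}, anchor_weight=0.8, seed=9)
        peps = sample_allele(gen, 2000, seed=10)
        pan = select_pan_features(peps)
        fs = build_feature_set(pan, select_allele_features(peps, pan))
        m = fit(peps, fs)
        rep = m.prediction_report("ALAAAAAAV")  # L at P2, V at the C terminus
        single_rows = {r.feature: r.log_odds for r in rep.rows if isinstance(r.feature, int)}
        top_two = sorted(single_rows, key=single_rows.get, reverse=True)[:2]
        assert set(top_two) == {2, 0}
        assert min(single_rows[2], single_rows[0]) > 0


class TestDiscrimination:
    def test_auroc_above_095_on_synthetic_allele(self, toy_proteome, any_feature_set):
        """Training on 500 strong-two-anchor peptides separates binders
        from background decoys with AUROC > 0.95."""
        from pepnb.benchmark import auroc, generate_decoys

        gen = anchor_generator("DISC", anchor_weight=0.75, seed=21)
        train = sample_allele(gen, 500, seed=22)
        test = sample_allele(gen, 200, seed=23)
        m = fit(train, any_feature_set)
        decoys = generate_decoys(test, toy_proteome, ratio=10, seed=24)
        scores = np.r_[m.score_many(test), m.score_many(decoys)]
        labels = np.r_[np.ones(len(test)), np.zeros(len(decoys))]
        assert auroc(scores, labels) > 0.95
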