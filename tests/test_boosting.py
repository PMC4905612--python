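"""Multi-view AdaBoost, PWM scanning and the CCA interplay analysis."""

import numpy as np
import pandas as pd
import pytest

from periscan.boosting import (
    LabeledGene,
    build_view_features,
    canonical_correlations,
    extract_iteration_scores,
    load_model,
    predict_scores,
    pwm_score,
    save_model,
    train_multiview_boost,
)
from periscan.features import MotifMatrix, motif_variants


def _revcomp(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestPwmScore:
    def test_consensus_scores_column_sum(self, strong_motif):
        consensus = strong_motif.consensus()
        expected = float(strong_motif.log_odds.max(axis=1).sum())
        assert pwm_score(consensus, strong_motif) == pytest.approx(expected)

    def test_background_matrix_scores_zero(self):
        flat = MotifMatrix(np.full((6, 4), 0.25))
        assert pwm_score("ACGTACGTACGT", flat) == pytest.approx(0.0)

    def test_strand_symmetry(self, strong_motif):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 60))
        assert pwm_score(seq, strong_motif) == pytest.approx(
            pwm_score(_revcomp(seq), strong_motif)
        )

    def test_n_windows_skipped(self, strong_motif):
        w = strong_motif.width
        seq = "N" * w + strong_motif.consensus()
        full = pwm_score(strong_motif.consensus(), strong_motif)
        assert pwm_score(seq, strong_motif) == pytest.approx(full)

    def test_all_n_unscoreable(self, strong_motif):
        assert pwm_score("N" * 30, strong_motif) == -np.inf

    def test_short_sequence_rejected(self, strong_motif):
        with pytest.raises(ValueError):
            pwm_score("ACG", strong_motif)


def _toy_genes(strong_motif, n=10, seed=0):
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n):
        seq = "".join(rng.choice(list("ACGT"), 50))
        if i < n // 2:
            seq = strong_motif.consensus() + seq[strong_motif.width:]
        genes.append(LabeledGene(f"g{i}", int(rng.integers(1, 10**6)), seq,
                                 +1 if i < n // 2 else -1))
    return genes


class TestBuildViewFeatures:
    def test_shapes(self, strong_motif):
        genes = _toy_genes(strong_motif)
        seq, pos = build_view_features(genes, {"full": strong_motif}, [93_000.0])
        assert seq.shape == (10, 1) and pos.shape == (10, 1)

    def test_position_column_order_invariant(self, strong_motif):
        genes = _toy_genes(strong_motif)
        _, pos1 = build_view_features(genes, {"full": strong_motif}, [93_000.0])
        _, pos2 = build_view_features(genes[::-1], {"full": strong_motif}, [93_000.0])
        assert pos2.loc[pos1.index].to_numpy() == pytest.approx(pos1.to_numpy())

    def test_unscoreable_gene_excluded_with_warning(self, strong_motif):
        genes = _toy_genes(strong_motif)
        genes.append(LabeledGene("allN", 500, "N" * 50, -1))
        with pytest.warns(UserWarning, match="allN"):
            seq, pos = build_view_features(genes, {"full": strong_motif}, [93_000.0])
        assert "allN" not in seq.index


class TestTraining:
    def test_alpha_formula(self):
        # a stump with weighted error 0.1 receives alpha = 0.5*ln(9);
        # balanced classes make every initial weight 0.1, and the best stump
        # (x > 3.5) misclassifies exactly one gene (the negative at x=9)
        X = pd.DataFrame({"x": [0, 1, 2, 3, 9, 5, 6, 7, 8, 4.0]})
        y = np.array([-1, -1, -1, -1, -1, +1, +1, +1, +1, +1])
        model = train_multiview_boost({"position": X}, y, T=1)
        assert model.classifiers[0].error == pytest.approx(0.1)
        assert model.classifiers[0].alpha == pytest.approx(0.5 * np.log(9), abs=1e-9)

    def test_perfect_column_stops_after_one_round(self):
        X = pd.DataFrame({"x": [0.0, 1, 2, 10, 11, 12]})
        y = np.array([-1, -1, -1, 1, 1, 1])
        model = train_multiview_boost({"position": X}, y, T=10)
        assert len(model) == 1
        F = predict_scores(model, {"position": X})["F"]
        assert (np.sign(F) == y).all()

    def test_useless_features_stop_training(self):
        X = pd.DataFrame({"x": [1.0, 1, 1, 1]})
        y = np.array([1, -1, 1, -1])
        model = train_multiview_boost({"position": X}, y, T=5)
        assert len(model) == 0

    def test_single_class_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            train_multiview_boost({"position": X}, [1, 1], T=1)

    def test_weights_sum_to_one_each_iteration(self, strong_motif):
        genes = _toy_genes(strong_motif, n=20, seed=3)
        seq, pos = build_view_features(genes, motif_variants(strong_motif), [93_000.0])
        y = [g.label for g in genes]
        model = train_multiview_boost({"sequence": seq, "position": pos}, y, T=6)
        for w in model.weight_history:
            assert w.sum() == pytest.approx(1.0)

    def test_exponential_loss_non_increasing(self, strong_motif):
        from periscan.synthetic import generate_regulon_dataset
        genes, _ = generate_regulon_dataset(30, 30, strong_motif, implant_prob=0.7, seed=11)
        seq, pos = build_view_features(genes, motif_variants(strong_motif), [93_000.0])
        y = np.array([g.label for g in genes])
        model = train_multiview_boost({"sequence": seq, "position": pos}, y, T=12)
        # boosting minimises the class-weighted exponential loss, with the
        # balanced initial weights as the fixed per-gene weighting
        w0 = np.where(y == 1, 0.5 / (y == 1).sum(), 0.5 / (y == -1).sum())
        F = np.zeros(len(y))
        losses = [(w0 * np.exp(-y * F)).sum()]
        for c in model.classifiers:
            table = {"sequence": seq, "position": pos}[c.view]
            F = F + c.alpha * c.predict(table[c.column].to_numpy(float))
            losses.append((w0 * np.exp(-y * F)).sum())
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))


class TestPrediction:
    def test_empty_model_scores_zero(self):
        X = pd.DataFrame({"x": [1.0, 2.0]})
        model = train_multiview_boost({"position": X}, [1, -1], T=1)
        model.classifiers = []
        out = predict_scores(model, {"position": X})
        assert (out["F"] == 0).all()

    def test_partial_sums_decompose_total(self, strong_motif):
        genes = _toy_genes(strong_motif, n=16, seed=5)
        seq, pos = build_view_features(genes, motif_variants(strong_motif), [93_000.0])
        y = [g.label for g in genes]
        model = train_multiview_boost({"sequence": seq, "position": pos}, y, T=8)
        out = predict_scores(model, {"sequence": seq, "position": pos})
        assert out["F"].to_numpy() == pytest.approx(
            (out["F_sequence"] + out["F_position"]).to_numpy()
        )

    def test_missing_column_named(self):
        X = pd.DataFrame({"x": [0.0, 1, 2, 10, 11, 12]})
        y = [-1, -1, -1, 1, 1, 1]
        model = train_multiview_boost({"position": X}, y, T=1)
        with pytest.raises(KeyError, match="x"):
            predict_scores(model, {"position": pd.DataFrame({"other": [1.0] * 6})})

    def test_model_round_trip(self, tmp_path, strong_motif):
        genes = _toy_genes(strong_motif, n=12, seed=6)
        seq, pos = build_view_features(genes, motif_variants(strong_motif), [93_000.0])
        y = [g.label for g in genes]
        model = train_multiview_boost({"sequence": seq, "position": pos}, y, T=4)
        save_model(model, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        f1 = predict_scores(model, {"sequence": seq, "position": pos})["F"]
        f2 = predict_scores(back, {"sequence": seq, "position": pos})["F"]
        assert f2.to_numpy() == pytest.approx(f1.to_numpy())


class TestIterationScores:
    def test_blocks_split_by_view_with_alpha_entries(self, strong_motif):
        genes = _toy_genes(strong_motif, n=20, seed=7)
        seq, pos = build_view_features(genes, motif_variants(strong_motif), [93_000.0])
        y = [g.label for g in genes]
        model = train_multiview_boost({"sequence": seq, "position": pos}, y, T=8)
        X, Y = extract_iteration_scores(model, {"sequence": seq, "position": pos})
        assert X.shape[1] + Y.shape[1] == len(model)
        alphas = {c.iteration: c.alpha for c in model.classifiers}
        for df in (X, Y):
            for col in df.columns:
                t = int(col.split("_t")[1])
                assert set(np.round(np.abs(df[col]), 12)) <= {round(alphas[t], 12)}


class TestCCA:
    def test_perfect_negative_association(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        res = canonical_correlations(pd.DataFrame({"x": x}),
                                     pd.DataFrame({"y": -x}), ridge=0.0)
        assert res.correlations[0] == pytest.approx(1.0, abs=1e-9)
        assert np.sign(res.x_loadings.variate1.iloc[0]) != np.sign(
            res.y_loadings.variate1.iloc[0]
        )

    def test_independent_noise_low_correlation(self):
        firsts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 2))
            Y = rng.normal(size=(200, 2))
            firsts.append(canonical_correlations(X, Y, ridge=0.0).correlations[0])
        assert max(firsts) < 0.3

    def test_correlations_sorted_in_unit_interval(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        Y = X @ rng.normal(size=(3, 3)) + 0.5 * rng.normal(size=(40, 3))
        res = canonical_correlations(X, Y)
        c = res.correlations
        assert (np.diff(c) <= 1e-12).all()
        assert ((c >= 0) & (c <= 1)).all()

    def test_constant_column_named(self):
        X = pd.DataFrame({"flat": np.ones(10), "ok": np.arange(10.0)})
        Y = pd.DataFrame({"y": np.arange(10.0)})
        with pytest.raises(ValueError, match="flat"):
            canonical_correlations(X, Y)

    def test_needs_three_rows(self):
        with pytest.raises(ValueError):
            canonical_correlations(np.ones((2, 1)), np.ones((2, 1)))
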