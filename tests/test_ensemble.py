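"""LUPI ensemble training, voting and hyperparameter tuning."""

import numpy as np
import pytest

from kelmplus.ensemble import (EnsembleConfig, member_cv_accuracy, predict_ensemble,
                               train_ensemble, tune_hyperparameters)
from kelmplus.errors import InvalidInputError


class TestConfig:
    def test_default_pi_types_are_the_other_five(self):
        cfg = EnsembleConfig(main="Thickness")
        assert len(cfg.pi_types) == 5 and "Thickness" not in cfg.pi_types

    def test_main_cannot_be_pi(self):
        with pytest.raises(InvalidInputError):
            EnsembleConfig(main="GMV", pi_types=("GMV", "WMV"))


class TestTrainEnsemble:
    def test_default_config_yields_five_members(self, tiny_matrices, fast_config):
        matrices, _, y = tiny_matrices
        model = train_ensemble(matrices, y, fast_config)
        assert len(model.members) == 5
        assert {m.pi_type for m in model.members} == set(fast_config.pi_types)

    def test_any_feature_type_can_be_main(self, tiny_matrices):
        matrices, _, y = tiny_matrices
        cfg = EnsembleConfig(main="Network", C_grid=(1.0,), eps_grid=(1.0,),
                             gamma_scale_grid=(1.0,), k=10, seed=0)
        model = train_ensemble(matrices, y, cfg)
        assert model.config.main == "Network" and len(model.members) == 5

    def test_single_pi_degenerate_ensemble(self, tiny_matrices):
        matrices, _, y = tiny_matrices
        cfg = EnsembleConfig(main="GMV", pi_types=("WMV",), C_grid=(1.0,),
                             eps_grid=(1.0,), gamma_scale_grid=(1.0,), k=10, seed=0)
        model = train_ensemble(matrices, y, cfg)
        assert len(model.members) == 1

    def test_fewer_than_two_classes_rejected(self, tiny_matrices, fast_config):
        matrices, _, y = tiny_matrices
        with pytest.raises(InvalidInputError):
            train_ensemble(matrices, np.ones_like(y), fast_config)

    def test_missing_table_rejected(self, tiny_matrices, fast_config):
        matrices, _, y = tiny_matrices
        partial = {k: v for k, v in matrices.items() if k != "Area"}
        with pytest.raises(InvalidInputError, match="Area"):
            train_ensemble(partial, y, fast_config)


class TestPredictEnsemble:
    def test_majority_vote_and_purity(self, tiny_matrices, fast_config):
        """Prediction consumes only the main table and matches the member vote."""
        matrices, _, y = tiny_matrices
        model = train_ensemble(matrices, y, fast_config)
        labels, votes = predict_ensemble(model, matrices["GMV"], return_votes=True)
        assert votes.shape == (5, len(y))
        for i, lab in enumerate(labels):
            counts = {c: np.sum(votes[:, i] == c) for c in model.classes}
            assert counts[lab] == max(counts.values())

    def test_training_accuracy_high_on_separated_cohort(self, tiny_matrices, fast_config):
        matrices, _, y = tiny_matrices
        model = train_ensemble(matrices, y, fast_config)
        labels = predict_ensemble(model, matrices["GMV"])
        assert np.mean(labels == y) >= 0.9

    def test_tie_break_by_summed_scores_enumeration(self):
        """3-class tie (A,A,B,B,C): winner is argmax of summed scores over {A,B}."""
        from kelmplus.ensemble import majority_vote

        classes = ["A", "B", "C"]
        votes = np.array([["A"], ["A"], ["B"], ["B"], ["C"]], dtype=object)
        summed = sum([np.array([[5.0, 1.0, 0.0]]), np.array([[4.0, 1.0, 0.0]]),
                      np.array([[1.0, 3.0, 0.0]]), np.array([[1.0, 2.0, 0.0]]),
                      np.array([[0.0, 0.0, 9.0]])])
        # brute-force oracle: A and B tie at 2 votes; A's summed 11 beats B's 7
        assert majority_vote(votes, summed, classes)[0] == "A"
        # flip the summed scores and the tie resolves the other way
        assert majority_vote(votes, summed[:, [1, 0, 2]], classes)[0] == "B"

    def test_unanimous_and_majority_votes(self):
        from kelmplus.ensemble import majority_vote

        votes = np.array([["A", "A"], ["A", "A"], ["A", "B"], ["A", "B"], ["A", "B"]],
                         dtype=object)
        labels = majority_vote(votes, np.zeros((2, 2)), ["A", "B"])
        assert list(labels) == ["A", "B"]

    def test_five_member_binary_vote_never_ties(self, tiny_matrices, fast_config):
        matrices, _, y = tiny_matrices
        model = train_ensemble(matrices, y, fast_config)
        _, votes = predict_ensemble(model, matrices["GMV"], return_votes=True)
        for i in range(votes.shape[1]):
            counts = sorted(np.sum(votes[:, i] == c) for c in model.classes)
            assert counts[-1] != counts[-2]  # odd member count, two classes


class TestTuning:
    def test_singleton_grids_returned_unchanged(self, tiny_matrices):
        matrices, _, y = tiny_matrices
        cfg = EnsembleConfig(main="GMV", pi_types=("WMV",), C_grid=(2.0,),
                             eps_grid=(0.5,), gamma_scale_grid=(1.0,), k=10, seed=0)
        best = tune_hyperparameters(matrices, y, cfg)
        assert best == {"WMV": (2.0, 0.5, 1.0)}

    def test_chosen_triple_maximizes_inner_cv_by_rescan(self, tiny_matrices):
        """Exhaustive oracle: no grid point beats the tuner's choice."""
        matrices, _, y = tiny_matrices
        cfg = EnsembleConfig(main="GMV", pi_types=("WMV",), C_grid=(0.1, 1.0, 10.0),
                             eps_grid=(1.0,), gamma_scale_grid=(0.5, 2.0),
                             k=10, tuning_folds=3, seed=0)
        best = tune_hyperparameters(matrices, y, cfg)["WMV"]

        from kelmplus.ensemble import _selected, _spec_for
        from kelmplus.kernels import fit_ekm
        from kelmplus.selection import select_features

        sel_m = select_features(matrices["GMV"], y, cfg.alpha, cfg.k, seed=cfg.seed)
        Xm = _selected(matrices["GMV"], sel_m)
        ekm_m = fit_ekm(Xm, _spec_for(cfg.kernel, Xm), cfg.ekm_tol)
        sel_p = select_features(matrices["WMV"], y, cfg.alpha, cfg.k, seed=cfg.seed)
        Xp = _selected(matrices["WMV"], sel_p)
        ekm_p = fit_ekm(Xp, _spec_for(cfg.kernel, Xp), cfg.ekm_tol)
        Pm, Pp = ekm_m.transform(Xm), ekm_p.transform(Xp)
        classes = sorted(np.unique(y).tolist())

        def acc(C, eps, gs):
            return member_cv_accuracy(Pm, Pp, y, classes, C, eps, gs,
                                      kernel=cfg.kernel, n_folds=3, seed=cfg.seed,
                                      include_main_gram=cfg.include_main_gram)

        best_acc = acc(*best)
        for C in cfg.C_grid:
            for gs in cfg.gamma_scale_grid:
                assert best_acc >= acc(C, 1.0, gs) - 1e-12

    def test_hyperparams_override_bypasses_grids(self, tiny_matrices):
        matrices, _, y = tiny_matrices
        cfg = EnsembleConfig(main="GMV", pi_types=("WMV",), k=10, seed=0)
        model = train_ensemble(matrices, y, cfg,
                               hyperparams={"WMV": (3.0, 0.25, 1.0)})
        member = model.members[0]
        assert (member.C, member.eps, member.gamma_scale) == (3.0, 0.25, 1.0)
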