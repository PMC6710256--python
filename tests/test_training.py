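import numpy as np
import pytest

from sspred.encoding import EncodedSequence, augment_with_ss3, weighted_profile, clip
from sspred.io_formats import ProteinRecord
from sspred.model import (
    ModelConfig,
    count_parameters,
    init_params,
    loss_and_grads,
    predict_probs,
)
from sspred.training import (
    EnsembleMember,
    EnsembleSpec,
    TrainingConfig,
    TrainingDiverged,
    baseline_predict,
    ensemble_average,
    fit_baseline,
    incremental_deepen,
    make_cv_folds,
    predict_cascade,
    ss_to_indices,
    train,
    unfreeze,
)


def toy_ffnn(n_inputs=4, n_classes=3, hidden=(5,)):
    return ModelConfig(architecture="ffnn", n_inputs=n_inputs, n_classes=n_classes,
                       window=1, hidden=hidden)


def toy_data(rng, n=6, L=12, D=4, C=3):
    return [
        (rng.normal(size=(L, D)), rng.integers(0, C, L)) for _ in range(n)
    ]


class TestTrainMechanics:
    def test_same_seed_gives_bit_identical_history(self, rng):
        cfg = toy_ffnn()
        data = toy_data(rng)
        tc = TrainingConfig(max_epochs=5, seed=11)
        p1, h1 = train(cfg, tc, data)
        p2, h2 = train(cfg, tc, data)
        assert h1.losses == h2.losses
        assert h1.learning_rates == h2.learning_rates
        for k in p1.blocks:
            assert np.array_equal(p1.blocks[k], p2.blocks[k])

    def test_lr_halves_exactly_after_plateau(self, rng):
        """All blocks frozen -> the loss is constant; after the default 100
        non-improving epochs the learning rate is exactly halved."""
        cfg = toy_ffnn()
        data = toy_data(rng, n=2, L=5)
        params = init_params(cfg, np.random.default_rng(0))
        params.frozen = frozenset(params.blocks)
        tc = TrainingConfig(max_epochs=102, seed=1, initial_learning_rate=0.4)
        _, hist = train(cfg, tc, data, init=params)
        assert hist.learning_rates[100] == 0.4
        assert hist.learning_rates[101] == 0.2
        ratios = {
            round(b / a, 12)
            for a, b in zip(hist.learning_rates, hist.learning_rates[1:])
        }
        assert ratios <= {1.0, 0.5}

    def test_lr_never_increases(self, rng):
        cfg = toy_ffnn()
        data = toy_data(rng)
        _, hist = train(cfg, TrainingConfig(max_epochs=20, patience_epochs=3, seed=2), data)
        lrs = hist.learning_rates
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))

    def test_single_step_is_lr_times_gradient_without_momentum(self, rng):
        cfg = toy_ffnn()
        data = toy_data(rng, n=1, L=6)
        init = init_params(cfg, np.random.default_rng(3))
        lr = 0.1
        X, y = data[0]
        _, grads = loss_and_grads(init, cfg, X, y, scale=1.0 / len(y))
        tc = TrainingConfig(initial_learning_rate=lr, momentum=0.0, max_epochs=1, seed=3)
        out, _ = train(cfg, tc, data, init=init.copy())
        for k in init.blocks:
            assert np.allclose(out.blocks[k], init.blocks[k] - lr * grads[k], atol=1e-12)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(toy_ffnn(), TrainingConfig(max_epochs=1), [])

    def test_nan_loss_aborts_with_diagnostic(self, rng):
        cfg = toy_ffnn()
        data = toy_data(rng, n=2)
        bad = init_params(cfg, np.random.default_rng(0))
        bad.blocks["ffnn.out.W"][:] = np.nan
        with pytest.raises(TrainingDiverged):
            train(cfg, TrainingConfig(max_epochs=2, seed=0), data, init=bad)

    def test_training_reduces_loss_on_separable_data(self, rng):
        """A deterministic residue->class cipher is perfectly learnable: a
        window-1 FFNN reaches >=95% training accuracy."""
        from sspred.alphabet import map_8_to_3
        from sspred.encoding import onehot_encode
        from sspred.metrics import q_accuracy
        from sspred.synthetic import SyntheticConfig, generate_ss
        from sspred.training import indices_to_ss

        table = {"H": np.zeros(20), "E": np.zeros(20), "C": np.zeros(20)}
        table["H"][0] = 1.0  # A
        table["E"][1] = 1.0  # C
        table["C"][2] = 1.0  # D
        cfg_syn = SyntheticConfig(propensity_table=table)
        g = np.random.default_rng(4)
        data = []
        obs = []
        from sspred.synthetic import emit_sequence

        for i in range(12):
            ss8 = generate_ss(40, cfg_syn, g)
            seq = emit_sequence(ss8, table, g)
            rec = ProteinRecord(f"p{i}", seq, ss8)
            data.append(
                (onehot_encode(rec).rows, ss_to_indices(map_8_to_3(ss8), "ss3"))
            )
            obs.append(map_8_to_3(ss8))
        cfg = ModelConfig(architecture="ffnn", n_inputs=20, n_classes=3,
                          window=0, hidden=(8,))
        params, hist = train(
            cfg, TrainingConfig(initial_learning_rate=0.5, max_epochs=60, seed=5), data
        )
        pred = [
            indices_to_ss(np.argmax(predict_probs(params, X, cfg), axis=1))
            for X, _ in data
        ]
        q3, _ = q_accuracy(pred, obs)
        assert hist.losses[-1] < hist.losses[0]
        assert q3 >= 95.0

    def test_refinement_continues_from_donor(self, rng):
        """Training initialized from a converged model starts near the donor's
        loss, far below a cold start."""
        cfg = toy_ffnn()
        data = toy_data(np.random.default_rng(6), n=4, L=10)
        tc = TrainingConfig(initial_learning_rate=0.3, max_epochs=30, seed=6)
        donor, hist = train(cfg, tc, data)
        _, refined_hist = train(
            cfg, TrainingConfig(initial_learning_rate=0.05, max_epochs=3, seed=7),
            data, init=donor,
        )
        assert refined_hist.losses[0] < hist.losses[0]


class TestIncrementalDeepening:
    def test_frozen_blocks_bit_identical_after_training(self, rng):
        cfg = toy_ffnn(hidden=(6,))
        data = toy_data(rng, n=3)
        params, _ = train(cfg, TrainingConfig(max_epochs=3, seed=8), data)
        deeper, dcfg = incremental_deepen(params, cfg, 5, np.random.default_rng(9))
        trained, _ = train(dcfg, TrainingConfig(max_epochs=4, seed=10), data, init=deeper)
        for k in deeper.frozen:
            assert np.array_equal(trained.blocks[k], params.blocks[k])
        # lifting the freeze lets every block move
        lifted, _ = train(
            dcfg, TrainingConfig(max_epochs=2, seed=11), data, init=unfreeze(trained)
        )
        assert any(
            not np.array_equal(lifted.blocks[k], trained.blocks[k])
            for k in deeper.frozen
        )

    def test_parameter_count_delta(self):
        h_old, h_new, C = 6, 5, 3
        cfg = toy_ffnn(hidden=(h_old,))
        deeper_cfg = ModelConfig(
            architecture="ffnn", n_inputs=4, n_classes=3, window=1,
            hidden=(h_old, h_new),
        )
        delta = count_parameters(deeper_cfg) - count_parameters(cfg)
        assert delta == (h_old + 1) * h_new + (h_new + 1) * C - (h_old + 1) * C

    def test_applying_twice_gives_three_hidden_layers(self, rng):
        cfg = toy_ffnn(hidden=(6,))
        params = init_params(cfg, rng)
        p2, c2 = incremental_deepen(params, cfg, 5, rng)
        p3, c3 = incremental_deepen(p2, c2, 4, rng)
        assert c3.hidden == (6, 5, 4)
        p3.validate_against(c3)

    def test_rejected_for_cbrcnn(self, rng):
        cfg = ModelConfig(architecture="cbrcnn", n_inputs=4, n_classes=3,
                          nf=3, nb=3, nhf=4, nhb=4, nhy=5, cofb=1, cseg=1, cwin=1)
        params = init_params(cfg, rng)
        with pytest.raises(ValueError):
            incremental_deepen(params, cfg, 5, rng)


class TestFolds:
    def test_partition_properties(self):
        records = [f"r{i}" for i in range(10)]
        folds = make_cv_folds(records, k=5, seed=1)
        assert [len(f) for f in folds] == [2, 2, 2, 2, 2]
        flat = [r for f in folds for r in f]
        assert sorted(flat) == sorted(records)

    def test_sizes_differ_by_at_most_one(self):
        folds = make_cv_folds(list(range(13)), k=5, seed=2)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_reproducible_from_seed(self):
        a = make_cv_folds(list(range(20)), k=5, seed=3)
        b = make_cv_folds(list(range(20)), k=5, seed=3)
        assert a == b


class TestEnsemble:
    def test_average_properties(self, rng):
        a = rng.dirichlet(np.ones(3), size=8)
        b = rng.dirichlet(np.ones(3), size=8)
        avg = ensemble_average([a, b])
        assert np.allclose(avg, (a + b) / 2)
        assert np.allclose(avg.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(ensemble_average([a, a]), a)
        one = np.tile([1.0, 0, 0], (2, 1))
        two = np.tile([0, 1.0, 0], (2, 1))
        assert np.allclose(ensemble_average([one, two]), np.tile([0.5, 0.5, 0], (2, 1)))


class TestEnsembleAccuracy:
    def test_ensemble_at_least_as_good_as_worst_member(self):
        """Held-out Q3 of the softmax average is >= the worst member's
        (a regression property of this fixture, not a theorem)."""
        from sspred.alphabet import map_8_to_3
        from sspred.encoding import clip, weighted_profile
        from sspred.metrics import q_accuracy
        from sspred.synthetic import SyntheticConfig, generate_dataset
        from sspred.training import indices_to_ss

        data = generate_dataset(SyntheticConfig(n_proteins=24, length_range=(40, 60), seed=2))
        profiles = [
            clip(weighted_profile(a), r).rows
            for a, r in zip(data.alignments_a, data.records)
        ]
        labels = [ss_to_indices(map_8_to_3(r.ss8)) for r in data.records]
        tr, te = list(range(18)), list(range(18, 24))
        cfg = ModelConfig(architecture="cbrcnn", n_inputs=22, n_classes=3,
                          nf=5, nb=5, nhf=8, nhb=8, nhy=10, cofb=2, cseg=3, cwin=5)
        pairs = [(profiles[i], labels[i]) for i in tr]
        members = [
            train(cfg, TrainingConfig(initial_learning_rate=0.03, max_epochs=15, seed=s), pairs)[0]
            for s in (0, 1, 2)
        ]
        obs = [map_8_to_3(data.records[i].ss8) for i in te]
        member_q3 = []
        outputs = {i: [] for i in te}
        for m in members:
            preds = []
            for i in te:
                p = predict_probs(m, profiles[i], cfg)
                outputs[i].append(p)
                preds.append(indices_to_ss(np.argmax(p, axis=1)))
            member_q3.append(q_accuracy(preds, obs)[0])
        ens_preds = [
            indices_to_ss(np.argmax(ensemble_average(outputs[i]), axis=1)) for i in te
        ]
        ens_q3, _ = q_accuracy(ens_preds, obs)
        assert ens_q3 >= min(member_q3)


def _trained_member(cfg, source, data, seed):
    params, _ = train(cfg, TrainingConfig(max_epochs=2, seed=seed), data)
    return EnsembleMember(params=params, config=cfg, source=source)


class TestCascade:
    @pytest.fixture
    def setup(self, rng):
        from sspred.synthetic import SyntheticConfig, generate_dataset

        cfg_syn = SyntheticConfig(n_proteins=4, length_range=(20, 30), seed=3)
        data = generate_dataset(cfg_syn)
        rec = data.records[0]
        prof_a = clip(weighted_profile(data.alignments_a[0]), rec)
        prof_b = clip(weighted_profile(data.alignments_b[0]), rec)
        from sspred.encoding import concat_profiles

        profiles = {"a": prof_a, "b": prof_b, "concat": concat_profiles(prof_a, prof_b)}
        return data, rec, profiles

    def _mini_cbrcnn(self, d, c):
        return ModelConfig(architecture="cbrcnn", n_inputs=d, n_classes=c,
                           nf=3, nb=3, nhf=4, nhb=4, nhy=5, cofb=1, cseg=3, cwin=3)

    def _training_pairs(self, data, width_from, level):
        from sspred.alphabet import map_8_to_3

        pairs = []
        for i, rec in enumerate(data.records):
            enc = width_from(i, rec)
            labels = map_8_to_3(rec.ss8) if level == "ss3" else rec.ss8
            pairs.append((enc, ss_to_indices(labels, level)))
        return pairs

    def test_full_seven_plus_seven_composition(self, setup):
        data, rec, profiles = setup

        def enc3(src):
            def f(i, r):
                if src == "a":
                    return clip(weighted_profile(data.alignments_a[i]), r).rows
                if src == "b":
                    return clip(weighted_profile(data.alignments_b[i]), r).rows
                from sspred.encoding import concat_profiles

                return concat_profiles(
                    clip(weighted_profile(data.alignments_a[i]), r),
                    clip(weighted_profile(data.alignments_b[i]), r),
                ).rows
            return f

        members3 = []
        seeds = iter(range(100))
        for src, d in (("a", 22), ("b", 22), ("concat", 44)):
            n = 1 if src == "concat" else 3
            pairs = self._training_pairs(data, enc3(src), "ss3")
            for _ in range(n):
                members3.append(
                    _trained_member(self._mini_cbrcnn(d, 3), src, pairs, next(seeds))
                )
        ens3 = EnsembleSpec(members=members3)
        assert len(ens3.members) == 7  # 3 + 3 + 1

        members8 = []
        for src, d in (("a", 25), ("b", 25), ("concat", 47)):
            n = 1 if src == "concat" else 3
            # train 8-state members on profile + final 3-state ensemble output
            def enc8(i, r, _src=src):
                base = enc3(_src)(i, r)
                from sspred.encoding import EncodedSequence

                enc = EncodedSequence(base, "weighted" if base.shape[1] == 22 else "concat")
                res = predict_cascade(
                    r,
                    {
                        "a": clip(weighted_profile(data.alignments_a[i]), r),
                        "b": clip(weighted_profile(data.alignments_b[i]), r),
                        "concat": profiles["concat"].__class__(
                            np.hstack(
                                [
                                    clip(weighted_profile(data.alignments_a[i]), r).rows,
                                    clip(weighted_profile(data.alignments_b[i]), r).rows,
                                ]
                            ),
                            "concat",
                        ),
                    },
                    ens3,
                )
                return augment_with_ss3(enc, res.p3).rows

            pairs = self._training_pairs(data, enc8, "ss8")
            for _ in range(n):
                members8.append(
                    _trained_member(self._mini_cbrcnn(d, 8), src, pairs, next(seeds))
                )
        ens8 = EnsembleSpec(members=members8)
        assert len(ens8.members) == 7

        res = predict_cascade(rec, profiles, ens3, ens8)
        assert res.p3.shape == (len(rec), 3)
        assert res.p8.shape == (len(rec), 8)
        assert np.allclose(res.p3.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(res.p8.sum(axis=1), 1.0, atol=1e-9)
        assert set(res.ss3) <= set("HEC") and set(res.ss8) <= set("HGIEBTSC")
        # 22-wide 8-state members consumed exactly 25 inputs
        assert members8[0].config.n_inputs == 25
        assert members8[-1].config.n_inputs == 47

    def test_single_member_reduces_to_augmented_prediction(self, setup):
        data, rec, profiles = setup
        from sspred.alphabet import map_8_to_3

        pairs3 = [
            (clip(weighted_profile(data.alignments_a[i]), r).rows,
             ss_to_indices(map_8_to_3(r.ss8), "ss3"))
            for i, r in enumerate(data.records)
        ]
        m3 = _trained_member(self._mini_cbrcnn(22, 3), "a", pairs3, 0)
        ens3 = EnsembleSpec(members=[m3])
        p3 = predict_probs(m3.params, profiles["a"], m3.config)
        pairs8 = [
            (augment_with_ss3(
                clip(weighted_profile(data.alignments_a[i]), r),
                predict_probs(m3.params,
                              clip(weighted_profile(data.alignments_a[i]), r),
                              m3.config),
            ).rows, ss_to_indices(r.ss8, "ss8"))
            for i, r in enumerate(data.records)
        ]
        m8 = _trained_member(self._mini_cbrcnn(25, 8), "a", pairs8, 1)
        res = predict_cascade(rec, profiles, ens3, EnsembleSpec(members=[m8]))
        direct8 = predict_probs(
            m8.params, augment_with_ss3(profiles["a"], p3), m8.config
        )
        assert np.allclose(res.p3, p3)
        assert np.allclose(res.p8, direct8)

    def test_missing_profile_scheme_is_configuration_error(self, setup, rng):
        data, rec, profiles = setup
        m = EnsembleMember(
            params=init_params(self._mini_cbrcnn(22, 3), rng),
            config=self._mini_cbrcnn(22, 3),
            source="b",
        )
        with pytest.raises(ValueError, match="source 'b'"):
            predict_cascade(rec, {"a": profiles["a"]}, EnsembleSpec(members=[m]))


class TestBaselines:
    def test_global_majority_accuracy_equals_majority_fraction(self):
        recs = [ProteinRecord("p", "A" * 10, ss8="C" * 5 + "H" * 3 + "E" * 2)]
        ref = fit_baseline(recs)
        assert ref.global_majority == "C"
        from sspred.alphabet import map_8_to_3
        from sspred.metrics import q_accuracy

        pred = baseline_predict(recs, "global_majority", ref)
        q, _ = q_accuracy(pred, [map_8_to_3(r.ss8) for r in recs])
        assert q == pytest.approx(50.0)

    def test_per_residue_refines_global_on_reference_set(self, rng):
        from sspred.alphabet import map_8_to_3
        from sspred.metrics import q_accuracy
        from sspred.synthetic import SyntheticConfig, generate_dataset

        data = generate_dataset(SyntheticConfig(n_proteins=20, seed=9))
        ref = fit_baseline(data.records)
        obs = [map_8_to_3(r.ss8) for r in data.records]
        q_global, _ = q_accuracy(
            baseline_predict(data.records, "global_majority", ref), obs
        )
        q_aa, _ = q_accuracy(
            baseline_predict(data.records, "per_residue_majority", ref), obs
        )
        assert q_aa >= q_global
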