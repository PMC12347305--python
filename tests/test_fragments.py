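import numpy as np
import pytest

from torsionfold.errors import DomainError
from torsionfold.fragments import (ALPHA_CENTER, BETA_CENTER, CNNPredictor,
                                   LookupPredictor, Fragment, PredictorConfig,
                                   assemble_initial_state,
                                   fit_fragment_predictor,
                                   generate_synthetic_library, one_hot_encode,
                                   predict_torsions, split_windows)
from torsionfold.geometry import count_variables
from torsionfold.nn import TinyConvNet


class TestSplitWindows:
    @pytest.mark.parametrize("length,n_windows,remainder", [
        (32, 5, 2),   # 32-mer worked example: five fragments + 2 leftover
        (12, 2, 0),
        (5, 0, 5),
        (6, 1, 0),
    ])
    def test_window_arithmetic(self, length, n_windows, remainder):
        seq = "A" * length
        windows, rem = split_windows(seq)
        assert len(windows) == n_windows
        assert rem == remainder
        assert all(len(w) == 6 for w in windows)
        # windows tile the prefix exactly once, left-anchored
        assert "".join(windows) == seq[:length - remainder]


class TestSyntheticLibrary:
    def test_class_counts_conserved(self, small_library):
        assert small_library.counts == {"alpha": 10, "beta": 5, "loop": 2}

    def test_seeded_determinism(self):
        a = generate_synthetic_library(5, 5, 5, 3.0, seed=11)
        b = generate_synthetic_library(5, 5, 5, 3.0, seed=11)
        assert a == b

    def test_zero_noise_pins_alpha_phi(self):
        lib = generate_synthetic_library(4, 0, 1, noise_deg=0.0, seed=1)
        for fr in lib.fragments:
            if fr.ss_label == "alpha":
                assert all(p == ALPHA_CENTER[0] for p in fr.phi)
                assert all(p == ALPHA_CENTER[1] for p in fr.psi)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(DomainError):
            generate_synthetic_library(0, 0, 0, 5.0, seed=1)

    def test_class_means_recover_centers(self):
        """Parameter recovery: class means within 3 standard errors at n=500."""
        lib = generate_synthetic_library(500, 500, 0, noise_deg=5.0, seed=3)
        for label, center in (("alpha", ALPHA_CENTER), ("beta", BETA_CENTER)):
            phis = np.concatenate([fr.phi for fr in lib.fragments
                                   if fr.ss_label == label])
            se = 5.0 / np.sqrt(len(phis))
            assert abs(phis.mean() - center[0]) < 3 * se


class TestLookupPredictor:
    def test_exact_match_returns_library_angles(self, small_library):
        pred = LookupPredictor(small_library)
        fr = small_library.fragments[3]
        np.testing.assert_array_equal(pred.predict(fr.sequence), fr.angles())

    def test_nearest_match_agrees_with_brute_force(self, small_library, rng):
        pred = LookupPredictor(small_library)
        for _ in range(20):
            window = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 6))
            got = pred.predict(window)
            # independent brute-force scan, first-best wins
            best, best_score = None, -1
            for fr in small_library.fragments:
                score = sum(a == b for a, b in zip(fr.sequence, window))
                if score > best_score:
                    best, best_score = fr, score
            np.testing.assert_array_equal(got, best.angles())

    def test_empty_library_rejected(self):
        from torsionfold.fragments import FragmentLibrary
        with pytest.raises(DomainError):
            LookupPredictor(FragmentLibrary([]))


class TestCnnPredictor:
    def test_output_has_18_values_in_range(self, small_library):
        cfg = PredictorConfig(backend="cnn", epochs=2, seed=0)
        pred = fit_fragment_predictor(small_library, cfg)
        out = pred.predict("ACDEFG")
        assert out.shape == (18,)
        assert np.all(out >= -180.0) and np.all(out < 180.0)

    def test_short_training_beats_untrained(self):
        lib = generate_synthetic_library(100, 80, 20, noise_deg=0.0, seed=5)
        x = np.stack([one_hot_encode(fr.sequence) for fr in lib.fragments])
        y = np.stack([fr.angles() for fr in lib.fragments]) / 180.0
        untrained = TinyConvNet(seed=0).mse(x, y)
        pred = fit_fragment_predictor(lib, PredictorConfig(epochs=5, seed=0))
        assert pred.validation_mse < untrained

    def test_gradients_match_finite_differences(self):
        # fixed draw keeps the finite-difference probe away from ReLU /
        # max-pool kinks, where one-sided derivatives differ legitimately
        rng = np.random.default_rng(0)
        net = TinyConvNet(conv_channels=4, dense=(8, 9), dropout=0.0, seed=1)
        x = rng.random((3, 6, 20))
        y = rng.random((3, 18))
        out, cache = net.forward(x)
        grads = net._backward(cache, 2 * (out - y) / out.size)
        for key in ("Wc0", "Wc3", "Wd0", "Wd2", "bc1", "bd1"):
            p = net.params[key]
            idx = tuple(0 for _ in p.shape)
            eps = 1e-6
            p[idx] += eps
            up = float(np.mean((net.predict(x) - y) ** 2))
            p[idx] -= 2 * eps
            down = float(np.mean((net.predict(x) - y) ** 2))
            p[idx] += eps
            assert (up - down) / (2 * eps) == pytest.approx(grads[key][idx], abs=1e-7)

    def test_save_load_round_trip(self, small_library, tmp_path):
        pred = fit_fragment_predictor(small_library,
                                      PredictorConfig(epochs=1, seed=0))
        path = tmp_path / "weights.npz"
        pred.save(path)
        loaded = CNNPredictor.load(path)
        np.testing.assert_array_equal(pred.predict("GGGGGG"),
                                      loaded.predict("GGGGGG"))

    def test_too_small_library_rejected(self):
        lib = generate_synthetic_library(3, 3, 3, 5.0, seed=1)
        with pytest.raises(DomainError):
            fit_fragment_predictor(lib, PredictorConfig(backend="cnn"))


class TestPredictTorsions:
    def test_wrong_window_length_rejected(self, small_library):
        pred = LookupPredictor(small_library)
        with pytest.raises(DomainError):
            predict_torsions(pred, "ACDEF")

    def test_outputs_wrapped(self, small_library):
        pred = LookupPredictor(small_library)
        phi, psi, omega = predict_torsions(pred, "ACDEFG")
        for arr in (phi, psi, omega):
            assert np.all(arr >= -180.0) and np.all(arr < 180.0)


class TestAssembly:
    def test_windowed_residues_predicted_remainder_random(self, rng):
        # 32-mer: residues 1..30 take window predictions, 31..32 are random
        lib = generate_synthetic_library(20, 0, 0, noise_deg=0.0, seed=2)
        pred = LookupPredictor(lib)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 32))
        state = assemble_initial_state(seq, pred, rng_seed=9)
        assert np.all(state.phi[:30] == ALPHA_CENTER[0])  # noiseless all-alpha library
        assert not np.any(state.phi[30:] == ALPHA_CENTER[0])

    def test_exact_window_retrieval_property(self):
        lib = generate_synthetic_library(3, 3, 3, noise_deg=4.0, seed=8)
        pred = LookupPredictor(lib)
        target = lib.fragments[0].sequence + lib.fragments[5].sequence
        state = assemble_initial_state(target, pred, rng_seed=1)
        np.testing.assert_allclose(state.phi[:6], lib.fragments[0].phi)
        np.testing.assert_allclose(state.psi[6:], lib.fragments[5].psi)

    def test_flattened_length_matches_variable_count(self, small_library):
        pred = LookupPredictor(small_library)
        state = assemble_initial_state("ACDEFGHIKLMNP", pred, rng_seed=0)
        assert len(state.flatten()) == count_variables("ACDEFGHIKLMNP")

    def test_seeded_determinism(self, small_library):
        pred = LookupPredictor(small_library)
        a = assemble_initial_state("ACDEFGHK", pred, rng_seed=4)
        b = assemble_initial_state("ACDEFGHK", pred, rng_seed=4)
        assert np.array_equal(a.flatten(), b.flatten())


def test_fragment_validation():
    with pytest.raises(DomainError):
        Fragment("ACDEF", (0,) * 6, (0,) * 6, (0,) * 6, "alpha")   # 5 residues
    with pytest.raises(DomainError):
        Fragment("ACDEFG", (0,) * 5, (0,) * 6, (0,) * 6, "alpha")  # 17 angles
    with pytest.raises(DomainError):
        Fragment("ACDEFG", (0,) * 6, (0,) * 6, (0,) * 6, "helix")  # bad label
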