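"""Three-state HMM: transitions, emissions, decoding, window calling."""

import numpy as np
import pytest

from poolsweep.afs import neutral_start_spectrum
from poolsweep.hmm import (
    DecodedPath,
    build_hmm,
    call_sweep_windows,
    decode,
    emission_matrix,
    forward_backward,
    state_emission,
    viterbi,
)
from poolsweep.likelihood import LikelihoodVector
from poolsweep.simulate import SimConfig, simulate_pileup
from poolsweep.spectrum import Spectrum
from poolsweep.sweep import build_state_spectra

from conftest import enumerate_hmm, vectors_from_lines


def toy_spectra(n=2):
    neutral = neutral_start_spectrum(n, 0.02)
    return build_state_spectra(neutral, 0.1, 0.6)


def random_emissions(rng, length):
    return rng.normal(loc=-1.0, scale=2.0, size=(length, 3))


class TestBuildHmm:
    def test_rows_stochastic_and_linear_chain(self):
        model = build_hmm(toy_spectra(), 0.01)
        np.testing.assert_allclose(model.transition.sum(axis=1), 1.0)
        assert model.transition[0, 2] == 0.0 and model.transition[2, 0] == 0.0

    def test_initial_is_stationary_uniform(self):
        model = build_hmm(toy_spectra(), 0.2)
        np.testing.assert_allclose(model.initial, 1 / 3)
        np.testing.assert_allclose(model.initial @ model.transition, model.initial)

    def test_tiny_q_off_diagonals(self):
        model = build_hmm(toy_spectra(), 1e-10)
        assert model.transition[0, 1] == pytest.approx(1e-10)

    @pytest.mark.parametrize("q", [0.0, 0.5, -0.1, 1.0])
    def test_q_range_enforced(self, q):
        with pytest.raises(ValueError):
            build_hmm(toy_spectra(), q)


class TestEmission:
    def test_uninformative_site_emits_zero_everywhere(self):
        lik = LikelihoodVector("c", 1, 2, np.zeros(3), "A", "T")
        for spec in toy_spectra():
            assert state_emission(lik, spec) == pytest.approx(0.0)

    def test_point_mass_spectrum_selects_one_class(self):
        lik = LikelihoodVector("c", 1, 2, np.log([0.2, 0.4, 0.9]), "A", "T")
        spec = Spectrum([0.0, 0.0, 1.0], 2)
        assert state_emission(lik, spec) == pytest.approx(np.log(0.9))

    def test_dot_product_example(self):
        lik = LikelihoodVector("c", 1, 2, np.log([0.2, 0.4, 0.9]), "A", "T")
        spec = Spectrum([0.5, 0.5, 0.0], 2)
        assert state_emission(lik, spec) == pytest.approx(np.log(0.3))


class TestDecodingOracles:
    def test_uninformative_emissions_give_constant_neutral_path(self):
        model = build_hmm(toy_spectra(), 0.1)
        positions = np.arange(1, 7)
        path = viterbi(model, positions, np.zeros((6, 3)))
        np.testing.assert_array_equal(path, 0)

    def test_viterbi_matches_exhaustive_paths(self):
        model = build_hmm(toy_spectra(), 0.08)
        rng = np.random.default_rng(2)
        for _ in range(15):
            L = rng.integers(2, 6)
            positions = np.cumsum(rng.integers(1, 5, size=L))
            em = random_emissions(rng, L)
            best, _, _ = enumerate_hmm(model, positions, em)
            np.testing.assert_array_equal(viterbi(model, positions, em), best)

    def test_forward_backward_matches_exhaustive_paths(self):
        model = build_hmm(toy_spectra(), 0.08)
        rng = np.random.default_rng(3)
        for _ in range(10):
            L = rng.integers(2, 6)
            positions = np.cumsum(rng.integers(1, 4, size=L))
            em = random_emissions(rng, L)
            _, post_oracle, ll_oracle = enumerate_hmm(model, positions, em)
            post, ll_f, ll_b = forward_backward(model, positions, em)
            np.testing.assert_allclose(post, post_oracle, atol=1e-9)
            assert ll_f == pytest.approx(ll_oracle, rel=1e-9)

    def test_posteriors_normalize_and_totals_agree(self):
        model = build_hmm(toy_spectra(), 0.01)
        rng = np.random.default_rng(4)
        positions = np.cumsum(rng.integers(1, 50, size=200))
        em = random_emissions(rng, 200)
        post, ll_f, ll_b = forward_backward(model, positions, em)
        np.testing.assert_allclose(np.exp(post).sum(axis=1), 1.0, atol=1e-9)
        assert abs(ll_f - ll_b) <= 1e-8 * abs(ll_f)

    def test_unsorted_positions_rejected(self):
        model = build_hmm(toy_spectra(), 0.01)
        with pytest.raises(ValueError, match="increasing"):
            viterbi(model, np.array([5, 3]), np.zeros((2, 3)))


class TestGapHandling:
    def test_power_laws(self):
        model = build_hmm(toy_spectra(), 0.03)
        t = model.transition
        np.testing.assert_allclose(np.linalg.matrix_power(t, 1), t)
        np.testing.assert_allclose(
            np.linalg.matrix_power(t, 7) @ np.linalg.matrix_power(t, 5),
            np.linalg.matrix_power(t, 12),
            atol=1e-12,
        )

    def test_wide_gap_forgets_state(self):
        """A huge uncovered gap returns the chain to its stationary mix."""
        model = build_hmm(toy_spectra(), 0.01)
        em = np.zeros((2, 3))
        em[0, 2] = 5.0  # strong Selection evidence at the first site only
        post, _, _ = forward_backward(model, np.array([1, 2_000_000]), em)
        np.testing.assert_allclose(np.exp(post[1]), 1 / 3, atol=1e-6)

    def test_fewer_switches_as_q_decreases(self):
        rng = np.random.default_rng(6)
        positions = np.cumsum(rng.integers(1, 3, size=150))
        em = random_emissions(rng, 150)
        switches = []
        for q in (0.2, 0.05, 0.01, 0.001):
            path = viterbi(build_hmm(toy_spectra(), q), positions, em)
            switches.append(int((np.diff(path) != 0).sum()))
        assert all(a >= b for a, b in zip(switches, switches[1:]))


class TestEqualSpectra:
    def test_selection_posterior_is_stationary_when_spectra_coincide(self):
        neutral = neutral_start_spectrum(4, 0.02)
        model = build_hmm((neutral, neutral, neutral), 0.05)
        em = np.zeros((5, 3))
        post, _, _ = forward_backward(model, np.arange(1, 6), em)
        np.testing.assert_allclose(np.exp(post[:, 2]), 1 / 3, atol=1e-12)


class TestSweepWindows:
    def decoded(self, states, positions=None, post=None):
        states = np.asarray(states)
        if positions is None:
            positions = np.arange(1, states.size + 1)
        if post is None:
            post = np.full(states.size, -0.5)
        return DecodedPath("chr1", np.asarray(positions), states, np.asarray(post), 0.0)

    def test_no_selection_no_windows(self):
        assert call_sweep_windows(self.decoded([0, 1, 0, 1])) == []

    def test_run_length_semantics(self):
        wins = call_sweep_windows(self.decoded([0, 0, 2, 2, 2, 0, 2]))
        assert [(w.start, w.end) for w in wins] == [(3, 5), (7, 7)]
        assert all(w.peak_log_posterior <= 0 for w in wins)

    def test_peak_is_window_maximum(self):
        post = np.array([-9.0, -2.0, -0.1, -3.0, -8.0])
        wins = call_sweep_windows(self.decoded([2, 2, 2, 2, 0], post=post))
        assert wins[0].peak_log_posterior == pytest.approx(-0.1)

    def test_windows_use_genomic_positions(self):
        wins = call_sweep_windows(
            self.decoded([0, 2, 2, 0], positions=np.array([100, 250, 400, 900]))
        )
        assert (wins[0].start, wins[0].end) == (250, 400)


class TestSweepRecoverySanity:
    def test_strong_sweep_block_is_recovered(self):
        """End-to-end recovery when the emission signal exceeds the switch cost.

        A 500-site full sweep (no escaping lineages) against q=1e-3: the
        block's log-odds (~80 nats) dwarf the 4|ln q| ~ 28-nat entry cost, so
        the Viterbi Selection run must land on the true block.
        """
        cfg = SimConfig(length=2000, seed=42, sweep_blocks=[(800, 1299, 0.0)])
        lines, _ = simulate_pileup(cfg)
        vecs = vectors_from_lines(lines, cfg.n)
        spectra = build_state_spectra(cfg.resolved_truth(), p_sel=0.0, p_int=0.6)
        model = build_hmm(spectra, 1e-3)
        decoded = decode(model, vecs)
        sel = set(decoded.positions[decoded.states == 2].tolist())
        true = set(range(800, 1300))
        assert sel, "no Selection sites decoded"
        jaccard = len(sel & true) / len(sel | true)
        assert jaccard >= 0.5
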