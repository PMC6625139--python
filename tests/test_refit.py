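"""Signature refit: cosine objective, greedy selection, oracle checks."""

import itertools

import numpy as np
import pytest

from sebsig.refit import (
    RefitConfig,
    SignatureMatrix,
    SignatureRefit,
    combined_contribution,
    cosine_similarity,
    refit,
)
from sebsig.simulate import SignatureMixture, simulate_catalog


def grid_search_cosine(target, matrix, support, resolution=0.005):
    """Exhaustive grid search over mixtures of the given signatures.

    Enumerates simplex weights at the given resolution over the support
    set and returns the best achievable cosine — the independent optimum
    the greedy refit is compared against.
    """
    target = np.asarray(target, float)
    rows = np.array([matrix.row(s) for s in support])
    steps = int(round(1.0 / resolution))
    best = -1.0
    if len(support) == 1:
        return cosine_similarity(target, rows[0])
    if len(support) == 2:
        for i in range(steps + 1):
            w = np.array([i, steps - i]) / steps
            best = max(best, cosine_similarity(target, w @ rows))
        return best
    assert len(support) == 3
    for i in range(steps + 1):
        for j in range(steps + 1 - i):
            w = np.array([i, j, steps - i - j]) / steps
            best = max(best, cosine_similarity(target, w @ rows))
    return best


class TestCosine:
    def test_identity(self):
        v = np.arange(1.0, 97.0)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_support_is_orthogonal(self):
        a = np.zeros(96); a[:48] = 1
        b = np.zeros(96); b[48:] = 1
        assert cosine_similarity(a, b) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(96), rng.random(96)
        assert cosine_similarity(2 * a, b) == pytest.approx(
            cosine_similarity(a, b), abs=1e-12
        )

    def test_zero_vector_is_an_error(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(96), np.ones(96))


class TestRefit:
    def test_single_signature_identity(self, signature_matrix):
        cat = 10_000 * signature_matrix.row("Signature 6")
        res = SignatureRefit(cat, signature_matrix).fit()
        assert res.weights["Signature 6"] == pytest.approx(1.0)
        assert res.cosine >= 0.999

    def test_two_signature_mixture_recovered_against_grid_oracle(self, signature_matrix):
        """Expected-count catalog of 0.6 sig1 + 0.4 sig6: greedy weights land
        within +-0.02 of truth and the cosine matches an exhaustive
        two-signature grid search at 0.005 resolution within 1e-3."""
        mix = SignatureMixture(
            weights={"Signature 1": 0.6, "Signature 6": 0.4}, total_snvs=10_000
        )
        cat = simulate_catalog(mix, signature_matrix, expected=True)
        res = SignatureRefit(cat, signature_matrix).fit()
        assert res.weights["Signature 1"] == pytest.approx(0.6, abs=0.02)
        assert res.weights["Signature 6"] == pytest.approx(0.4, abs=0.02)
        oracle = grid_search_cosine(cat, signature_matrix,
                                    ["Signature 1", "Signature 6"])
        assert abs(res.cosine - oracle) <= 1e-3

    def test_three_signature_multinomial_combined_recovery(self, signature_matrix):
        """A 10k-SNV multinomial draw from the MMR-deficient-scale mixture
        (sig6 0.31 + sig15 0.10, combined 0.41) refits to a combined
        sig6+sig15 weight within +-0.05."""
        mix = SignatureMixture(
            weights={"Signature 6": 0.31, "Signature 15": 0.10, "Signature 1": 0.59},
            total_snvs=10_000,
        )
        cat = simulate_catalog(mix, signature_matrix, seed=17)
        res = SignatureRefit(cat, signature_matrix).fit()
        assert res.combined(["Signature 6", "Signature 15"]) == pytest.approx(
            41.0, abs=5.0
        )

    def test_objective_is_monotone_over_accepted_iterations(self, signature_matrix):
        mix = SignatureMixture(
            weights={"Signature 1": 0.5, "Signature 6": 0.3, "Signature 7": 0.2},
            total_snvs=5_000,
        )
        cat = simulate_catalog(mix, signature_matrix, seed=3)
        res = SignatureRefit(cat, signature_matrix).fit()
        traj = res.objective_trajectory
        assert all(b >= a for a, b in zip(traj, traj[1:]))

    def test_scale_invariance_of_refit(self, signature_matrix):
        cat = simulate_catalog(
            SignatureMixture(weights={"Signature 1": 0.7, "Signature 6": 0.3},
                             total_snvs=2_000),
            signature_matrix, expected=True,
        )
        r1 = SignatureRefit(cat, signature_matrix).fit()
        r5 = SignatureRefit(5 * cat, signature_matrix).fit()
        assert np.allclose(r1.weights.to_numpy(), r5.weights.to_numpy(), atol=1e-9)

    def test_all_zero_catalog_is_refused(self, signature_matrix):
        with pytest.raises(ValueError, match="all-zero"):
            SignatureRefit(np.zeros(96), signature_matrix)

    def test_weight_floor_discards_trace_exposures(self, signature_matrix):
        mix = SignatureMixture(
            weights={"Signature 1": 0.97, "Signature 6": 0.03}, total_snvs=10_000
        )
        cat = simulate_catalog(mix, signature_matrix, expected=True)
        res = SignatureRefit(cat, signature_matrix).fit()
        assert "Signature 6" not in res.exposures.index  # below 0.06 floor
        assert res.weights.sum() == pytest.approx(1.0)

    def test_sse_objective_agrees_on_clean_mixtures(self, signature_matrix):
        cat = simulate_catalog(
            SignatureMixture(weights={"Signature 1": 0.6, "Signature 6": 0.4},
                             total_snvs=10_000),
            signature_matrix, expected=True,
        )
        res = refit(cat, signature_matrix, RefitConfig(objective="sse"))
        assert res.weights["Signature 1"] == pytest.approx(0.6, abs=0.02)

    def test_summary_mentions_cosine_and_exposures(self, signature_matrix):
        cat = 1_000 * signature_matrix.row("Signature 7")
        text = SignatureRefit(cat, signature_matrix).fit().summary()
        assert "cosine" in text and "Signature 7" in text


class TestCombinedContribution:
    WEIGHTS = {"Signature 6": 0.31, "Signature 15": 0.08, "Signature 1": 0.61}

    def test_empty_list_is_zero(self):
        assert combined_contribution(self.WEIGHTS, []) == 0.0

    def test_all_ids_is_hundred(self):
        assert combined_contribution(self.WEIGHTS, list(self.WEIGHTS)) == pytest.approx(100.0)

    def test_mmr_pair_arithmetic(self):
        assert combined_contribution(
            self.WEIGHTS, ["Signature 6", "Signature 15"]
        ) == pytest.approx(39.0)

    def test_unknown_id_raises(self):
        with pytest.raises(KeyError):
            combined_contribution(self.WEIGHTS, ["Signature 99"])
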