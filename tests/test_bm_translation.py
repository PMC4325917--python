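import numpy as np
import pytest

from spikesampling.bm_translation import (
    BoltzmannMachine,
    FactorSpec,
    bm_from_dict,
    bm_to_dict,
    boltzmann_distribution,
    build_boltzmann,
    clamp,
    direct_terms,
    expand_factor,
    factors_from_network,
    principal_distribution,
)
from spikesampling.experiments import knill_kersten_network
from spikesampling.graph_model import BayesianNetwork, enumerate_joint
from spikesampling.random_bn import GeneratorConfig, generate


def tv(p, q):
    return 0.5 * np.abs(np.asarray(p) - np.asarray(q)).sum()


class TestFactors:
    def test_parentless_uniform_node_gives_flat_factor(self):
        bn = BayesianNetwork(("A",), {"A": ()}, {"A": [0.5]})
        (f,) = factors_from_network(bn)
        assert f.order == 1
        np.testing.assert_allclose(f.table, [0.5, 0.5])

    def test_two_parent_node_gives_third_order_factor(self):
        bn = knill_kersten_network()
        factors = {f.factor_id: f for f in factors_from_network(bn)}
        assert factors["Z3"].order == 3
        assert factors["Z3"].table.size == 8

    def test_degenerate_cpt_rejected(self):
        bn = BayesianNetwork(("A",), {"A": ()}, {"A": [1.0]})
        with pytest.raises(ValueError):
            factors_from_network(bn)


class TestDirectTerms:
    def test_flat_first_order_factor_has_zero_bias(self):
        f = FactorSpec("k", (0,), [0.4, 0.4])
        _, biases = direct_terms(f)
        assert biases[0] == pytest.approx(0.0)

    def test_symmetric_second_order_weight(self):
        a, c = 0.4, 0.1
        f = FactorSpec("k", (0, 1), [a, c, c, a])
        pairs, biases = direct_terms(f)
        assert pairs[0, 2] == pytest.approx(2 * np.log(a / c))
        assert biases[0] == pytest.approx(np.log(c / a))

    def test_two_node_network_compiles_exactly(self):
        bn = BayesianNetwork(("A", "B"), {"A": (), "B": ("A",)},
                             {"A": [0.3], "B": [0.2, 0.7]})
        bm = build_boltzmann(bn)
        assert bm.n_units == 2
        np.testing.assert_allclose(
            boltzmann_distribution(bm).probabilities,
            enumerate_joint(bn).probabilities,
            atol=1e-12,
        )


class TestExpandFactor:
    def test_third_order_factor_creates_eight_aux_units(self):
        f = FactorSpec("k", (0, 1, 2), np.linspace(0.1, 0.9, 8))
        couplings, biases, M = expand_factor(f, gamma=10.0)
        assert couplings.shape == (8, 3)
        assert M == pytest.approx(10.0 * 0.9)

    def test_all_zero_assignment_bias(self):
        table = np.linspace(0.1, 0.9, 8)
        f = FactorSpec("k", (0, 1, 2), table)
        _, biases, _ = expand_factor(f, gamma=10.0, mu=1.0 + 1e-4)
        expected = np.log((1.0 + 1e-4) * table[0] / table.min() - 1.0)
        assert biases[0] == pytest.approx(expected)

    def test_low_order_rejected(self):
        f = FactorSpec("k", (0, 1), [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError):
            expand_factor(f)


class TestBuildBoltzmann:
    def test_independent_pair_gives_logit_biases(self):
        bn = BayesianNetwork(("A", "B"), {"A": (), "B": ()},
                             {"A": [0.3], "B": [0.8]})
        bm = build_boltzmann(bn)
        np.testing.assert_allclose(bm.W, 0.0)
        assert bm.b[0] == pytest.approx(np.log(0.3 / 0.7))
        assert bm.b[1] == pytest.approx(np.log(0.8 / 0.2))

    def test_knill_kersten_unit_count(self):
        """4 principal units + 2**3 auxiliaries from the one third-order factor."""
        bm = build_boltzmann(knill_kersten_network())
        assert bm.n_units == 12
        assert sum(r == "principal" for r in bm.roles) == 4

    def test_symmetry_and_block_structure(self):
        bm = build_boltzmann(knill_kersten_network())
        np.testing.assert_allclose(bm.W, bm.W.T)
        assert np.all(np.diag(bm.W) == 0)
        aux = [i for i, r in enumerate(bm.roles) if r == "auxiliary"]
        # no auxiliary-auxiliary couplings
        assert np.all(bm.W[np.ix_(aux, aux)] == 0)

    def test_second_order_only_networks_compile_exactly(self, rng):
        for _ in range(5):
            K = int(rng.integers(2, 5))
            nodes = tuple(f"N{i}" for i in range(K))
            parents = {nodes[0]: ()}
            cpt = {nodes[0]: rng.uniform(0.1, 0.9, 1)}
            for i in range(1, K):  # at most one parent: all factors order <= 2
                pa = (nodes[int(rng.integers(i))],) if rng.random() < 0.7 else ()
                parents[nodes[i]] = pa
                cpt[nodes[i]] = rng.uniform(0.1, 0.9, 2 ** len(pa))
            bn = BayesianNetwork(nodes, parents, cpt)
            bm = build_boltzmann(bn)
            np.testing.assert_allclose(
                boltzmann_distribution(bm).probabilities,
                enumerate_joint(bn).probabilities,
                atol=1e-10,
            )

    def test_gamma_monotone_tv_on_random_networks(self):
        """Finite-M error of the auxiliary expansion shrinks as gamma grows."""
        checked = 0
        seed = 0
        while checked < 10:
            bn = generate(GeneratorConfig(K=4, N=200, eta=1.0, seed=seed))
            seed += 1
            bm10 = build_boltzmann(bn, gamma=10.0)
            if bm10.n_units > 20:
                continue
            p = enumerate_joint(bn).probabilities
            tvs = [
                tv(principal_distribution(build_boltzmann(bn, gamma=g)), p)
                for g in (5.0, 10.0, 15.0)
            ]
            assert tvs[0] >= tvs[1] >= tvs[2]
            checked += 1


class TestBoltzmannDistribution:
    def test_zero_parameters_give_uniform(self):
        bm = BoltzmannMachine(W=np.zeros((3, 3)), b=np.zeros(3),
                              roles=("principal",) * 3)
        np.testing.assert_allclose(boltzmann_distribution(bm).probabilities, 1 / 8)

    def test_single_unit_is_logistic(self):
        bm = BoltzmannMachine(W=np.zeros((1, 1)), b=np.array([1.3]),
                              roles=("principal",))
        p = boltzmann_distribution(bm).probabilities
        assert p[1] == pytest.approx(1 / (1 + np.exp(-1.3)))

    def test_against_direct_summation_oracle(self, rng):
        W = rng.normal(0, 1, (3, 3))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        b = rng.normal(0, 1, 3)
        bm = BoltzmannMachine(W=W, b=b, roles=("principal",) * 3)
        # independent oracle: explicit loop over states and energy terms
        weights = []
        for s in range(8):
            z = np.array([(s >> k) & 1 for k in range(3)], dtype=float)
            e = b @ z
            for i in range(3):
                for j in range(i + 1, 3):
                    e += W[i, j] * z[i] * z[j]
            weights.append(np.exp(e))
        expected = np.array(weights) / np.sum(weights)
        np.testing.assert_allclose(
            boltzmann_distribution(bm).probabilities, expected, atol=1e-12
        )


class TestClamp:
    def test_clamp_nothing_is_identity(self):
        bm = build_boltzmann(knill_kersten_network())
        assert clamp(bm, {}).clamp == {}

    def test_clamped_distribution_conditions_exactly(self):
        bn = knill_kersten_network()
        bm = clamp(build_boltzmann(bn), {"Z3": 1, "Z4": 0})
        assert bm.clamp == {2: 1, 3: 0}
        assert bm.effective_bias()[2] == 20.0
        assert bm.effective_bias()[3] == -20.0
        q = principal_distribution(bm)
        # all mass on states compatible with the evidence
        for s in range(16):
            if not ((s >> 2) & 1) or ((s >> 3) & 1):
                assert q[s] == 0.0

    def test_auxiliary_clamp_rejected(self):
        bm = build_boltzmann(knill_kersten_network())
        with pytest.raises(ValueError):
            clamp(bm, {5: 1})

    def test_json_round_trip(self):
        bm = clamp(build_boltzmann(knill_kersten_network()), {"Z4": 1})
        back = bm_from_dict(bm_to_dict(bm))
        np.testing.assert_allclose(back.W, bm.W)
        np.testing.assert_allclose(back.b, bm.b)
        assert back.clamp == bm.clamp
        assert back.aux_map == bm.aux_map
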