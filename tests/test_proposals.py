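"""Proposal weight functions against hand values and literal-formula oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest

import iscoal as ic
from iscoal.sampling import _RunCache


def _node(dataset_or_config):
    cache = _RunCache()
    c = dataset_or_config
    X = getattr(c, "X")
    nu = getattr(c, "nu")
    return cache.node_for(np.ascontiguousarray(X), np.asarray(nu, dtype=np.int64))


class TestEGT:
    def test_table1_weights_theta5(self, table1):
        node = _node(table1)
        w = ic.EGTProposal(5.0).step_weights(node)
        # coalescence: nu(nu-1)/n = 2/5; type-I removal: theta/n = 1
        assert w.tolist() == [pytest.approx(0.4), 1.0]

    def test_theta_zero_kills_mutations(self, table1):
        node = _node(table1)
        w = ic.EGTProposal(0.0).step_weights(node)
        assert w.tolist() == [pytest.approx(0.4), 0.0]

    def test_type_two_weight(self):
        # rows {10, 01, 00}; row 1's lone mutation merges it into row 3
        d = ic.K69Dataset(X=np.array([[1, 0], [0, 1], [0, 0]], dtype=np.uint8),
                          nu=[1, 1, 2])
        node = _node(d)
        w = ic.EGTProposal(1.0).step_weights(node)
        kinds = [e[0] for e in node.events]
        i2 = kinds.index(ic.EventKind.MUT_TYPE_II)
        # theta * (nu_merge + 1) / n = 1 * 3 / 4
        assert w[i2] == pytest.approx(3 / 4)


class TestSD:
    def test_table1_weights(self, table1):
        w = ic.SDProposal().step_weights(_node(table1))
        assert w.tolist() == [2.0, 1.0]

    def test_theta_free(self, table1):
        node = _node(table1)
        w = ic.SDProposal().step_weights(node)
        assert np.array_equal(w, ic.SDProposal().step_weights(node))


class TestHuwPNext:
    def test_n2_d1_is_one(self):
        for theta in (0.3, 1.0, 7.0):
            assert ic.huw_p_next(1, 2, theta) == pytest.approx(1.0)

    def test_d_equals_n(self):
        assert ic.huw_p_next(6, 6, 2.0) == 1.0

    def test_matches_literal_formula(self):
        # independent naive transcription in exact rationals
        def oracle(d, n, theta):
            th = Fraction(theta)
            if d == 1:
                num = Fraction(1, 1) / (n - 1 + th)
                den = sum(Fraction(k - 1) / ((k - 1 + th) * (n - 1))
                          for k in range(2, n + 1))
                return float(num / den)
            num = Fraction(0)
            den = Fraction(0)
            for k in range(2, n - d + 2):
                a = Fraction(math.comb(n - d - 1, k - 2), math.comb(n - 1, k - 1))
                a /= (k - 1 + th)
                den += a
                num += a * Fraction(d - 1, n - k)
            return float(num / den)

        for (d, n, theta) in [(3, 10, 2.0), (2, 5, 0.5), (5, 9, 4.0), (1, 8, 1.5)]:
            assert ic.huw_p_next(d, n, theta) == pytest.approx(
                oracle(d, n, theta), rel=1e-12)

    def test_in_unit_interval(self):
        for n in range(2, 20):
            for d in range(1, n + 1):
                for theta in (0.1, 1.0, 10.0):
                    p = ic.huw_p_next(d, n, theta)
                    assert 0.0 <= p <= 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ic.huw_p_next(0, 5, 1.0)
        with pytest.raises(ValueError):
            ic.huw_p_next(2, 5, 0.0)


class TestHUW:
    def test_weights_match_literal_transcription(self, table1):
        # u_{i,m} summed per row, written out longhand
        theta0 = 2.0
        X, nu = table1.X, table1.nu
        n = 5
        dm = [int(X[:, m] @ nu) for m in range(4)]
        p = [ic.huw_p_next(d, n, theta0) for d in dm]
        expect = []
        for i in range(4):
            tot = 0.0
            for m in range(4):
                if X[i, m]:
                    tot += p[m] * nu[i] / dm[m]
                elif dm[m] < n:
                    tot += (1 - p[m]) * nu[i] / (n - dm[m])
            expect.append(tot)
        node = _node(table1)
        w = ic.HUWProposal(theta0).step_weights(node)
        rows = [e[1] for e in node.events]
        assert np.allclose(w, [expect[r] for r in rows], rtol=1e-12)

    def test_normalised_weights_sum_to_one_for_pair(self, one_mutation_pair):
        node = _node(one_mutation_pair)
        w = ic.HUWProposal(1.0).step_weights(node)
        assert (w > 0).all()
        assert (w / w.sum()).sum() == pytest.approx(1.0)

    def test_zero_columns_fall_back_to_sd(self):
        d = ic.K69Dataset(X=np.zeros((1, 0), dtype=np.uint8), nu=[3])
        node = _node(d)
        w = ic.HUWProposal(2.0).step_weights(node)
        assert w.tolist() == [3.0]

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(2)
        d = ic.simulate_dataset(10, 4.0, rng)
        if d.num_sites >= 2:
            node = _node(d)
            w = ic.HUWProposal(3.0).step_weights(node)
            cp = rng.permutation(d.num_sites)
            d2 = ic.K69Dataset(X=d.X[:, cp], nu=d.nu.copy())
            w2 = ic.HUWProposal(3.0).step_weights(_node(d2))
            assert np.allclose(sorted(w), sorted(w2))


class TestExactSingleton:
    def test_delegation_when_multiplicities_exceed_one(self, table1):
        node = _node(table1)  # nu = (2,1,1,1): not all-singleton
        prop = ic.ExactSingletonProposal(ic.SDProposal(), theta=2.0)
        w = prop.step_weights(node)
        assert np.allclose(w, ic.SDProposal().step_weights(node))
        assert prop.delegate_steps == 1 and prop.exact_steps == 0

    def test_exact_regime_on_all_singleton_config(self):
        # two singleton haplotypes with private mutations: both events
        # live in the all-singleton subgraph
        d = ic.K69Dataset(X=np.array([[1, 0], [0, 1]], dtype=np.uint8), nu=[1, 1])
        node = _node(d)
        prop = ic.ExactSingletonProposal(ic.SDProposal(), theta=2.0)
        w = prop.step_weights(node)
        assert prop.exact_steps == 1
        cache = ic.ExactCache(theta=2.0)
        _, p_exact = ic.exact_step_distribution(d.initial_config(), 2.0, cache)
        assert np.allclose(w / w.sum(), p_exact)

    def test_budget_exhaustion_falls_back(self):
        d = ic.K69Dataset(X=np.array([[1, 0], [0, 1]], dtype=np.uint8), nu=[1, 1])
        node = _node(d)
        prop = ic.ExactSingletonProposal(ic.SDProposal(), theta=2.0, max_keys=1)
        w = prop.step_weights(node)
        assert prop.exact_steps == 0 and prop.delegate_steps == 1
        assert np.allclose(w, ic.SDProposal().step_weights(node))

    def test_mixed_ess_not_worse_than_delegate(self, table1):
        # paired-seed comparison over replicate seeds
        diffs = []
        for seed in range(10):
            r_sd = ic.run_sampler(ic.SDProposal(), table1, 2.0,
                                  ic.Budget.realizations(5000), seed=seed)
            prop = ic.ExactSingletonProposal(ic.SDProposal(), theta=2.0)
            r_mx = ic.run_sampler(prop, table1, 2.0,
                                  ic.Budget.realizations(5000), seed=seed)
            diffs.append(ic.ess(r_mx) - ic.ess(r_sd))
        assert np.mean(diffs) > -50  # never meaningfully worse


class TestCrossProposalConsistency:
    def test_all_proposals_agree_on_table1(self, table1):
        theta = 2.0
        exact = math.exp(ic.exact_log_likelihood(table1, theta))
        for name in ("egt", "sd", "huw", "exact-singleton"):
            run = ic.run_sampler(ic.get_proposal(name, theta=theta), table1,
                                 theta, ic.Budget.realizations(10_000), seed=5)
            est = ic.likelihood_estimate(run)
            se = ic.standard_error(run)
            assert abs(est - exact) < 4 * se

    def test_full_support_on_simulated_data(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            d = ic.simulate_dataset(8, 3.0, rng)
            for name in ("egt", "sd", "huw"):
                ic.run_sampler(ic.get_proposal(name, theta=3.0), d, 3.0,
                               ic.Budget.realizations(50), seed=1)


class TestFactory:
    def test_factory_names(self):
        assert ic.get_proposal("egt", theta=1.0).name == "egt"
        assert ic.get_proposal("sd").name == "sd"
        assert ic.get_proposal("huw", theta0=2.0).name == "huw"
        assert "sd" in ic.get_proposal("exact-singleton", theta=1.0).name

    def test_missing_parameters_rejected(self):
        with pytest.raises(ValueError):
            ic.get_proposal("egt")
        with pytest.raises(ValueError):
            ic.get_proposal("huw")
        with pytest.raises(ValueError):
            ic.get_proposal("nope")
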