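"""The cis-trans coevolution simulator: pattern algebra, lineage evolution,
swap construction, and cohort generation."""

from collections import Counter

import numpy as np
import pytest

from swapmeta.classify import classify_experiment
from swapmeta.simulate import (
    EvolutionRates, RegulatoryState, SimulationError, SimulatorConfig,
    TransFactor, coded_view, evolve_lineage, expression_pattern,
    simulate_cohort, simulate_swap_experiment,
)

ZERO = dict(site_gain=0.0, site_loss=0.0, trans_domain_change=0.0,
            coevolution_conserving=0.0, coevolution_diverging=0.0)


def rates(**kw):
    return EvolutionRates(**{**ZERO, **kw})


class TestExpressionPattern:
    def test_single_match_unions_that_factors_domains(self):
        f = TransFactor("s1", frozenset({"head", "wing"}))
        assert expression_pattern(Counter(["s1"]), [f]) == {"head", "wing"}

    def test_no_sites_no_pattern(self):
        f = TransFactor("s1", frozenset({"head"}))
        assert expression_pattern(Counter(), [f]) == frozenset()

    def test_union_over_matching_factors_only(self):
        factors = [TransFactor("s1", frozenset({"A"})),
                   TransFactor("s2", frozenset({"B"})),
                   TransFactor("s3", frozenset({"C"}))]
        pattern = expression_pattern(Counter(["s1", "s2"]), factors)
        assert pattern == {"A", "B"}


class TestEvolveLineage:
    def test_zero_steps_identity(self):
        state = SimulatorConfig().ancestor()
        out, log = evolve_lineage(state, 0, EvolutionRates(),
                                  np.random.default_rng(0))
        assert out.cis_sites == state.cis_sites
        assert out.trans_factors == state.trans_factors
        assert log == []

    def test_all_zero_rates_change_nothing(self):
        state = SimulatorConfig().ancestor()
        out, log = evolve_lineage(state, 1000, rates(),
                                  np.random.default_rng(0))
        assert out.cis_sites == state.cis_sites
        assert out.trans_factors == state.trans_factors
        assert all(e.endswith(":noop") for (_, _, e) in log)

    def test_certain_site_gain_adds_one_matching_site_per_step(self):
        state = SimulatorConfig().ancestor()
        out, log = evolve_lineage(state, 1, rates(site_gain=1.0),
                                  np.random.default_rng(3))
        assert log == [("L", 0, "site_gain")]
        # exactly one new site, and its label matches an existing factor
        diff = Counter(out.cis_sites)
        diff.subtract(state.cis_sites)
        (gained_label, n), = [kv for kv in diff.items() if kv[1] != 0]
        assert n == 1
        assert gained_label in {f.label for f in out.trans_factors}

    def test_site_loss_on_empty_cis_is_logged_noop(self):
        state = RegulatoryState(Counter(),
                                [TransFactor("s0", frozenset({"d0"}))])
        out, log = evolve_lineage(state, 1, rates(site_loss=1.0),
                                  np.random.default_rng(0))
        assert log == [("L", 0, "site_loss:noop")]
        assert out.cis_sites == Counter()

    def test_deterministic_given_generator_seed(self):
        state = SimulatorConfig().ancestor()
        a = evolve_lineage(state, 50, EvolutionRates(),
                           np.random.default_rng(11))
        b = evolve_lineage(state, 50, EvolutionRates(),
                           np.random.default_rng(11))
        assert a == b

    def test_conserving_coevolution_preserves_output(self):
        config = SimulatorConfig()
        state = config.ancestor()
        before = expression_pattern(state.cis_sites, state.trans_factors)
        out, log = evolve_lineage(state, 30,
                                  rates(coevolution_conserving=1.0),
                                  np.random.default_rng(5))
        assert any(e == "coevolution_conserving" for (_, _, e) in log)
        after = expression_pattern(out.cis_sites, out.trans_factors)
        assert after == before


class TestRates:
    def test_rates_must_be_probabilities(self):
        with pytest.raises(SimulationError):
            EvolutionRates(site_gain=-0.1)
        with pytest.raises(SimulationError):
            EvolutionRates(site_gain=0.9, site_loss=0.9)


class TestSimulateSwap:
    def test_zero_divergence_time_all_patterns_equal_c1(self):
        sim = simulate_swap_experiment(SimulatorConfig(), 0,
                                       rng=np.random.default_rng(0))
        assert sim.donor_pattern == sim.host_pattern == sim.swap_pattern
        assert sim.true_mode == "none"
        exp = coded_view(sim, 0, 0.0, np.random.default_rng(0))
        assert classify_experiment(exp).value == "C1"

    def test_cis_only_divergence_is_always_donor_like(self):
        """Under cis-only evolution the host trans background equals the
        donor's, so whenever the endogenous patterns differ the swap is
        donor-like (C3) — never host-like (C2)."""
        config = SimulatorConfig()
        r = rates(site_gain=0.2, site_loss=0.2)
        seen_c3 = 0
        for i in range(300):
            rng = np.random.default_rng(1000 + i)
            sim = simulate_swap_experiment(config, 6, r, rng=rng)
            if sim.donor_pattern != sim.host_pattern:
                exp = coded_view(sim, i, 0.0, rng)
                assert classify_experiment(exp).value == "C3"
                seen_c3 += 1
        assert seen_c3 > 50

    def test_conserving_coevolution_yields_dsd(self):
        """Conserving coevolution keeps both endogenous patterns identical
        while making the donor cis element depend on lineage-private labels,
        so any event surfaces as C5 (Developmental Systems Drift)."""
        config = SimulatorConfig()
        r = rates(coevolution_conserving=0.3)
        seen_c5 = 0
        for i in range(200):
            rng = np.random.default_rng(2000 + i)
            sim = simulate_swap_experiment(config, 5, r, rng=rng)
            assert sim.donor_pattern == sim.host_pattern
            events = [e for (_, _, e) in sim.event_log
                      if not e.endswith(":noop")]
            exp = coded_view(sim, i, 0.0, rng)
            cat = classify_experiment(exp).value
            if events:
                assert cat == "C5"
                seen_c5 += 1
            else:
                assert cat == "C1"
        assert seen_c5 > 50

    def test_true_mode_precedence_coevolution_wins(self):
        r = rates(site_gain=0.3, trans_domain_change=0.3,
                  coevolution_diverging=0.3)
        modes = set()
        for i in range(100):
            sim = simulate_swap_experiment(SimulatorConfig(), 8, r,
                                           rng=np.random.default_rng(i))
            modes.add(sim.true_mode)
        assert modes <= {"none", "cis_only", "trans_only",
                         "coevolution_divergent", "coevolution_conserved"}
        assert "coevolution_divergent" in modes


class TestCohort:
    def test_time_zero_cohort_all_c1(self):
        _, coded = simulate_cohort(100, [0], seed=0)
        assert len(coded) == 100
        assert {classify_experiment(e).value for e in coded} == {"C1"}

    def test_deterministic_given_seed(self):
        t1, c1 = simulate_cohort(50, [3, 6], seed=42)
        t2, c2 = simulate_cohort(50, [3, 6], seed=42)
        assert c1 == c2
        assert [s.true_mode for s in t1] == [s.true_mode for s in t2]

    def test_full_noise_records_everything_alike(self):
        _, coded = simulate_cohort(200, [20], epsilon=1.0, seed=7)
        assert {classify_experiment(e).value for e in coded} == {"C1"}

    def test_noise_monotonically_masks_divergence(self):
        """The recorded diverged fraction is non-increasing in the
        detection-noise probability."""
        fractions = []
        for eps in (0.0, 0.3, 0.6, 1.0):
            _, coded = simulate_cohort(400, [10], epsilon=eps, seed=11)
            diverged = sum(classify_experiment(e).value != "C1"
                           for e in coded)
            fractions.append(diverged / len(coded))
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))
        assert fractions[0] > 0.5 and fractions[-1] == 0.0

    def test_coded_view_is_valid_and_controlled(self):
        _, coded = simulate_cohort(20, [5], seed=3)
        for e in coded:
            assert e.violations() == []
            assert e.controlled and e.provenance == "simulated"


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("alphabet_size: 6\ndomain_universe: 4\n"
                     "n_factors: 2\nn_sites: 1\n"
                     "rates: {site_gain: 0.5}\n")
        config = SimulatorConfig.from_yaml(p)
        assert config.alphabet_size == 6
        assert config.rates.site_gain == 0.5
        assert config.rates.site_loss == 0.05  # default retained

    def test_ancestor_shape(self):
        state = SimulatorConfig().ancestor()
        assert len(state.trans_factors) == 3
        assert sum(state.cis_sites.values()) == 2
        labels = [f.label for f in state.trans_factors]
        assert len(set(labels)) == 3  # distinct specificities

    def test_invalid_config_rejected(self):
        with pytest.raises(SimulationError):
            SimulatorConfig(n_factors=0)
        with pytest.raises(SimulationError):
            SimulatorConfig(n_factors=2, n_sites=3)
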