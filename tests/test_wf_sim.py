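"""Unit and property tests for the forward Wright-Fisher simulator."""

import numpy as np
import pytest

from softsweep import wf_sim
from softsweep.wf_sim import (
    Deme,
    ScenarioConfig,
    SelectionScheme,
    _OriginLog,
    migrate_step,
    mutate_step,
    recombine_step,
    replicate_rng,
    resample_step,
    run_scenario,
)


def all_resistant_deme(n, config=0b111):
    """A deme fixed for one resistant class, so every event is tracked."""
    d = Deme.founder(n)
    d.configs = np.array([config], dtype=np.int8)
    d.ids = np.array([1], dtype=np.int64)
    return d


class TestMutateStep:
    def test_zero_mu_is_noop(self, rng):
        cfg = ScenarioConfig(N=1000, mu=0.0)
        d = Deme.founder(1000)
        mutate_step(d, cfg, rng)
        assert d.total == 2000 and len(d.ids) == 1

    def test_event_rate_matches_poisson_mean(self, rng):
        """On a 1m background every event creates a class, so the
        class-creation rate estimates the Poisson mean mu*L*2N."""
        cfg = ScenarioConfig(N=1000, mu=2.5e-6, L=1500)  # mean 7.5/generation
        log = _OriginLog()
        t = 400
        for gen in range(t):
            d = all_resistant_deme(1000, config=0b100)
            mutate_step(d, cfg, rng, log, gen)
        mean = (log.n - 1) / t
        se = np.sqrt(cfg.mutation_mean / t)
        assert abs(mean - cfg.mutation_mean) < 3 * se

    def test_one_third_of_adaptive_hits_confer_resistance(self, rng):
        """With every position adaptive, sensitive->resistant flips happen
        for one nucleotide change in three."""
        cfg = ScenarioConfig(
            N=2000, mu=2e-4, L=3, site_positions=(1, 2, 3), rho_cM_per_Mbp=0.0
        )
        gains = events = 0
        log = _OriginLog()
        for gen in range(300):
            d = Deme.founder(2000)  # all sensitive
            n0 = log.n
            mutate_step(d, cfg, rng, log, gen)
            gains += log.n - n0  # every tracked event here is a gain
            # sensitive-site hits that stayed sensitive are untracked:
            events += 2 * 2000 * cfg.mu * cfg.L  # expected events
        frac = gains / events
        assert abs(frac - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / events)

    def test_resistant_site_hit_always_reverts(self, rng):
        cfg = ScenarioConfig(
            N=500, mu=1e-3, L=3, site_positions=(1, 2, 3), rho_cM_per_Mbp=0.0
        )
        log = _OriginLog()
        d = all_resistant_deme(500)
        mutate_step(d, cfg, rng, log, 0)
        new = d.configs[d.ids > 1]
        assert len(new) > 0
        # every new class lost exactly one resistant bit
        assert all(bin(int(c)).count("1") == 2 for c in new)

    def test_copy_count_is_conserved(self, rng):
        cfg = ScenarioConfig(N=1000, mu=1e-5)
        d = all_resistant_deme(1000)
        mutate_step(d, cfg, rng)
        assert d.total == 2000


class TestRecombineStep:
    def test_zero_rho_is_noop(self, rng):
        cfg = ScenarioConfig(N=1000, rho_cM_per_Mbp=0.0)
        d = all_resistant_deme(1000)
        recombine_step(d, cfg, rng)
        assert len(d.ids) == 1

    def test_products_of_100_and_001_parents(self, rng):
        """Breakpoint between the outer sites combines the parental bits:
        products are 100, 001, or the recombinant 101 (the reciprocal 000
        merges into the sensitive class)."""
        cfg = ScenarioConfig(N=1, rho_cM_per_Mbp=1e7)  # force one event
        seen = set()
        for trial in range(400):
            d = Deme(
                np.array([1, 2], dtype=np.int64),
                np.array([0b100, 0b001], dtype=np.int8),
                np.array([1, 1], dtype=np.int64),
                1,
            )
            r = np.random.default_rng(trial)
            recombine_step(d, cfg, r)
            new = d.configs[d.ids > 2]
            seen.update(int(c) for c in new)
            assert d.total == 2
        assert seen <= {0b100, 0b001, 0b101}
        assert 0b101 in seen

    def test_identical_resistant_parents_get_fresh_id(self, rng):
        cfg = ScenarioConfig(N=50, rho_cM_per_Mbp=1e6)
        d = all_resistant_deme(50, config=0b010)
        log = _OriginLog()
        recombine_step(d, cfg, rng, log, 0)
        fresh = d.ids > 1
        assert fresh.any()
        assert np.all(d.configs[fresh] == 0b010)

    def test_infinite_alleles_ids_strictly_increase(self, rng):
        cfg = ScenarioConfig(N=500, mu=1e-5, rho_cM_per_Mbp=100.0)
        log = _OriginLog()
        d = all_resistant_deme(500, config=0b100)
        highest = 1
        for gen in range(50):
            mutate_step(d, cfg, rng, log, gen)
            recombine_step(d, cfg, rng, log, gen)
            assert log.n - 1 >= highest
            highest = log.n - 1
            assert len(np.unique(d.ids)) == len(d.ids)


class TestMigrateStep:
    def test_single_deme_noop(self, rng):
        cfg = ScenarioConfig(N=100, M=5.0)
        demes = [Deme.founder(100)]
        migrate_step(demes, cfg, rng)
        assert demes[0].total == 200

    def test_zero_m_noop(self, rng):
        cfg = ScenarioConfig(N=100, n_subpops=2, M=0.0)
        demes = [Deme.founder(100), Deme.founder(100)]
        migrate_step(demes, cfg, rng)
        assert all(d.total == 200 for d in demes)

    def test_mean_copies_transferred(self, rng):
        """M migrant individuals contribute 2M haplotype copies per
        direction per generation on average."""
        cfg = ScenarioConfig(N=10_000, n_subpops=2, M=10.0)
        total_added = 0
        t = 300
        for _ in range(t):
            demes = [Deme.founder(10_000), Deme.founder(10_000)]
            migrate_step(demes, cfg, rng)
            total_added += demes[0].total - 20_000
        mean = total_added / t
        assert abs(mean - 20.0) < 3 * np.sqrt(40.0 / t)  # Poisson(10)*2 copies

    def test_migrants_mirror_source_composition(self, rng):
        """A resistant class at 30% in the source shows up among migrant
        copies at ~30%."""
        cfg = ScenarioConfig(N=10_000, n_subpops=2, M=50.0)
        got_res = got_all = 0
        for _ in range(200):
            src = Deme(
                np.array([0, 1], dtype=np.int64),
                np.array([0, 0b100], dtype=np.int8),
                np.array([14_000, 6_000], dtype=np.int64),
                10_000,
            )
            dst = Deme.founder(10_000)
            migrate_step([src, dst], cfg, rng)
            added = dst.total - 20_000
            got_all += added
            res_idx = dst.ids == 1
            if res_idx.any():
                got_res += int(dst.counts[res_idx].sum())
        frac = got_res / got_all
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / got_all)


class TestResampleStep:
    def test_fixed_neutral_class_is_absorbing(self, rng):
        d = Deme.founder(1000)
        resample_step(d, np.zeros(8), rng)
        assert d.total == 2000 and len(d.ids) == 1

    def test_neutral_drift_variance(self):
        """One generation of neutral binomial resampling from x=0.5 has
        Var(dx) = x(1-x)/2N."""
        n = 500
        rng = np.random.default_rng(7)
        reps = 20_000
        deltas = np.empty(reps)
        for r in range(reps):
            d = Deme(
                np.array([0, 1], dtype=np.int64),
                np.array([0, 0b001], dtype=np.int8),
                np.array([n, n], dtype=np.int64),
                n,
            )
            resample_step(d, np.zeros(8), rng)
            x = d.counts[d.ids == 1].sum() / (2 * n)
            deltas[r] = x - 0.5
        expected = 0.25 / (2 * n)
        assert abs(deltas.mean()) < 3 * np.sqrt(expected / reps)
        assert deltas.var() == pytest.approx(expected, rel=0.05)

    def test_selection_shifts_expectation(self):
        """E[x'] = x(1+s)/w_bar under the selection-adjusted multinomial."""
        n, s = 2000, 0.05
        rng = np.random.default_rng(8)
        coeffs = np.zeros(8)
        coeffs[0b001] = s
        reps = 5000
        xs = np.empty(reps)
        for r in range(reps):
            d = Deme(
                np.array([0, 1], dtype=np.int64),
                np.array([0, 0b001], dtype=np.int8),
                np.array([n, n], dtype=np.int64),
                n,
            )
            resample_step(d, coeffs, rng)
            xs[r] = d.counts[d.ids == 1].sum() / (2 * n)
        expected = 0.5 * (1 + s) / (1 + 0.5 * s)
        se = np.sqrt(expected * (1 - expected) / (2 * n) / reps)
        assert abs(xs.mean() - expected) < 3 * se

    def test_lethal_scheme_raises(self, rng):
        with pytest.raises(ValueError):
            SelectionScheme(1.0, 1.0, 1.0).coefficients(pesticide=False)


class TestRunScenario:
    def test_determinism_under_fixed_seed(self):
        cfg = ScenarioConfig(N=5000, mu=2.5e-7, burn_in=50, epoch=120, seed=77)
        a = run_scenario(cfg, replicate_rng(77, 0))
        b = run_scenario(cfg, replicate_rng(77, 0))
        assert a.flags == b.flags
        np.testing.assert_array_equal(a.config_freq, b.config_freq)
        np.testing.assert_array_equal(a.ss_pair_prob, b.ss_pair_prob)
        assert a.n_classes_created == b.n_classes_created

    def test_copy_count_conservation_through_generations(self, rng):
        cfg = ScenarioConfig(
            N=2000, mu=2.5e-6, rho_cM_per_Mbp=10.0, n_subpops=2, M=2.0
        )
        demes = [Deme.founder(2000) for _ in range(2)]
        coeffs = cfg.scheme.coefficients(pesticide=True)
        log = _OriginLog()
        for gen in range(200):
            for d in demes:
                mutate_step(d, cfg, rng, log, gen)
                recombine_step(d, cfg, rng, log, gen)
            migrate_step(demes, cfg, rng)
            for d in demes:
                resample_step(d, coeffs, rng)
                assert d.total == 2 * cfg.N

    def test_neutral_scheme_drifts_without_bias(self):
        """With all coefficients zero, a resistant config at 50% stays at
        50% on average."""
        cfg = ScenarioConfig(
            N=300, mu=0.0, rho_cM_per_Mbp=0.0, burn_in=0, epoch=60,
            scheme=SelectionScheme(0.0, 0.0, 0.0),
        )
        finals = []
        for r in range(300):
            rng = replicate_rng(123, r)
            d = Deme(
                np.array([0, 1], dtype=np.int64),
                np.array([0, 0b100], dtype=np.int8),
                np.array([300, 300], dtype=np.int64),
                300,
            )
            coeffs = cfg.scheme.coefficients(pesticide=True)
            for _ in range(cfg.epoch):
                resample_step(d, coeffs, rng)
            x = d.counts[d.ids == 1].sum() / 600 if (d.ids == 1).any() else 0.0
            finals.append(x)
        finals = np.asarray(finals)
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean() - 0.5) < 2 * se + 1e-9

    def test_burnin_balance_matches_deterministic_expectation(self, balance_runs):
        """Late burn-in per-site resistant frequency ~ mu_u/|s_d|."""
        freqs = np.array([r.burnin_resistant_freq for r in balance_runs])
        expected = (2.5e-7 / 3) / 0.05
        se = freqs.std(ddof=1) / np.sqrt(len(freqs))
        assert abs(freqs.mean() - expected) < 2 * se + 0.05 * expected

    def test_scenario_config_roundtrip(self, tmp_path):
        cfg = ScenarioConfig(theta=0.1, n_subpops=3, M=0.5, seed=9)
        for name in ("cfg.yaml", "cfg.json"):
            p = tmp_path / name
            cfg.to_file(p)
            back = ScenarioConfig.from_file(p)
            assert back.to_dict() == cfg.to_dict()
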