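"""The forward Wright-Fisher simulator: neutral equilibrium, demography, sweeps."""

import numpy as np
import pytest

from omegascan import (
    SimParams,
    Sweep,
    read_ms,
    sample_trajectory,
    simulate_neutral,
    simulate_paired,
    simulate_sweep,
    write_ms,
)
from omegascan.simulate import DEMOGRAPHIES, size_schedule
from omegascan.stats import harmonic, sfs, theta_pi


SMALL = dict(n_samples=10, pop_size=40, region_length=10_000.0,
             theta_total=10.0, rho_total=10.0)


def test_seeded_determinism_and_seed_sensitivity():
    p = SimParams(**SMALL)
    a = simulate_neutral(p, 3, seed=42)
    b = simulate_neutral(p, 3, seed=42)
    c = simulate_neutral(p, 3, seed=43)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.positions, y.positions)
        np.testing.assert_array_equal(x.to_codes(), y.to_codes())
    assert any(x.n_snps != y.n_snps or not np.array_equal(x.positions, y.positions)
               for x, y in zip(a, c))


def test_zero_mutation_rate_yields_no_snps():
    p = SimParams(**{**SMALL, "theta_total": 0.0})
    assert all(r.n_snps == 0 for r in simulate_neutral(p, 2, seed=1))


def test_expected_segregating_sites_matches_coalescent():
    p = SimParams(**SMALL)
    reps = simulate_neutral(p, 150, seed=9)
    s = np.array([r.n_snps for r in reps])
    expected = p.theta_total * harmonic(p.n_samples - 1)
    se = s.std(ddof=1) / np.sqrt(len(s))
    assert abs(s.mean() - expected) < 3 * se + 1e-9


def test_recombination_decays_adjacent_ld(rng):
    from omegascan.ld import r2_pairs

    def mean_adjacent_r2(rho, seed):
        p = SimParams(n_samples=16, pop_size=40, region_length=10_000.0,
                      theta_total=15.0, rho_total=rho)
        vals = []
        for rep in simulate_neutral(p, 40, seed=seed):
            if rep.n_snps < 2:
                continue
            idx = np.arange(rep.n_snps - 1)
            vals.append(r2_pairs(rep, idx, idx + 1).mean())
        return np.mean(vals)

    assert mean_adjacent_r2(0.0, 5) > mean_adjacent_r2(200.0, 6)


def test_size_schedule_preserves_bottleneck_intensity():
    for name in ["bottleneck2", "bottleneck3", "bottleneck4"]:
        p = SimParams(demography=name)
        m = p.chromosomes
        epoch = DEMOGRAPHIES[name][0]
        sched = size_schedule(p)
        # realised pairwise coalescent intensity vs the continuous profile
        realised = np.sum(1.0 / sched)
        span_gens = epoch.end * 2 * m
        target = (
            (epoch.start * 2 * m) / m
            + (epoch.end - epoch.start) * 2 * m / (epoch.relative_size * m)
        )
        # whole-generation rounding of fractional epoch boundaries keeps the
        # realised intensity within a quarter of the continuous profile
        assert realised == pytest.approx(target, rel=0.25)
        assert sched.min() >= 2
        assert span_gens < sched.size + 20  # horizon covers the epoch


def test_trajectory_endpoints_and_determinism():
    p = SimParams(**SMALL, sweep=Sweep(alpha=30.0))
    t1 = sample_trajectory(p, seed=5)
    t2 = sample_trajectory(p, seed=5)
    np.testing.assert_array_equal(t1.frequencies, t2.frequencies)
    assert t1.frequencies[0] == pytest.approx(1 / p.chromosomes)
    assert t1.frequencies[-1] == 1.0
    assert np.all(t1.frequencies > 0)


def test_stronger_selection_fixes_faster():
    def mean_sojourn(alpha, seed):
        p = SimParams(**SMALL, sweep=Sweep(alpha=alpha))
        rng = np.random.default_rng(seed)
        return np.mean(
            [sample_trajectory(p, rng).n_generations for _ in range(60)]
        )

    assert mean_sojourn(60.0, 2) < mean_sojourn(15.0, 2)


def test_sweep_reduces_central_diversity():
    p = SimParams(sweep=Sweep(), n_samples=30, pop_size=60,
                  region_length=1_000_000.0, theta_total=300.0, rho_total=200.0)
    central, flank = [], []
    for rep in simulate_sweep(p, 12, seed=21):
        spec_c = sfs(rep, rep.window(450_000, 550_000))
        spec_f = sfs(rep, rep.window(0, 400_000))
        central.append(theta_pi(spec_c))
        flank.append(theta_pi(spec_f) / 4.0)  # per-100kb scale
    assert np.mean(central) < np.mean(flank)


def test_sweep_site_is_not_a_snp_and_positions_sorted():
    p = SimParams(**SMALL, sweep=Sweep(alpha=30.0))
    for rep in simulate_sweep(p, 3, seed=8):
        assert np.all(np.diff(rep.positions) > 0)
        d = rep.derived_counts()
        assert np.all((d > 0) & (d < rep.n_samples))


def test_paired_replicates_share_seeding():
    p = SimParams(**SMALL, sweep=Sweep(alpha=30.0))
    neu, sw = simulate_paired(p, 4, seed=3)
    assert len(neu) == len(sw) == 4
    neu2, sw2 = simulate_paired(p, 4, seed=3)
    for a, b in zip(neu + sw, neu2 + sw2):
        np.testing.assert_array_equal(a.positions, b.positions)


def test_write_ms_round_trip(tmp_path):
    p = SimParams(**SMALL)
    reps = simulate_neutral(p, 2, seed=13)
    path = tmp_path / "sim.ms"
    write_ms(reps, path, region_length=p.region_length)
    back = read_ms(path, region_length=p.region_length)
    for a, b in zip(reps, back):
        assert a.n_snps == b.n_snps
        np.testing.assert_allclose(a.positions, b.positions, atol=p.region_length * 1e-6)
        np.testing.assert_array_equal(a.to_codes(), b.to_codes())


def test_alpha_must_fit_rescaled_population():
    with pytest.raises(ValueError):
        SimParams(**SMALL, sweep=Sweep(alpha=1000.0))
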