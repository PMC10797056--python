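"""Generator and degradation-operator behavior."""

import dataclasses
import math

import numpy as np
import pytest

from magne.diversity import DEFAULT_MU
from magne.experiment import estimate_population_ne, undegraded_family_diversity
from magne.simulate import (
    DegradationConfig,
    SimulationConfig,
    branch_substitution_prob,
    degrade_to_mag,
    simulate_population,
)

from conftest import STOPS


def _all_cds(genomes):
    return {(g.genome_id, fid): seq for g in genomes for fid, seq in g.cds.items()}


def test_zero_theta_yields_identical_genomes():
    cfg = SimulationConfig(n_genomes=5, n_families=10, codons_per_family=30, theta4=0.0, seed=7)
    genomes, truth = simulate_population(cfg)
    reference = genomes[0].cds
    assert all(g.cds == reference for g in genomes)
    assert all(pi == 0.0 for pi in truth.per_family_true_pi if not math.isnan(pi))
    result = estimate_population_ne(genomes)
    assert result.estimate.median_pi_s == 0.0
    assert result.estimate.ne_median == 0.0


def test_same_seed_reproduces_identical_sequences(small_population):
    cfg, genomes, truth = small_population
    again, truth2 = simulate_population(cfg)
    assert _all_cds(genomes) == _all_cds(again)
    assert truth.per_family_true_pi == truth2.per_family_true_pi


@pytest.mark.parametrize("genealogy", ["star", "coalescent"])
def test_no_internal_stop_codons(genealogy):
    cfg = SimulationConfig(
        n_genomes=6,
        n_families=15,
        codons_per_family=40,
        theta4=0.05,
        constrained_rate_ratio=0.5,
        genealogy=genealogy,
        seed=11,
    )
    genomes, _ = simulate_population(cfg)
    for g in genomes:
        for fid, seq in g.cds.items():
            assert len(seq) == 3 * cfg.codons_per_family
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not (codons & STOPS), f"stop codon in {g.genome_id}/{fid}"


def test_branch_probability_inverts_pairwise_difference():
    # two independent tips differ with probability 2b(1-b) + (2/3)b^2
    for theta in (0.0, 0.005, 0.02, 0.05, 0.2):
        b = branch_substitution_prob(theta)
        assert 2 * b * (1 - b) + (2 / 3) * b * b == pytest.approx(theta, abs=1e-12)


def test_star_calibration_single_seed():
    cfg = SimulationConfig(n_genomes=10, n_families=100, codons_per_family=200, theta4=0.02, seed=5)
    _, truth = simulate_population(cfg)
    mean_pi = float(np.nanmean(truth.per_family_true_pi))
    assert mean_pi == pytest.approx(0.02, rel=0.10)


def test_coalescent_calibration_averaged():
    pis = []
    for seed in range(5):
        cfg = SimulationConfig(
            n_genomes=8,
            n_families=60,
            codons_per_family=120,
            theta4=0.02,
            genealogy="coalescent",
            seed=seed,
        )
        _, truth = simulate_population(cfg)
        pis.append(float(np.nanmean(truth.per_family_true_pi)))
    assert float(np.mean(pis)) == pytest.approx(0.02, rel=0.25)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="theta4"):
        SimulationConfig(theta4=0.5)
    with pytest.raises(ValueError):
        SimulationConfig(n_genomes=0)
    with pytest.raises(ValueError):
        DegradationConfig(consensus_collapse_fraction=1.5)
    with pytest.raises(ValueError):
        DegradationConfig(target_completeness=0.0)
    with pytest.warns(UserWarning, match="fourfold"):
        SimulationConfig(codons_per_family=5)


def test_degradation_noop_is_exact(small_population):
    _, genomes, _ = small_population
    fam_div = undegraded_family_diversity(genomes)
    noop = DegradationConfig(0.0, 0.0, 0.0, 1.0, seed=99)
    assert noop.is_noop
    mags = degrade_to_mag(genomes, noop, fam_div)
    for orig, mag in zip(genomes, mags):
        assert mag.cds == orig.cds
        assert mag.source_class == "MAG"


def test_full_consensus_collapse_removes_all_diversity(small_population):
    _, genomes, _ = small_population
    fam_div = undegraded_family_diversity(genomes)
    mags = degrade_to_mag(genomes, DegradationConfig(1.0, 0.0, 0.0, 1.0, seed=1), fam_div)
    reference = mags[0].cds
    assert all(m.cds == reference for m in mags)
    result = estimate_population_ne(mags)
    assert result.estimate.mean_pi_s == 0.0
    assert result.estimate.ne_median == 0.0


def test_variable_loss_removes_most_diverse_families(small_population):
    _, genomes, _ = small_population
    fam_div = undegraded_family_diversity(genomes)
    mags = degrade_to_mag(genomes, DegradationConfig(0.0, 0.2, 1.0, 1.0, seed=2), fam_div)
    n_top = round(0.2 * len(fam_div))
    ranked = sorted(fam_div, key=lambda fid: (-fam_div[fid], fid))
    top = set(ranked[:n_top])
    for m in mags:
        assert not (top & set(m.cds)), "a top-diversity family survived in a MAG"
        assert set(m.cds) == set(genomes[0].cds) - top
    undegraded = estimate_population_ne(genomes).estimate
    degraded = estimate_population_ne(mags).estimate
    assert degraded.median_pi_s <= undegraded.median_pi_s


def test_completeness_loss_reaches_target(small_population):
    _, genomes, _ = small_population
    fam_div = undegraded_family_diversity(genomes)
    mags = degrade_to_mag(genomes, DegradationConfig(0.0, 0.0, 0.0, 0.6, seed=3), fam_div)
    n_orig = len(genomes[0].cds)
    originals = {g.genome_id: g for g in genomes}
    for m in mags:
        assert len(m.cds) == math.floor(0.6 * n_orig)
        assert m.completeness == pytest.approx(100.0 * len(m.cds) / n_orig)
        # surviving sequences are untouched
        for fid, seq in m.cds.items():
            assert seq == originals[m.genome_id].cds[fid]


def test_degradation_deterministic(small_population):
    _, genomes, _ = small_population
    fam_div = undegraded_family_diversity(genomes)
    dcfg = DegradationConfig(seed=8)
    a = degrade_to_mag(genomes, dcfg, fam_div)
    b = degrade_to_mag(genomes, dcfg, fam_div)
    assert _all_cds(a) == _all_cds(b)


def _mean_ne(dcfg_kwargs, seeds, sim_kwargs):
    nes = []
    for seed in seeds:
        cfg = SimulationConfig(seed=seed, **sim_kwargs)
        genomes, _ = simulate_population(cfg)
        fam_div = undegraded_family_diversity(genomes)
        dcfg = DegradationConfig(seed=seed + 1000, **dcfg_kwargs)
        mags = degrade_to_mag(genomes, dcfg, fam_div)
        nes.append(estimate_population_ne(mags).estimate.ne_median)
    return float(np.mean(nes))


SMALL_SIM = dict(n_genomes=4, n_families=30, codons_per_family=60, theta4=0.02)


def test_mean_ne_nonincreasing_in_collapse_fraction():
    seeds = range(20)
    means = [
        _mean_ne(
            dict(consensus_collapse_fraction=f, variable_loss_prob=0.0), seeds, SMALL_SIM
        )
        for f in (0.0, 0.25, 0.5, 0.75, 1.0)
    ]
    assert all(a >= b for a, b in zip(means, means[1:])), means


def test_mean_ne_nonincreasing_in_variable_loss():
    seeds = range(20)
    means = [
        _mean_ne(
            dict(
                consensus_collapse_fraction=0.0,
                variable_loss_quantile=0.2,
                variable_loss_prob=p,
            ),
            seeds,
            SMALL_SIM,
        )
        for p in (0.0, 0.5, 1.0)
    ]
    assert all(a >= b for a, b in zip(means, means[1:])), means
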