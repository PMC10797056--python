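"""Comparative statistics and the replicate bias study."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from magne.experiment import (
    ExperimentConfig,
    estimated_genome_size,
    mann_whitney_u,
    regress_ne_on_divergence,
    run_bias_study,
    write_experiment,
)
from magne.simulate import DegradationConfig, SimulationConfig


# --- estimated genome size ---------------------------------------------------

@pytest.mark.parametrize(
    "size,comp,cont,expect",
    [
        (2_000_000, 100.0, 0.0, 2_000_000),
        (1_000_000, 50.0, 0.0, 2_000_000),
        (2_100_000, 100.0, 5.0, 2_000_000),
    ],
)
def test_estimated_genome_size(size, comp, cont, expect):
    assert estimated_genome_size(size, comp, cont) == pytest.approx(expect)


def test_estimated_genome_size_rejects_bad_inputs():
    with pytest.raises(ValueError):
        estimated_genome_size(1e6, 0.0, 0.0)
    with pytest.raises(ValueError):
        estimated_genome_size(1e6, 50.0, -1.0)


# --- Mann-Whitney ------------------------------------------------------------

def test_mann_whitney_small_exact_example():
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert u == 0
    assert p == pytest.approx(2 / 6)


def test_mann_whitney_identical_multisets():
    _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p >= 0.99


def test_mann_whitney_constant_data_returns_one():
    _, p = mann_whitney_u([5.0, 5.0], [5.0, 5.0, 5.0])
    assert p == 1.0


def _enumeration_oracle(x, y, alternative="two-sided"):
    vals = np.concatenate([x, y])
    nx = len(x)
    ranks = sps.rankdata(vals)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(vals)), nx):
        us.append(ranks[list(idx)].sum() - nx * (nx + 1) / 2)
    us = np.array(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    if alternative == "two-sided":
        return u_obs, min(1.0, 2.0 * min(p_le, p_ge))
    return u_obs, p_ge if alternative == "greater" else p_le


@pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
def test_mann_whitney_matches_enumeration(rng, alternative):
    for nx in (2, 4, 5):
        for ny in (3, 5):
            x = rng.choice(10_000, nx, replace=False).astype(float)
            y = rng.choice(10_000, ny, replace=False).astype(float) + 0.5
            u1, p1 = mann_whitney_u(x, y, alternative=alternative)
            u2, p2 = _enumeration_oracle(x, y, alternative)
            assert u1 == pytest.approx(u2, abs=1e-12)
            assert p1 == pytest.approx(p2, abs=1e-12)


def test_mann_whitney_large_samples_use_normal_approximation(rng):
    x = rng.normal(0, 1, 30)
    y = rng.normal(1, 1, 30)
    _, p = mann_whitney_u(x, y)
    ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert p == pytest.approx(float(ref.pvalue))


# --- regression --------------------------------------------------------------

def test_regression_recovers_exact_line():
    pts = [(x, 2 * x + 1) for x in (0.0, 1.0, 2.0, 5.0)]
    res = regress_ne_on_divergence(pts)
    assert res.slope == pytest.approx(2.0)
    assert res.intercept == pytest.approx(1.0)
    assert res.r_squared == pytest.approx(1.0)


def test_regression_constant_response():
    res = regress_ne_on_divergence([(0.0, 3.0), (1.0, 3.0), (2.0, 3.0)])
    assert res.slope == pytest.approx(0.0)
    assert res.r_squared == pytest.approx(0.0)


def test_regression_constant_predictor_flagged():
    res = regress_ne_on_divergence([(1.0, 1.0), (1.0, 2.0), (1.0, 3.0)])
    assert not res.ok


def test_regression_matches_normal_equations(rng):
    x = rng.uniform(0, 5, 12)
    y = 3.0 * x + rng.normal(0, 1, 12)
    res = regress_ne_on_divergence(list(zip(x, y)))
    xc = x - x.mean()
    slope = float((xc * (y - y.mean())).sum() / (xc**2).sum())
    intercept = float(y.mean() - slope * x.mean())
    assert res.slope == pytest.approx(slope)
    assert res.intercept == pytest.approx(intercept)
    r = float(np.corrcoef(x, y)[0, 1])
    assert res.r_squared == pytest.approx(r * r)


# --- replicate studies -------------------------------------------------------

SMALL_TEMPLATE = SimulationConfig(n_genomes=4, n_families=30, codons_per_family=80)


def test_bias_study_deterministic(tmp_path):
    cfg = ExperimentConfig(
        n_populations_per_class=4,
        sim_template=SMALL_TEMPLATE,
        replicates=1,
        seed=17,
    )
    a = run_bias_study(cfg)
    b = run_bias_study(cfg)
    write_experiment(a, tmp_path / "a")
    write_experiment(b, tmp_path / "b")
    for name in ("experiment_results.tsv", "experiment_stats.tsv", "experiment_summary.json"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_degradation_lowers_mag_class_ne():
    cfg = ExperimentConfig(
        n_populations_per_class=6,
        sim_template=SMALL_TEMPLATE,
        degradation=DegradationConfig(0.5, 0.2, 0.5, 1.0),
        replicates=2,
        seed=23,
    )
    res = run_bias_study(cfg)
    assert res.summary["mean_bias_mag"] < res.summary["mean_bias_isolate"]
    assert res.summary["frac_replicates_mag_bias_lt_1"] == 1.0


def test_no_degradation_gives_comparable_classes():
    cfg = ExperimentConfig(
        n_populations_per_class=6,
        sim_template=SMALL_TEMPLATE,
        degradation=DegradationConfig(0.0, 0.0, 0.0, 1.0),
        replicates=2,
        seed=29,
    )
    res = run_bias_study(cfg)
    # both classes estimate the truth to within sampling noise
    assert res.summary["mean_bias_isolate"] == pytest.approx(1.0, abs=0.25)
    assert res.summary["mean_bias_mag"] == pytest.approx(1.0, abs=0.25)


def test_isolate_ne_increases_with_divergence():
    """Across theta4 values, Ne and whole-genome divergence rise together."""
    cfg = ExperimentConfig(
        n_populations_per_class=12,
        sim_template=SimulationConfig(n_genomes=6, n_families=50, codons_per_family=150),
        degradation=DegradationConfig(0.0, 0.0, 0.0, 1.0),
        theta4_grid=(0.005, 0.01, 0.02, 0.04),
        replicates=1,
        seed=31,
    )
    res = run_bias_study(cfg)
    row = res.stats.iloc[0]
    assert row["isolate_slope"] > 0
    assert row["isolate_reg_p"] < 0.05
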