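"""Population densities, distances, k-NN likelihood, optimizer, reproducibility."""

import math
import random

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps

from corvidsim.cmaes import CMAES, minimize
from corvidsim.inference import (
    Population,
    beta_shapes,
    dataset_distance,
    knn_loglik,
    knn_loglik_distances,
    quantize_p,
    rate_difference_pvalue,
    reproducibility,
    softplus_exponent,
)
from corvidsim.parameters import BirdParameters, ParamEntry
from corvidsim.protocol import SummaryDataset


# -- p-value quantization ---------------------------------------------------

@pytest.mark.parametrize("p, level", [
    (1e-11, 1), (1e-5, 1), (0.000999, 1),
    (0.001, 2), (0.009, 2),
    (0.01, 3), (0.03, 3), (0.049999, 3),
    (0.05, 4), (0.099, 4),
    (0.1, 5), (0.5, 5), (1.0, 5),
])
def test_quantize_p_bands(p, level):
    assert quantize_p(p) == level


def test_quantize_p_monotone_step():
    grid = np.linspace(0, 1, 2001)
    levels = [quantize_p(p) for p in grid]
    assert levels == sorted(levels)
    with pytest.raises(ValueError):
        quantize_p(1.5)


# -- dataset distance -------------------------------------------------------

def _ds(values, pnames=()):
    return SummaryDataset("e", values, frozenset(pnames))


def test_distance_zero_iff_equal_up_to_quantization():
    d1 = _ds({"m": 2.0, "p": 0.03}, ["p"])
    assert dataset_distance(d1, d1) == 0.0
    d2 = _ds({"m": 2.0, "p": 0.02}, ["p"])  # same quantization band
    assert dataset_distance(d1, d2) == 0.0
    d3 = _ds({"m": 2.0, "p": 0.2}, ["p"])
    assert dataset_distance(d1, d3) == pytest.approx(2.0)  # |3 - 5|


def test_distance_mixed_hand_computed():
    d1 = _ds({"m": 1.0, "s": 0.5, "p": 0.004}, ["p"])
    d2 = _ds({"m": 3.0, "s": 0.0, "p": 0.2}, ["p"])
    expected = math.sqrt(2.0 ** 2 + 0.5 ** 2 + (5 - 2) ** 2)
    assert dataset_distance(d1, d2) == pytest.approx(expected)
    assert dataset_distance(d2, d1) == pytest.approx(expected)  # symmetry
    with pytest.raises(ValueError):
        dataset_distance(d1, _ds({"m": 1.0}, []))


# -- softplus-beta population -----------------------------------------------

def test_symmetric_when_d_zero():
    a, b = beta_shapes(1.3, 0.0)
    assert a == b
    assert softplus_exponent(0.0) == pytest.approx(math.log(2.0) - 1.0)


@pytest.mark.parametrize("s,d", [(0.0, 0.0), (2.0, 1.5), (1.0, -2.0), (-1.0, 0.5)])
def test_sampled_moments_match_quadrature(s, d):
    """10^5 samples against Gauss-Jacobi quadrature of the printed density.

    The Jacobi weight (1-x)^(b-1) (1+x)^(a-1) absorbs the density's edge
    singularities exactly, so the quadrature mean is an independent oracle
    even for shape parameters below one.
    """
    from scipy.special import roots_jacobi

    entry = ParamEntry("tau_h")
    lo, hi = entry.bounds
    pop = Population(BirdParameters(), [entry], s=[s], d=[d])
    a, b = beta_shapes(s, d)
    nodes, weights = roots_jacobi(80, b - 1.0, a - 1.0)
    z = (nodes + 1.0) / 2.0
    mean_z = float(np.sum(weights * z) / np.sum(weights))
    mean_q = lo + (hi - lo) * mean_z
    rng = random.Random(123)
    samples = np.array([entry.get(pop.sample_parameters(rng))
                        for _ in range(100_000)])
    assert samples.mean() == pytest.approx(mean_q, abs=0.01 * (hi - lo))
    assert pop.mean(entry) == pytest.approx(mean_q, abs=1e-9 * (hi - lo))
    assert samples.min() >= lo and samples.max() <= hi
    # the density itself is proper (mild case checked on a plain grid)
    if a >= 1.0 and b >= 1.0:
        grid = np.linspace(lo + 1e-9, hi - 1e-9, 20001)
        assert integrate.simpson(pop.density(entry, grid), x=grid) == \
            pytest.approx(1.0, abs=1e-3)
    assert samples.min() >= lo and samples.max() <= hi


def test_large_positive_d_shifts_mass_to_lower_bound():
    entry = ParamEntry("v_eat", "worm")
    base = BirdParameters(v_eat={"worm": 0.5})
    lo, hi = entry.bounds
    pop = Population(base, [entry], s=[1.0], d=[8.0])
    assert pop.mean(entry) < lo + 0.25 * (hi - lo)


# -- k-NN log-likelihood ----------------------------------------------------

def test_knn_normal_mode_small():
    """1-D standard normal, query at the mode; modest-K spot check."""
    rng = np.random.default_rng(0)
    ests = [knn_loglik_distances(np.abs(rng.standard_normal(4000)), 1, n=5)
            for _ in range(10)]
    assert np.mean(ests) == pytest.approx(-math.log(math.sqrt(2 * math.pi)),
                                          abs=0.1)


def test_knn_doubling_distances_log_linear():
    d = np.array([0.5, 1.0, 2.0, 3.0, 4.0, 5.0])
    dim = 3
    a = knn_loglik_distances(d, dim, n=4)
    b = knn_loglik_distances(2 * d, dim, n=4)
    assert a - b == pytest.approx(dim * math.log(2.0))


def test_knn_permutation_invariant_and_tie_floor():
    obs = _ds({"m": 0.0})
    sims = [_ds({"m": v}) for v in [3.0, 1.0, 2.0, 0.5, 4.0]]
    a = knn_loglik(obs, sims, n=2)
    b = knn_loglik(obs, list(reversed(sims)), n=2)
    assert a == b
    with pytest.warns(UserWarning):
        knn_loglik_distances([0.0, 0.0, 1.0], 1, n=2)
    with pytest.raises(ValueError):
        knn_loglik_distances([1.0], 1, n=5)


# -- reproducibility and the Bernoulli-rate note ----------------------------

def test_reproducibility_same_side_rule():
    assert reproducibility([[0.01]], [0.03]) == 1.0
    assert reproducibility([[0.2]], [0.01]) == 0.0
    # all listed tests must be reproduced simultaneously
    assert reproducibility([[0.01, 0.2]], [0.03, 0.01]) == 0.0
    assert reproducibility([[0.01], [0.3], [0.04], [0.2]], [0.001]) == 0.5
    with pytest.raises(ValueError):
        reproducibility([[0.01, 0.02]], [0.03])


def test_rate_difference_pvalue():
    p = rate_difference_pvalue(0.03, 1000)
    assert p <= 0.031
    assert p == pytest.approx(sps.norm.sf(0.03 / math.sqrt(0.25 / 1000)))
    assert rate_difference_pvalue(0.0, 1000) == pytest.approx(0.5)
    # 0.5 is the least favorable baseline
    for b in (0.1, 0.2, 0.35, 0.65, 0.9):
        assert rate_difference_pvalue(0.03, 1000, baseline=b) < p


# -- optimizer adapter -------------------------------------------------------

def test_cmaes_quadratic_convergence():
    target = np.array([1.5, -2.0, 0.5])

    def f(x):
        return float(np.sum((x - target) ** 2))

    x, fbest = minimize(f, np.zeros(3), 1.0, max_evals=2000, seed=4)
    assert np.allclose(x, target, atol=1e-3)
    assert fbest < 1e-6


def test_cmaes_rosenbrock_2d():
    def rosen(x):
        return float(100 * (x[1] - x[0] ** 2) ** 2 + (1 - x[0]) ** 2)

    x, fbest = minimize(rosen, np.array([-1.0, 1.0]), 0.5, max_evals=4000, seed=1)
    assert np.allclose(x, [1.0, 1.0], atol=1e-2)
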