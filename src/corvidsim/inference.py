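"""Population parametrization and likelihood-free fitting.

A model describes a *population* of birds: each bird parameter theta_i,
bounded to [l_i, u_i], is drawn from a rescaled beta density whose two
shape exponents derive from a location hyperparameter s_i and an asymmetry
hyperparameter d_i through the shifted softplus f(x) = log(exp(x) + 1) - 1:

    z ~ Beta with exponents (f(s), f(s+d))  if d < 0
                            (f(s-d), f(s))  if d >= 0
    theta = (u - l) z + l

(the beta shape parameters are the exponents + 1, always positive).  For
d > 0 the density of z gains mass near 0, i.e. theta shifts towards the
lower bound.

The likelihood of the observed summary tables under such a population is
intractable, so fitting is likelihood-free: simulate K independent groups,
summarize each like the real experiment, and score the hyperparameters by a
k-nearest-neighbor estimate of the log-likelihood of the observed summary.
Distances mix raw quantities (means, SEMs, counts) with a five-level
quantization of p-values.  Optimization uses CMA-ES with a simple adaptive
schedule for K.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from . import cmaes
from .parameters import BirdParameters, ParamEntry
from .protocol import SummaryDataset
from .simulator import run_population


# ---------------------------------------------------------------------------
# bounded softplus-beta population densities
# ---------------------------------------------------------------------------

def softplus_exponent(x: float) -> float:
    """f(x) = log(exp(x) + 1) - 1; the beta exponent (shape - 1)."""
    return float(np.logaddexp(0.0, x)) - 1.0


def beta_shapes(s: float, d: float) -> tuple[float, float]:
    """Beta shape parameters (a, b) induced by location s and asymmetry d."""
    if d < 0:
        return softplus_exponent(s) + 1.0, softplus_exponent(s + d) + 1.0
    return softplus_exponent(s - d) + 1.0, softplus_exponent(s) + 1.0


@dataclass
class Population:
    """A bird population: base parameters plus fitted entries with (s, d).

    Entries listed in ``space`` are resampled per bird from the softplus-beta
    density on their admissible range; all other parameters are taken from
    ``base`` unchanged (a point mass).
    """

    base: BirdParameters
    space: list[ParamEntry] = field(default_factory=list)
    s: np.ndarray = None
    d: np.ndarray = None
    variant: str = "plastic_caching"
    caching_variant: str = "hunger_modulated"

    def __post_init__(self) -> None:
        m = len(self.space)
        if self.s is None:
            self.s = np.zeros(m)
        if self.d is None:
            self.d = np.zeros(m)
        self.s = np.asarray(self.s, dtype=float)
        self.d = np.asarray(self.d, dtype=float)

    def with_hyperparameters(self, theta_vec) -> "Population":
        """New population with the stacked hyperparameter vector (d..., s...)."""
        m = len(self.space)
        vec = np.asarray(theta_vec, dtype=float)
        if vec.shape != (2 * m,):
            raise ValueError(f"expected vector of length {2 * m}")
        return Population(self.base, self.space, s=vec[m:], d=vec[:m],
                          variant=self.variant,
                          caching_variant=self.caching_variant)

    @property
    def hyperparameters(self) -> np.ndarray:
        return np.concatenate([self.d, self.s])

    def sample_parameters(self, rng: random.Random) -> BirdParameters:
        params = self.base.copy()
        for entry, s_i, d_i in zip(self.space, self.s, self.d):
            a, b = beta_shapes(s_i, d_i)
            z = rng.betavariate(a, b)
            lo, hi = entry.bounds
            entry.set(params, lo + (hi - lo) * z)
        return params

    def mean(self, entry: ParamEntry) -> float:
        """Analytic population mean of one fitted parameter."""
        i = self.space.index(entry)
        a, b = beta_shapes(self.s[i], self.d[i])
        lo, hi = entry.bounds
        return lo + (hi - lo) * a / (a + b)

    def density(self, entry: ParamEntry, theta_grid) -> np.ndarray:
        """Population density on the parameter's own scale."""
        i = self.space.index(entry)
        a, b = beta_shapes(self.s[i], self.d[i])
        lo, hi = entry.bounds
        z = (np.asarray(theta_grid) - lo) / (hi - lo)
        return sps.beta.pdf(z, a, b) / (hi - lo)


# ---------------------------------------------------------------------------
# distances and the k-NN log-likelihood
# ---------------------------------------------------------------------------

def quantize_p(p: float) -> int:
    """Five-level quantization of p-values (roughly log-scale, saturating)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return 1
    if p < 0.01:
        return 2
    if p < 0.05:
        return 3
    if p < 0.1:
        return 4
    return 5


def dataset_distance(d1: SummaryDataset, d2: SummaryDataset) -> float:
    """Euclidean distance mixing raw quantities and quantized p-values."""
    if set(d1.values) != set(d2.values) or d1.pvalue_names != d2.pvalue_names:
        raise ValueError("datasets must share their index sets")
    total = 0.0
    for name, x in d1.values.items():
        y = d2.values[name]
        if name in d1.pvalue_names:
            diff = quantize_p(y) - quantize_p(x)
        else:
            diff = y - x
        total += diff * diff
    return math.sqrt(total)


def log_unit_ball_volume(dim: int) -> float:
    return (dim / 2.0) * math.log(math.pi) - gammaln(dim / 2.0 + 1.0)


def knn_loglik_distances(distances, dim: int, n: int = 5,
                         floor: float = 1e-12) -> float:
    """k-NN log-density estimate at a query from distances to K samples.

    log p-hat = log(n/K) - log V_dim - dim * log Delta^(n), the standard
    k-nearest-neighbor density estimator; tie distances of zero are floored
    (with a warning) so the estimate stays finite.
    """
    dist = np.sort(np.asarray(distances, dtype=float))
    K = len(dist)
    if not 1 <= n <= K:
        raise ValueError("need K >= n >= 1")
    d_n = dist[n - 1]
    if d_n <= 0.0:
        import warnings

        warnings.warn("k-NN distance tie at zero; flooring", stacklevel=2)
        d_n = floor
    return math.log(n / K) - log_unit_ball_volume(dim) - dim * math.log(d_n)


def knn_loglik(observed: SummaryDataset, simulated: list[SummaryDataset],
               n: int = 5) -> float:
    """Approximate log-likelihood of one experiment's observed summary."""
    dists = [dataset_distance(observed, d) for d in simulated]
    dim = len(observed.values)
    return knn_loglik_distances(dists, dim, n=n)


def _dataset_matrix(datasets: list[SummaryDataset]) -> np.ndarray:
    """Stack datasets into rows with p-value entries quantized.

    On this representation the mixed distance of two datasets is plain
    Euclidean, which lets replicated-observation likelihoods use one
    vectorized distance matrix.
    """
    first = datasets[0]
    names = sorted(first.values)
    pnames = first.pvalue_names
    rows = np.empty((len(datasets), len(names)))
    for i, ds in enumerate(datasets):
        if set(ds.values) != set(names) or ds.pvalue_names != pnames:
            raise ValueError("datasets must share their index sets")
        rows[i] = [quantize_p(ds.values[n]) if n in pnames else ds.values[n]
                   for n in names]
    return rows


def knn_loglik_replicated(observed: list[SummaryDataset],
                          simulated: list[SummaryDataset], n: int = 5,
                          floor: float = 1e-12) -> float:
    """Summed k-NN log-likelihood of many observed replications.

    Treats each observed dataset as an independent replication of the same
    experiment and sums the k-NN estimates of their log-densities under the
    simulated sample -- the replicated-data analogue of :func:`knn_loglik`,
    evaluated with one vectorized distance matrix.
    """
    from scipy.spatial.distance import cdist

    obs = _dataset_matrix(observed)
    sim = _dataset_matrix(simulated)
    K = len(simulated)
    if not 1 <= n <= K:
        raise ValueError("need K >= n >= 1")
    dim = obs.shape[1]
    dmat = cdist(obs, sim)
    d_n = np.partition(dmat, n - 1, axis=1)[:, n - 1]
    if np.any(d_n <= 0.0):
        import warnings

        warnings.warn("k-NN distance tie at zero; flooring", stacklevel=2)
        d_n = np.maximum(d_n, floor)
    const = math.log(n / K) - log_unit_ball_volume(dim)
    return float(np.sum(const - dim * np.log(d_n)))


# ---------------------------------------------------------------------------
# reproducibility scoring
# ---------------------------------------------------------------------------

def reproducibility(simulated_pvalue_sets, experimental_pvalues) -> float:
    """Fraction of simulated repetitions reproducing all relevant tests.

    A test is reproduced when simulated and experimental p-values fall on
    the same side of 0.05; a repetition reproduces the experiment when all
    its tests do so simultaneously.
    """
    exp_sig = [p < 0.05 for p in experimental_pvalues]
    n_rep = 0
    for sim_ps in simulated_pvalue_sets:
        if len(sim_ps) != len(exp_sig):
            raise ValueError("test lists must be aligned")
        if all((p < 0.05) == sig for p, sig in zip(sim_ps, exp_sig)):
            n_rep += 1
    return n_rep / len(simulated_pvalue_sets)


def rate_difference_pvalue(rate_difference: float, trials: int,
                           baseline: float = 0.5) -> float:
    """One-sided p-value of an excess over a Bernoulli baseline rate.

    Normal approximation of a one-sample proportion test at the given trial
    count; baseline 0.5 is the least favorable (largest variance) choice.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0.0 <= rate_difference <= 1.0:
        raise ValueError("rate difference must be in [0, 1]")
    se = math.sqrt(baseline * (1.0 - baseline) / trials)
    if se == 0.0:
        return 0.0 if rate_difference > 0 else 0.5
    return float(sps.norm.sf(rate_difference / se))


# ---------------------------------------------------------------------------
# CMA-ES fitting with adaptive simulation count
# ---------------------------------------------------------------------------

@dataclass
class FitPhase:
    """One optimization phase: evaluation budget, pinned K, step size."""

    evals: int
    k: int
    sigma0: float
    popsize: int | None = None


@dataclass
class FitConfig:
    budget_evals: int = 2000
    sigma0: float = 1.0
    popsize: int | None = None
    n_neighbor: int = 5
    k_min: int = 5
    k_max: int = 500
    k_init: int = 8
    n_per_group: int | dict | None = None
    final_evaluations: int = 2  # averaged log p-hat reported with SEM
    #: optional multi-phase schedule (e.g. localize at small K, then refine
    #: at large K where the objective's shallow directions gain a reliable
    #: slope); overrides budget_evals/k_*/sigma0/popsize when set
    schedule: list[FitPhase] | None = None


@dataclass
class FitResult:
    population: Population
    loglik_trace: list
    k_schedule: list
    seeds: dict
    final_loglik: float = math.nan
    final_loglik_sem: float = math.nan

    def to_json(self) -> str:
        pop = self.population
        return json.dumps({
            "variant": pop.variant,
            "caching_variant": pop.caching_variant,
            "space": [e.label for e in pop.space],
            "bounds": [list(e.bounds) for e in pop.space],
            "d": list(map(float, pop.d)),
            "s": list(map(float, pop.s)),
            "population_means": {e.label: pop.mean(e) for e in pop.space},
            "loglik_trace": self.loglik_trace,
            "k_schedule": self.k_schedule,
            "seeds": self.seeds,
            "final_loglik": self.final_loglik,
            "final_loglik_sem": self.final_loglik_sem,
        }, indent=1)


def _objective(population, fits, K, seed, n_neighbor, n_per_group):
    """Negative summed k-NN log-likelihood over (protocol, observed) pairs.

    ``seed`` pins the simulation randomness: candidates evaluated with the
    same seed share their random numbers, which cancels most of the
    evaluation noise in within-generation comparisons.  ``observed`` may be
    a single summary dataset or a list of replications of the experiment.
    """
    total = 0.0
    for j, (protocol, observed) in enumerate(fits):
        sims = run_population(protocol, population, K, (seed + j) % 2 ** 31,
                              n_per_group=n_per_group)
        if isinstance(observed, (list, tuple)):
            total += knn_loglik_replicated(observed, sims,
                                           n=min(n_neighbor, K))
        else:
            total += knn_loglik(observed, sims, n=min(n_neighbor, K))
    return -total


def fit(population: Population, fits: list[tuple], seed: int,
        config: FitConfig | None = None, verbose: bool = False) -> FitResult:
    """Maximize the approximate log-likelihood over the (d, s) hyperparameters.

    ``fits`` is a list of (protocol, observed SummaryDataset) pairs sharing
    one hyperparameter vector (joint fits are the same call with several
    pairs).  K starts small and grows whenever the generation's candidate
    ranking looks unstable (best re-evaluation disagrees), within
    [k_min, k_max]; non-finite objective values reject the candidate.
    """
    cfg = config or FitConfig()
    rng = random.Random(seed)
    trace, k_sched = [], []
    vec = population.hyperparameters
    if cfg.schedule:
        phases = [(p.evals, p.k, p.k, p.k, p.sigma0, p.popsize)
                  for p in cfg.schedule]
    else:
        phases = [(cfg.budget_evals, cfg.k_init, cfg.k_min, cfg.k_max,
                   cfg.sigma0, cfg.popsize)]
    for budget, k_init, k_min, k_max, sigma0, popsize in phases:
        es = cmaes.CMAES(vec, sigma0, seed=rng.randrange(2 ** 31),
                         popsize=popsize)
        K = k_init
        evals = 0
        while evals < budget:
            xs = es.ask()
            gen_seed = rng.randrange(2 ** 31)  # common random numbers
            fs = []
            for x in xs:
                pop = population.with_hyperparameters(x)
                val = _objective(pop, fits, K, gen_seed, cfg.n_neighbor,
                                 cfg.n_per_group)
                if not math.isfinite(val):
                    val = 1e6  # rejected candidate
                fs.append(val)
                evals += 1
            es.tell(xs, fs)
            gen_best = int(np.argmin(fs))
            if k_min == k_max:
                # K pinned: spend the whole budget on search
                score = fs[gen_best]
            else:
                # noise handling: re-evaluate the generation's best on fresh
                # randomness; K grows when the re-evaluation no longer ranks
                # in the better half of the generation, shrinks slowly else
                reval = _objective(
                    population.with_hyperparameters(xs[gen_best]), fits, K,
                    rng.randrange(2 ** 31), cfg.n_neighbor, cfg.n_per_group)
                evals += 1
                if reval > float(np.quantile(fs, 0.75)):
                    K = min(k_max, max(K + 1, int(K * 1.25)))
                else:
                    K = max(k_min, int(K * 0.97))
                score = 0.5 * (fs[gen_best] + reval)
            trace.append(-score)
            k_sched.append(K)
            if verbose:
                print(f"evals={evals} K={K} loglik={-score:.3f}")
        # carry the recombination mean into the next phase: under an
        # objective this stochastic it is stabler than the running best
        vec = es.mean.copy()
    fitted = population.with_hyperparameters(vec)
    finals = [-_objective(fitted, fits, max(K * 2, 32),
                          rng.randrange(2 ** 31), cfg.n_neighbor,
                          cfg.n_per_group)
              for _ in range(cfg.final_evaluations)]
    return FitResult(
        population=fitted,
        loglik_trace=trace,
        k_schedule=k_sched,
        seeds={"fit": seed},
        final_loglik=float(np.mean(finals)),
        final_loglik_sem=float(sps.sem(finals)) if len(finals) > 1 else math.nan,
    )
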