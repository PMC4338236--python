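"""Rejection-ABC inference of the adaptive mutation rate and Bayes factors.

A candidate sweep is summarized by the pair (H12, H2/H1) observed in its
highest-H12 window.  The posterior of the population-scaled adaptive
mutation rate theta_A = 4 N_e mu_A is sampled by drawing nuisance parameters
(s, PF, T_E) and theta_A from uniform priors, simulating a sweep for each
draw, and accepting draws whose simulated summary lies within a normalized
distance of 0.1 of the observation:

    d_i = sqrt( (H12_obs - H12_i)^2 / Var(H12)
              + (H2/H1_obs - H2/H1_i)^2 / Var(H2/H1) )

with the variances estimated from all simulations of the run.  The MAP
estimate is the mode of a Gaussian kernel density over the accepted draws;
the credible interval is the 2.5th-97.5th percentile range.

Bayes factors compare point hypotheses: BF = (# soft-sweep simulations
within the distance radius) / (# hard-sweep simulations within the radius),
with hard sweeps generated at theta_A = 0.01 and soft sweeps at theta_A of
5, 10, 50, or the inferred MAP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import gaussian_kde

from hapsweep.scan import WINDOW_SIZE
from hapsweep.sweepsim import SweepLossError, SweepModel, simulate

__all__ = [
    "AbcConfig",
    "AbcPosterior",
    "BayesFactor",
    "BayesFactorGrid",
    "accept_distance",
    "sample_posterior",
    "posterior_from_table",
    "posterior_nearest",
    "map_estimate",
    "bayes_factor",
    "bf_grid",
    "make_sweep_simulator",
    "simulate_reference_table",
]

#: Recombination-rate bins (cM/bp) used to integrate out local rate
#: uncertainty; a draw samples the rate uniformly within the chosen bin.
RHO_BINS = (
    (5.42e-7, 1.61e-6),
    (1.61e-6, 2.68e-6),
    (2.68e-6, 3.74e-6),
    (3.74e-6, 4.81e-6),
    (4.81e-6, 5.88e-6),
)


@dataclass(frozen=True)
class AbcConfig:
    """Priors and acceptance rule for one ABC run.

    Priors are uniform: theta_A on ``theta_a_range``, s on ``s_range``, PF
    on ``pf_range`` and T_E on ``t_e_range`` (units of 4 N_e generations).
    ``rho_bin`` picks one of :data:`RHO_BINS`, or ``None`` to hold the base
    model's rate fixed.  ``relative_rule=True`` switches the acceptance rule
    from the normalized distance to a per-component "within 10%" comparison.
    """

    theta_a_range: tuple[float, float] = (0.0, 100.0)
    s_range: tuple[float, float] = (0.0, 1.0)
    pf_range: tuple[float, float] = (0.0, 1.0)
    t_e_range: tuple[float, float] = (0.0, 0.001)
    rho_bin: int | None = None
    target_acceptances: int = 1000
    max_simulations: int = 100_000
    radius: float = 0.1
    relative_rule: bool = False
    batch_size: int = 200


@dataclass
class AbcPosterior:
    """Accepted theta_A draws with MAP and credible interval."""

    draws: np.ndarray
    theta_a_map: float
    ci_low: float
    ci_high: float
    acceptance_rate: float
    n_simulations: int


@dataclass(frozen=True)
class BayesFactor:
    """Soft-vs-hard evidence for one (H12, H2/H1) observation.

    ``lower_bound`` flags the zero-hard-count convention: no hard simulation
    fell within the radius, so ``bf`` (reported as the soft count) is only a
    lower bound.  ``undefined`` flags the no-counts-at-all case.
    """

    bf: float
    n_soft: int
    n_hard: int
    lower_bound: bool = False
    undefined: bool = False


@dataclass
class BayesFactorGrid:
    h12_edges: np.ndarray
    h2h1_edges: np.ndarray
    bf: np.ndarray  # (n_h12_cells, n_h2h1_cells)
    n_soft: np.ndarray
    n_hard: np.ndarray
    flagged: np.ndarray  # undefined or lower-bound cells


def accept_distance(
    obs: tuple[float, float],
    sim: tuple[float, float],
    var_h12: float,
    var_h2h1: float,
) -> float:
    """Variance-normalized Euclidean distance between summary pairs."""
    if var_h12 <= 0 or var_h2h1 <= 0:
        raise ValueError("summary variances must be positive")
    return float(
        np.sqrt(
            (obs[0] - sim[0]) ** 2 / var_h12 + (obs[1] - sim[1]) ** 2 / var_h2h1
        )
    )


def _distances(obs: np.ndarray, sims: np.ndarray) -> np.ndarray:
    """Normalized distances of each row of ``sims`` from ``obs``.

    Variances are estimated from all rows of ``sims``.  A degenerate
    component with zero variance contributes 0 where the simulated value
    equals the observation and infinity otherwise (so a simulator that
    reproduces the observation exactly accepts everything, and one stuck
    elsewhere accepts nothing).
    """
    var = sims.var(axis=0, ddof=1)
    diff2 = (sims - obs[None, :]) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = diff2 / var[None, :]
    d2[diff2 == 0] = 0.0
    d2[(diff2 > 0) & (var[None, :] == 0).repeat(sims.shape[0], axis=0)] = np.inf
    return np.sqrt(d2.sum(axis=1))


def map_estimate(
    draws: np.ndarray,
    support: tuple[float, float] = (0.0, 100.0),
    grid_points: int = 512,
) -> tuple[float, tuple[float, float]]:
    """MAP and 95% credible interval from accepted posterior draws.

    The MAP is the argmax over a ``grid_points``-point grid on the prior
    support of a Gaussian kernel density (Silverman bandwidth); the interval
    is the empirical 2.5th-97.5th percentile range.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 30:
        raise ValueError(f"need >= 30 draws for a density estimate, got {draws.size}")
    grid = np.linspace(support[0], support[1], grid_points)
    if np.ptp(draws) < 1e-12:  # point mass; KDE is singular
        mode = float(draws.mean())
    else:
        kde = gaussian_kde(draws, bw_method="silverman")
        mode = float(grid[int(np.argmax(kde(grid)))])
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return mode, (float(lo), float(hi))


def make_sweep_simulator(
    base_model: SweepModel, min_snps: int = WINDOW_SIZE, max_restarts: int = 3
) -> Callable:
    """Build the default simulator: a de novo sweep under ``base_model``
    with (theta_a, s, pf, t_e, rho) overridden per draw, summarized by
    (H12, H2/H1) on the central analysis window.

    ``max_restarts`` is kept small so that parameter draws that cannot
    yield enough SNPs (e.g. strong complete sweeps on a short locus) fail
    fast and are redrawn from the prior, mirroring the discard-and-redraw
    treatment of sub-400-SNP samples.
    """
    from dataclasses import replace

    from hapsweep.hapstats import window_stats

    def sim(theta_a, s, pf, t_e, rho_cm_per_bp, seed):
        model = replace(
            base_model,
            mode="de_novo",
            theta_a=theta_a,
            s=s,
            pf=pf,
            t_e=t_e,
            rho_cm_per_bp=rho_cm_per_bp,
        )
        sample = simulate(model, seed=seed, min_snps=min_snps, max_restarts=max_restarts)
        alleles = sample.matrix.alleles
        start = (alleles.shape[1] - min_snps) // 2
        stats = window_stats(
            alleles, start, min_snps, np.random.default_rng(seed)
        )
        return stats.h12, stats.h2_h1

    return sim


def simulate_reference_table(
    config: AbcConfig,
    simulator: Callable,
    n: int,
    seed: int,
    base_rho: float = 5e-7,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` parameter vectors from the priors and simulate each.

    Returns ``(params, summaries)`` where params columns are
    (theta_a, s, pf, t_e) and summaries columns are (h12, h2_h1).  Draws
    whose simulation fails (e.g. a lost sweep at tiny s) are redrawn.
    """
    rng = np.random.default_rng(seed)
    params = np.empty((n, 4))
    sums = np.empty((n, 2))
    i = 0
    failures = 0
    while i < n:
        theta_a = rng.uniform(*config.theta_a_range)
        s = rng.uniform(*config.s_range)
        pf = rng.uniform(*config.pf_range)
        t_e = rng.uniform(*config.t_e_range)
        if config.rho_bin is not None:
            rho = rng.uniform(*RHO_BINS[config.rho_bin])
        else:
            rho = base_rho
        try:
            h12, h2h1 = simulator(
                theta_a, s, pf, t_e, rho, int(rng.integers(1, 2**31 - 1))
            )
        except (SweepLossError, ValueError):
            failures += 1
            if failures > 10 * n + 100:
                raise SweepLossError("too many failed simulations in ABC run")
            continue
        params[i] = (theta_a, s, pf, t_e)
        sums[i] = (h12, h2h1)
        i += 1
    return params, sums


def posterior_from_table(
    obs: tuple[float, float],
    params: np.ndarray,
    summaries: np.ndarray,
    radius: float = 0.1,
    relative_rule: bool = False,
    support: tuple[float, float] = (0.0, 100.0),
) -> AbcPosterior:
    """Rejection step on a precomputed reference table."""
    obs_arr = np.asarray(obs, dtype=float)
    if relative_rule:
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(summaries - obs_arr[None, :]) / np.abs(obs_arr[None, :])
        accept = (rel <= radius).all(axis=1)
    else:
        accept = _distances(obs_arr, summaries) < radius
    draws = params[accept, 0]
    mode, (lo, hi) = map_estimate(draws, support=support)
    return AbcPosterior(
        draws=draws,
        theta_a_map=mode,
        ci_low=lo,
        ci_high=hi,
        acceptance_rate=float(accept.mean()),
        n_simulations=int(summaries.shape[0]),
    )


def posterior_nearest(
    obs: tuple[float, float],
    params: np.ndarray,
    summaries: np.ndarray,
    k: int = 100,
    support: tuple[float, float] = (0.0, 100.0),
) -> AbcPosterior:
    """Quantile-based rejection: keep the ``k`` draws nearest to ``obs``.

    The fixed-radius rule needs very large reference tables when the
    observation falls in a low prior-predictive-density region; accepting
    the nearest ``k`` draws is the standard small-budget variant of
    rejection ABC (the tolerance adapts to the local density).
    """
    obs_arr = np.asarray(obs, dtype=float)
    d = _distances(obs_arr, np.asarray(summaries, dtype=float))
    nearest = np.argsort(d, kind="stable")[:k]
    draws = np.asarray(params)[nearest, 0]
    mode, (lo, hi) = map_estimate(draws, support=support)
    return AbcPosterior(
        draws=draws,
        theta_a_map=mode,
        ci_low=lo,
        ci_high=hi,
        acceptance_rate=k / summaries.shape[0],
        n_simulations=int(summaries.shape[0]),
    )


def sample_posterior(
    obs: tuple[float, float],
    config: AbcConfig,
    simulator: Callable,
    seed: int,
    base_rho: float = 5e-7,
) -> AbcPosterior:
    """Sample the theta_A posterior for one observed (H12, H2/H1) pair.

    Simulates in batches, re-evaluating acceptances against variances
    estimated from all simulations so far, until ``target_acceptances``
    accepted draws are found or ``max_simulations`` is exhausted (then a
    :class:`BudgetExceededError` carrying partial results is raised).
    """
    if not (0 <= obs[0] <= 1 and 0 <= obs[1] <= 1):
        raise ValueError("observed summaries must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    all_params = []
    all_sums = []
    n_done = 0
    while n_done < config.max_simulations:
        batch = min(config.batch_size, config.max_simulations - n_done)
        p, s = simulate_reference_table(
            config, simulator, batch, int(rng.integers(1, 2**31 - 1)), base_rho
        )
        all_params.append(p)
        all_sums.append(s)
        n_done += batch
        params = np.concatenate(all_params)
        sums = np.concatenate(all_sums)
        try:
            post = posterior_from_table(
                obs,
                params,
                sums,
                radius=config.radius,
                relative_rule=config.relative_rule,
                support=config.theta_a_range,
            )
        except ValueError:  # not enough accepted draws yet
            continue
        if post.draws.size >= config.target_acceptances:
            return post
    raise BudgetExceededError(
        obs=obs,
        n_simulations=n_done,
        n_accepted=int(post.draws.size) if "post" in locals() else 0,
    )


class BudgetExceededError(RuntimeError):
    """ABC ran out of simulation budget before reaching the target."""

    def __init__(self, obs, n_simulations, n_accepted):
        self.obs = obs
        self.n_simulations = n_simulations
        self.n_accepted = n_accepted
        super().__init__(
            f"accepted {n_accepted} draws in {n_simulations} simulations "
            f"for obs={obs}"
        )


def bayes_factor(
    obs: tuple[float, float],
    hard_sims: np.ndarray,
    soft_sims: np.ndarray,
    radius: float = 0.1,
) -> BayesFactor:
    """Soft-vs-hard Bayes factor by counting simulations near ``obs``.

    Distances are normalized by summary variances pooled over both
    simulation sets.  A zero hard count yields a flagged lower bound
    (``bf = n_soft``); zero counts in both sets yield an undefined flag.
    """
    hard = np.asarray(hard_sims, dtype=float)
    soft = np.asarray(soft_sims, dtype=float)
    if hard.size == 0 or soft.size == 0:
        raise ValueError("both simulation sets must be non-empty")
    pooled = np.concatenate([hard, soft])
    obs_arr = np.asarray(obs, dtype=float)
    d = _distances(obs_arr, pooled)
    n_hard = int((d[: hard.shape[0]] < radius).sum())
    n_soft = int((d[hard.shape[0] :] < radius).sum())
    if n_hard == 0 and n_soft == 0:
        return BayesFactor(bf=float("nan"), n_soft=0, n_hard=0, undefined=True)
    if n_hard == 0:
        return BayesFactor(bf=float(n_soft), n_soft=n_soft, n_hard=0, lower_bound=True)
    return BayesFactor(bf=n_soft / n_hard, n_soft=n_soft, n_hard=n_hard)


def bf_grid(
    hard_sims: np.ndarray,
    soft_sims: np.ndarray,
    h12_edges: np.ndarray | None = None,
    h2h1_edges: np.ndarray | None = None,
    radius: float = 0.1,
) -> BayesFactorGrid:
    """Bayes factors over a grid of (H12, H2/H1) cell centers."""
    if h12_edges is None:
        h12_edges = np.linspace(0.0, 1.0, 11)
    if h2h1_edges is None:
        h2h1_edges = np.linspace(0.0, 1.0, 11)
    h12_edges = np.asarray(h12_edges, dtype=float)
    h2h1_edges = np.asarray(h2h1_edges, dtype=float)
    nx, ny = h12_edges.size - 1, h2h1_edges.size - 1
    bf = np.full((nx, ny), np.nan)
    n_soft = np.zeros((nx, ny), dtype=int)
    n_hard = np.zeros((nx, ny), dtype=int)
    flagged = np.zeros((nx, ny), dtype=bool)
    for i in range(nx):
        x = 0.5 * (h12_edges[i] + h12_edges[i + 1])
        for j in range(ny):
            y = 0.5 * (h2h1_edges[j] + h2h1_edges[j + 1])
            res = bayes_factor((x, y), hard_sims, soft_sims, radius=radius)
            bf[i, j] = res.bf
            n_soft[i, j] = res.n_soft
            n_hard[i, j] = res.n_hard
            flagged[i, j] = res.lower_bound or res.undefined
    return BayesFactorGrid(
        h12_edges=h12_edges,
        h2h1_edges=h2h1_edges,
        bf=bf,
        n_soft=n_soft,
        n_hard=n_hard,
        flagged=flagged,
    )
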