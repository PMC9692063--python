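"""Hierarchical Gibbs ABC for individual differences in cue-based retrieval.

The estimation problem: each participant j contributes a pair of observed
summary statistics y_j = (mean reading time, facilitatory interference
effect), assumed generated by the LV05 retrieval model at that participant's
latency factor LF_j and cue-weighting ratio CW_j.  The (LF_j, CW_j) pairs
come from a bivariate normal population with means (mu_LF, mu_CW), SDs
(sigma_LF, sigma_CW) and correlation rho, giving 2n + 5 model parameters
plus one global nuisance offset.

The model's likelihood is intractable, so individual-level updates use
approximate Bayesian computation: a proposal's likelihood is replaced by the
average, over ``n_sim`` forward simulations, of a Gaussian kernel in the
distance between simulated and observed summaries, with tolerance delta per
component.  Population-level parameters are then drawn exactly from their
normal-inverse-Wishart conjugate conditional given the current individual
parameters (Gibbs ABC in the style of Turner & Van Zandt).

A scalar non-retrieval offset ``tbase`` (ms) absorbs lexical, encoding and
motor time shared by all participants: the observed mean RT is compared to
``simulated mean RT + tbase``.  Without it, mean reading times would force
the latency factor to absorb stage durations the retrieval model does not
describe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .retrieval import (
    CONDITIONS,
    ConditionSchedule,
    LV05Config,
    ParticipantParams,
    mean_activations,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NIWPrior",
    "NormalPrior",
    "ABCConfig",
    "PosteriorChains",
    "kernel_weight",
    "simulate_summaries_batch",
    "abc_weight_estimate",
    "update_individual",
    "update_population",
    "run_gibbs_abc",
    "summarize_posterior",
    "run_abc_mh",
    "CueRetrievalABC",
    "CueRetrievalABCResults",
]

POPULATION_PARAMS = ("mu_LF", "mu_CW", "sigma_LF", "sigma_CW", "rho")

_COND_MATCH = {c: ConditionSchedule.for_condition(c).match_matrix for c in CONDITIONS}


class ToleranceError(RuntimeError):
    """Every ABC weight in a full sweep vanished: the tolerance is too
    small for the data/model distances at hand; increase delta."""


@dataclass(frozen=True)
class NIWPrior:
    """Normal-inverse-Wishart prior for the (LF, CW) population.

    mu0 is the prior location, kappa0 the prior strength on the mean, nu0
    the inverse-Wishart degrees of freedom and ``scale`` its 2x2 scale
    matrix.  The default is weakly informative on the empirically plausible
    range: latency factors of a few hundred ms and cue weightings between 1
    and about 4.
    """

    mu0: tuple[float, float] = (0.2, 1.5)
    kappa0: float = 1.0
    nu0: float = 4.0
    scale: tuple[tuple[float, float], tuple[float, float]] = ((0.01**2, 0.0), (0.0, 0.75**2))

    def __post_init__(self) -> None:
        dim = 2
        if self.nu0 <= dim - 1:
            raise ValueError(f"nu0 must exceed dim - 1 = {dim - 1}, got {self.nu0}")
        if self.kappa0 <= 0:
            raise ValueError(f"kappa0 must be > 0, got {self.kappa0}")
        s = np.asarray(self.scale, dtype=float)
        if s.shape != (2, 2) or not np.allclose(s, s.T):
            raise ValueError("scale must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(s).min() < 0:
            raise ValueError("scale matrix must be positive semi-definite")

    @property
    def mu0_arr(self) -> np.ndarray:
        return np.asarray(self.mu0, dtype=float)

    @property
    def scale_arr(self) -> np.ndarray:
        return np.asarray(self.scale, dtype=float)


@dataclass(frozen=True)
class NormalPrior:
    mean: float = 0.0
    sd: float = 50.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"prior sd must be > 0, got {self.sd}")


@dataclass(frozen=True)
class ABCConfig:
    """Sampler settings for the hierarchical Gibbs ABC run.

    delta_rt_ms / delta_eff_ms : kernel tolerances for the two summary
        components.  The tolerance acts as the effective measurement-noise
        scale of the approximate likelihood, so both default to 5 ms — the
        typical posterior SE of shrunken per-participant estimates; a
        tolerance much larger than the data noise washes out population
        spread (see docs/methods.md).
    n_sim : forward simulations averaged per likelihood-weight evaluation.
    n_trials_sim : Monte-Carlo races per condition inside each forward
        simulation (controls the model-side noise the kernel integrates
        over).
    iterations, burnin, thin : sampler schedule; proposal scales are adapted
        toward 20-40% acceptance during burn-in only and frozen afterwards.
    proposal_sd_* : initial random-walk SDs.
    prior_pop : NIW hyperprior for the population; prior_tbase : Normal
        prior for the global non-retrieval offset (ms).
    """

    delta_rt_ms: float = 5.0
    delta_eff_ms: float = 5.0
    n_sim: int = 24
    n_trials_sim: int = 128
    iterations: int = 4000
    burnin: int = 1000
    thin: int = 1
    proposal_sd_lf: float = 0.02
    proposal_sd_cw: float = 0.2
    proposal_sd_tbase: float = 5.0
    adapt_interval: int = 100
    prior_pop: NIWPrior = field(default_factory=NIWPrior)
    prior_tbase: NormalPrior = field(default_factory=NormalPrior)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_rt_ms <= 0 or self.delta_eff_ms <= 0:
            raise ValueError("all tolerance components must be > 0")
        if self.n_sim < 1:
            raise ValueError(f"n_sim must be >= 1, got {self.n_sim}")
        if self.n_trials_sim < 1:
            raise ValueError(f"n_trials_sim must be >= 1, got {self.n_trials_sim}")
        if not self.iterations > self.burnin >= 0:
            raise ValueError(
                f"need iterations > burnin >= 0, got {self.iterations}, {self.burnin}"
            )
        if self.thin < 1:
            raise ValueError(f"thin must be >= 1, got {self.thin}")

    def replace(self, **kwargs) -> "ABCConfig":
        return replace(self, **kwargs)

    @property
    def delta(self) -> np.ndarray:
        return np.array([self.delta_rt_ms, self.delta_eff_ms])


def kernel_weight(distance, delta):
    """Gaussian ABC kernel exp(-d^2 / (2 delta^2)).

    Equals 1 at zero distance and decreases strictly with distance;
    vectorized over ``distance``.
    """
    distance = np.asarray(distance, dtype=float)
    if np.any(distance < 0):
        raise ValueError("distance must be non-negative")
    if np.any(np.asarray(delta) <= 0):
        raise ValueError("tolerance delta must be > 0")
    return np.exp(-(distance**2) / (2.0 * np.asarray(delta, dtype=float) ** 2))


def simulate_summaries_batch(
    LF: float,
    CW: float,
    config: LV05Config,
    n_sim: int,
    n_trials: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """``n_sim`` independent forward simulations of the per-participant
    summary pair, each from ``n_trials`` races per condition.

    Returns an (n_sim, 2) array of (mean_rt_ms, effect_ms) rows.  Ties in
    the race go to the target, which leaves the latency unchanged.
    """
    cond_means = np.empty((2, n_sim))
    for c, cond in enumerate(CONDITIONS):
        a = mean_activations(CW, config, ConditionSchedule.for_condition(cond))
        A = a + config.sigma * rng.standard_normal((n_sim, n_trials, 2))
        A_win = A.max(axis=2)
        rt_ms = LF * config.ms_per_second * np.exp(-config.f * A_win)
        cond_means[c] = rt_ms.mean(axis=1)
    out = np.empty((n_sim, 2))
    out[:, 0] = 0.5 * (cond_means[0] + cond_means[1])
    out[:, 1] = cond_means[0] - cond_means[1]  # multiple_match - single_match
    return out


def _simulate_summaries_all(
    LF: np.ndarray,
    CW: np.ndarray,
    config: LV05Config,
    n_sim: int,
    n_trials: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized forward simulation for all participants at once.

    Returns (n, n_sim, 2) of (mean_rt_ms, effect_ms).  Same model as
    :func:`simulate_summaries_batch`; participants are batched because the
    per-participant MH steps are conditionally independent given the
    population parameters and tbase.
    """
    n = LF.shape[0]
    w_n = config.W_total / (1.0 + CW)
    w_s = config.W_total - w_n
    cond_means = np.empty((2, n, n_sim))
    for c, cond in enumerate(CONDITIONS):
        match = _COND_MATCH[cond]
        a = config.B_base + config.S_assoc * (
            np.stack([w_s, w_n], axis=1) @ match.T
        )  # (n, 2 chunks)
        A = a[:, None, None, :] + config.sigma * rng.standard_normal((n, n_sim, n_trials, 2))
        rt_ms = np.exp(-config.f * A.max(axis=3))
        rt_ms *= (LF * config.ms_per_second)[:, None, None]
        cond_means[c] = rt_ms.mean(axis=2)
    out = np.empty((n, n_sim, 2))
    out[..., 0] = 0.5 * (cond_means[0] + cond_means[1])
    out[..., 1] = cond_means[0] - cond_means[1]
    return out


def _weight_from_sims(sims: np.ndarray, obs: np.ndarray, tbase: float, delta: np.ndarray):
    """Kernel-weighted approximate likelihood from cached simulations.

    ``sims`` is (n_sim, 2) raw model output; the observed mean RT is
    compared against the simulated mean RT shifted by ``tbase``.
    Vectorized: ``sims`` may also be (n, n_sim, 2) with ``obs`` (n, 2),
    returning one weight per participant.
    """
    shifted = sims + np.array([tbase, 0.0])
    dist = np.abs(shifted - obs[..., None, :])
    w = np.exp(-(dist**2) / (2.0 * delta**2)).prod(axis=-1)
    return w.mean(axis=-1)


def abc_weight_estimate(
    theta_j: ParticipantParams,
    y_j,
    config: LV05Config,
    abc: ABCConfig,
    tbase: float,
    seed,
) -> float:
    """Approximate likelihood weight of one participant's parameters.

    Averages, over ``abc.n_sim`` forward simulations, the product of the
    per-component Gaussian kernel weights for |sim_mean_rt + tbase -
    obs_mean_rt| and |sim_effect - obs_effect|.  Lies in [0, 1] and is 1
    when a noise-free model reproduces the observation exactly.
    """
    rng = np.random.default_rng(seed)
    sims = simulate_summaries_batch(
        theta_j.LF, theta_j.CW, config, abc.n_sim, abc.n_trials_sim, rng
    )
    obs = np.array([float(y_j["mean_rt_ms"]), float(y_j["effect_ms"])])
    return float(_weight_from_sims(sims, obs, tbase, abc.delta))


def _bvn_chol(pop) -> tuple[np.ndarray, np.ndarray, float]:
    cov = pop.cov
    chol = np.linalg.cholesky(cov)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return np.asarray(pop.mean), chol, logdet


def _bvn_logpdf(x: np.ndarray, mean: np.ndarray, chol: np.ndarray, logdet: float) -> float:
    u = np.linalg.solve(chol, x - mean)
    return float(-0.5 * (u @ u) - 0.5 * logdet - np.log(2.0 * np.pi))


def _log_weight_ratio(w_new: float, w_cur: float) -> tuple[float, bool]:
    """Log of w_new / w_cur with the documented 0/0 convention.

    A 0/0 ratio is treated as 1 (the event is reported to the caller so it
    can be logged); 0/positive is -inf, positive/0 is +inf.
    """
    if w_new == 0.0 and w_cur == 0.0:
        return 0.0, True
    if w_new == 0.0:
        return -np.inf, False
    if w_cur == 0.0:
        return np.inf, False
    return float(np.log(w_new) - np.log(w_cur)), False


@dataclass
class IndividualUpdate:
    theta: ParticipantParams
    accepted: bool
    weight: float
    sims: np.ndarray
    zero_zero: bool = False


def _update_individual_state(
    theta: np.ndarray,
    weight: float,
    sims: np.ndarray,
    obs: np.ndarray,
    pop_mean: np.ndarray,
    pop_chol: np.ndarray,
    pop_logdet: float,
    tbase: float,
    config: LV05Config,
    abc: ABCConfig,
    scales: np.ndarray,
    rng: np.random.Generator,
):
    """One MH step on (LF_j, CW_j); returns updated state pieces."""
    prop = theta + scales * rng.standard_normal(2)
    if not (prop[0] > 0 and prop[1] >= 1):
        return theta, weight, sims, False, False  # outside domain: reject outright
    if prop[0] == theta[0] and prop[1] == theta[1]:
        # identical proposal: ratio is exactly 1, accept without re-simulating
        return theta, weight, sims, True, False
    prop_sims = simulate_summaries_batch(
        prop[0], prop[1], config, abc.n_sim, abc.n_trials_sim, rng
    )
    w_prop = float(_weight_from_sims(prop_sims, obs, tbase, abc.delta))
    log_wr, zero_zero = _log_weight_ratio(w_prop, weight)
    dlp = _bvn_logpdf(prop, pop_mean, pop_chol, pop_logdet) - _bvn_logpdf(
        theta, pop_mean, pop_chol, pop_logdet
    )
    log_alpha = log_wr + dlp
    if np.log(rng.uniform()) < log_alpha:
        return prop, w_prop, prop_sims, True, zero_zero
    return theta, weight, sims, False, zero_zero


def update_individual(
    theta_j: ParticipantParams,
    y_j,
    pop,
    tbase: float,
    config: LV05Config,
    abc: ABCConfig,
    seed,
) -> IndividualUpdate:
    """One Metropolis-Hastings step for one participant's (LF_j, CW_j).

    Symmetric Gaussian random-walk proposal; the acceptance ratio multiplies
    the ABC weight ratio by the bivariate-normal population-density ratio.
    Proposals outside {LF > 0, CW >= 1} are rejected outright.  When both
    the current and the proposed weights are exactly zero the weight ratio
    is taken to be 1 (logged), so the chain cannot freeze at a too-small
    tolerance.
    """
    rng = np.random.default_rng(seed)
    obs = np.array([float(y_j["mean_rt_ms"]), float(y_j["effect_ms"])])
    cur_sims = simulate_summaries_batch(
        theta_j.LF, theta_j.CW, config, abc.n_sim, abc.n_trials_sim, rng
    )
    w_cur = float(_weight_from_sims(cur_sims, obs, tbase, abc.delta))
    mean, chol, logdet = _bvn_chol(pop)
    scales = np.array([abc.proposal_sd_lf, abc.proposal_sd_cw])
    theta = np.array([theta_j.LF, theta_j.CW])
    new_theta, w, sims, accepted, zz = _update_individual_state(
        theta, w_cur, cur_sims, obs, mean, chol, logdet, tbase, config, abc, scales, rng
    )
    if zz:
        logger.info("0/0 ABC weight ratio treated as 1 for theta=%s", theta)
    return IndividualUpdate(
        theta=ParticipantParams(LF=float(new_theta[0]), CW=float(new_theta[1])),
        accepted=accepted,
        weight=w,
        sims=sims,
        zero_zero=zz,
    )


def update_population(participant_draws, abc: ABCConfig, seed):
    """Exact conjugate normal-inverse-Wishart draw for the population.

    Given the current individual parameters (an (n, 2) array of (LF_j,
    CW_j)), samples the population covariance from its inverse-Wishart
    conditional and the mean from its normal conditional, and returns the
    result as (mu_LF, mu_CW, sigma_LF, sigma_CW, rho).  With an empty draw
    set, samples from the NIW prior (prior-predictive mode).
    """
    from .populations import PopulationParams

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prior = abc.prior_pop
    thetas = np.asarray(participant_draws, dtype=float).reshape(-1, 2)
    n = thetas.shape[0]
    if n == 0:
        mu_n, kappa_n, nu_n, lam_n = (
            prior.mu0_arr,
            prior.kappa0,
            prior.nu0,
            prior.scale_arr,
        )
    else:
        xbar = thetas.mean(axis=0)
        diff = thetas - xbar
        S = diff.T @ diff
        kappa_n = prior.kappa0 + n
        nu_n = prior.nu0 + n
        mu_n = (prior.kappa0 * prior.mu0_arr + n * xbar) / kappa_n
        d0 = (xbar - prior.mu0_arr)[:, None]
        lam_n = prior.scale_arr + S + (prior.kappa0 * n / kappa_n) * (d0 @ d0.T)
    cond = np.linalg.cond(lam_n)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"NIW scale matrix is numerically singular (condition number {cond:.3e}); "
            f"scale={lam_n.tolist()}"
        )
    Sigma = stats.invwishart.rvs(df=nu_n, scale=lam_n, random_state=rng)
    mu = rng.multivariate_normal(mu_n, Sigma / kappa_n, method="cholesky")
    sd = np.sqrt(np.diag(Sigma))
    rho = float(Sigma[0, 1] / (sd[0] * sd[1]))
    return PopulationParams(
        mu_LF=float(mu[0]), mu_CW=float(mu[1]), sd_LF=float(sd[0]), sd_CW=float(sd[1]), rho=rho
    )


@dataclass
class PosteriorChains:
    """Retained draws from one hierarchical Gibbs ABC run.

    ``participant_draws`` has shape (n_kept, n_participants, 2) with the
    trailing axis ordered (LF, CW); ``population_draws`` has shape
    (n_kept, 5) ordered as :data:`POPULATION_PARAMS`; ``tbase_draws`` holds
    the global offset nuisance (logged separately from the 2n + 5 model
    parameters).
    """

    participant_ids: list
    participant_draws: np.ndarray
    population_draws: np.ndarray
    tbase_draws: np.ndarray
    acceptance_rates: dict
    zero_zero_events: int
    model_config: LV05Config
    abc_config: ABCConfig

    @property
    def n_participants(self) -> int:
        return self.participant_draws.shape[1]

    @property
    def n_model_params(self) -> int:
        """2n + 5: one (LF, CW) pair per participant plus five
        population-level parameters."""
        return 2 * self.n_participants + 5

    @property
    def n_kept(self) -> int:
        return self.population_draws.shape[0]

    @property
    def rho_draws(self) -> np.ndarray:
        return self.population_draws[:, 4]

    def parameter_names(self, include_individuals: bool = True) -> list[str]:
        names = list(POPULATION_PARAMS) + ["tbase"]
        if include_individuals:
            for pid in self.participant_ids:
                names += [f"LF[{pid}]", f"CW[{pid}]"]
        return names

    def draw_matrix(self, include_individuals: bool = True) -> np.ndarray:
        cols = [self.population_draws, self.tbase_draws[:, None]]
        if include_individuals:
            flat = self.participant_draws.reshape(self.n_kept, -1)
            # interleaved (LF_1, CW_1, LF_2, CW_2, ...) matches parameter_names
            cols.append(flat)
        return np.concatenate(cols, axis=1)

    def to_tidy_frame(self, include_individuals: bool = True) -> pd.DataFrame:
        names = self.parameter_names(include_individuals)
        mat = self.draw_matrix(include_individuals)
        frames = []
        for k, name in enumerate(names):
            frames.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(self.n_kept),
                        "parameter": name,
                        "value": mat[:, k],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _validate_one_block(data: pd.DataFrame) -> None:
    if data[["dataset_id", "dependency"]].drop_duplicates().shape[0] > 1:
        raise ValueError(
            "run_gibbs_abc fits one dataset x dependency block at a time; "
            "got multiple blocks — split the table first"
        )


def run_gibbs_abc(
    data: pd.DataFrame, config: LV05Config, abc: ABCConfig
) -> PosteriorChains:
    """Fit the 2n + 5 parameter hierarchical model to one dataset block.

    Alternates (i) one ABC Metropolis-Hastings sweep over all participants'
    (LF_j, CW_j), (ii) an MH update of the global offset tbase reusing each
    participant's cached simulations, and (iii) an exact conjugate NIW draw
    of the population parameters.  Proposal scales adapt toward 20-40%
    acceptance during burn-in and are frozen afterwards; burn-in draws are
    discarded and the rest thinned.  Identical seeds give identical chains.
    """
    data = data.reset_index(drop=True)
    _validate_one_block(data)
    n = data.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 participants, got {n}")
    obs = data[["mean_rt_ms", "effect_ms"]].to_numpy(dtype=float)
    pids = data["participant_id"].astype(str).tolist()
    rng = np.random.default_rng(np.random.SeedSequence(abc.seed))

    # data-informed initialization: start every participant at the prior
    # location CW, with LF set so the noise-free mean RT (plus the prior
    # tbase) matches the observed mean RT
    from .retrieval import expected_mean_rt_quadrature

    tbase = abc.prior_tbase.mean
    cw_init = max(1.0, abc.prior_pop.mu0_arr[1])
    rt_per_lf = expected_mean_rt_quadrature(ParticipantParams(LF=1.0, CW=cw_init), config)
    thetas = np.empty((n, 2))
    thetas[:, 0] = np.clip((obs[:, 0] - tbase) / rt_per_lf, 0.02, None)
    thetas[:, 1] = cw_init

    sims = _simulate_summaries_all(
        thetas[:, 0], thetas[:, 1], config, abc.n_sim, abc.n_trials_sim, rng
    )
    weights = _weight_from_sims(sims, obs, tbase, abc.delta)
    pop = update_population(thetas, abc, rng)

    scales_joint = np.tile(np.array([abc.proposal_sd_lf, abc.proposal_sd_cw]), (n, 1))
    scales_cw = np.full(n, abc.proposal_sd_cw)
    scales_lf = np.full(n, abc.proposal_sd_lf)
    tbase_scale = abc.proposal_sd_tbase

    n_kept_max = (abc.iterations - abc.burnin + abc.thin - 1) // abc.thin
    part_out = np.empty((n_kept_max, n, 2))
    pop_out = np.empty((n_kept_max, 5))
    tbase_out = np.empty(n_kept_max)

    acc_ind = np.zeros(n, dtype=int)
    acc_joint_w = np.zeros(n, dtype=int)
    acc_cw_w = np.zeros(n, dtype=int)
    acc_lf_w = np.zeros(n, dtype=int)
    acc_tbase = 0
    acc_tbase_window = 0
    n_post = 0
    zero_zero = 0
    kept = 0
    mean = chol = None  # set per iteration from the current population draw

    def _pop_logpdf(theta_arr: np.ndarray) -> np.ndarray:
        u = np.linalg.solve(chol, (theta_arr - mean).T)
        return -0.5 * (u**2).sum(axis=0)

    def _mh_sweep(props: np.ndarray, prop_sims: np.ndarray) -> np.ndarray:
        """Vectorized per-participant MH accept/reject; mutates state."""
        nonlocal zero_zero
        in_domain = (props[:, 0] > 0) & (props[:, 1] >= 1)
        safe = np.where(in_domain[:, None], props, thetas)
        w_props = _weight_from_sims(prop_sims, obs, tbase, abc.delta)
        both_zero = (w_props == 0.0) & (weights == 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_wr = np.where(both_zero, 0.0, np.log(w_props) - np.log(weights))
        dlp = _pop_logpdf(safe) - _pop_logpdf(thetas)
        accept = in_domain & (np.log(rng.uniform(size=n)) < log_wr + dlp)
        zero_zero += int((both_zero & in_domain).sum())
        thetas[accept] = props[accept]
        weights[accept] = w_props[accept]
        sims[accept] = prop_sims[accept]
        return accept

    for it in range(abc.iterations):
        in_burnin = it < abc.burnin
        mean, chol, _ = _bvn_chol(pop)

        # fresh-simulation joint (LF, CW) sweep: the only move that explores
        # CW, and it also refreshes the cached simulation noise
        props = thetas + scales_joint * rng.standard_normal((n, 2))
        safe = np.where((props[:, 0] > 0)[:, None], props, thetas)
        prop_sims = _simulate_summaries_all(
            safe[:, 0], np.maximum(safe[:, 1], 1.0), config, abc.n_sim, abc.n_trials_sim, rng
        )
        accept = _mh_sweep(props, prop_sims)
        acc_joint_w += accept
        if not in_burnin:
            acc_ind += accept

        # second fresh-simulation sweep moving CW only: cue weighting is the
        # weakly-identified direction, so it gets its own simulation budget
        props_cw = thetas.copy()
        props_cw[:, 1] += scales_cw * rng.standard_normal(n)
        prop_sims = _simulate_summaries_all(
            props_cw[:, 0], np.maximum(props_cw[:, 1], 1.0),
            config, abc.n_sim, abc.n_trials_sim, rng,
        )
        acc_cw_w += _mh_sweep(props_cw, prop_sims)

        # two cheap LF-only sweeps: summaries are exactly proportional to
        # LF, so cached simulations rescale to the proposal without new
        # forward simulation (simulation noise held fixed — a valid move on
        # the extended (theta, u) space)
        for _ in range(2):
            lf_prop = thetas[:, 0] + scales_lf * rng.standard_normal(n)
            factor = np.where(lf_prop > 0, lf_prop / thetas[:, 0], 1.0)
            props_lf = np.column_stack([lf_prop, thetas[:, 1]])
            acc_lf_w += _mh_sweep(props_lf, sims * factor[:, None, None])

        # ridge move: shift tbase and compensate every LF_j so each
        # participant's mean simulated total RT is unchanged.  Given the
        # cached noise the simulated mean RT is c_j * LF_j, so the
        # compensation is a pure translation of LF_j (unit Jacobian).
        dt = tbase_scale * rng.standard_normal()
        m_j = sims[..., 0].mean(axis=1)
        lf_ridge = thetas[:, 0] * (m_j - dt) / m_j
        if np.all(lf_ridge > 0):
            factor = lf_ridge / thetas[:, 0]
            sims_r = sims * factor[:, None, None]
            w_r = _weight_from_sims(sims_r, obs, tbase + dt, abc.delta)
            with np.errstate(divide="ignore"):
                lw_r = np.log(w_r).sum()
                lw_c = np.log(weights).sum()
            if np.isneginf(lw_r) and np.isneginf(lw_c):
                log_wr_r = 0.0
                zero_zero += 1
            else:
                log_wr_r = lw_r - lw_c
            theta_r = np.column_stack([lf_ridge, thetas[:, 1]])
            dlp_r = float(_pop_logpdf(theta_r).sum() - _pop_logpdf(thetas).sum())
            dlp_r += stats.norm.logpdf(
                tbase + dt, abc.prior_tbase.mean, abc.prior_tbase.sd
            ) - stats.norm.logpdf(tbase, abc.prior_tbase.mean, abc.prior_tbase.sd)
            if np.log(rng.uniform()) < log_wr_r + dlp_r:
                tbase = tbase + dt
                thetas[:, 0] = lf_ridge
                sims = sims_r
                weights = w_r
        if np.all(weights == 0.0):
            raise ToleranceError(
                "every participant's ABC weight is zero after a full sweep: "
                f"tolerance delta=({abc.delta_rt_ms}, {abc.delta_eff_ms}) ms is too "
                "small for the model-data distances; increase delta"
            )

        # tbase MH step from cached simulations
        tb_prop = tbase + tbase_scale * rng.standard_normal()
        w_prop = _weight_from_sims(sims, obs, tb_prop, abc.delta)
        with np.errstate(divide="ignore"):
            lw_prop = np.log(w_prop).sum()
            lw_cur = np.log(weights).sum()
        if np.isneginf(lw_prop) and np.isneginf(lw_cur):
            log_wr = 0.0
            zero_zero += 1
        else:
            log_wr = lw_prop - lw_cur
        dlp = stats.norm.logpdf(tb_prop, abc.prior_tbase.mean, abc.prior_tbase.sd) - stats.norm.logpdf(
            tbase, abc.prior_tbase.mean, abc.prior_tbase.sd
        )
        if np.log(rng.uniform()) < log_wr + dlp:
            tbase = tb_prop
            weights = w_prop
            acc_tbase_window += 1
            if not in_burnin:
                acc_tbase += 1
        if not in_burnin:
            n_post += 1

        pop = update_population(thetas, abc, rng)

        # burn-in adaptation toward 20-40% acceptance, frozen afterwards
        if in_burnin and (it + 1) % abc.adapt_interval == 0:
            scales_joint *= np.exp(acc_joint_w / abc.adapt_interval - 0.3)[:, None]
            scales_joint = np.clip(scales_joint, 1e-5, 10.0)
            scales_cw *= np.exp(acc_cw_w / abc.adapt_interval - 0.3)
            scales_cw = np.clip(scales_cw, 1e-5, 10.0)
            scales_lf *= np.exp(acc_lf_w / (2 * abc.adapt_interval) - 0.3)
            scales_lf = np.clip(scales_lf, 1e-5, 10.0)
            tb_rate = acc_tbase_window / abc.adapt_interval
            tbase_scale = float(np.clip(tbase_scale * np.exp(tb_rate - 0.3), 1e-3, 100.0))
            acc_joint_w[:] = 0
            acc_cw_w[:] = 0
            acc_lf_w[:] = 0
            acc_tbase_window = 0

        if not in_burnin and (it - abc.burnin) % abc.thin == 0:
            part_out[kept] = thetas
            pop_out[kept] = (pop.mu_LF, pop.mu_CW, pop.sd_LF, pop.sd_CW, pop.rho)
            tbase_out[kept] = tbase
            kept += 1

    if zero_zero:
        logger.info("Gibbs ABC: %d zero/zero weight-ratio events treated as ratio 1", zero_zero)
    return PosteriorChains(
        participant_ids=pids,
        participant_draws=part_out[:kept],
        population_draws=pop_out[:kept],
        tbase_draws=tbase_out[:kept],
        acceptance_rates={
            "individual": acc_ind / max(n_post, 1),
            "individual_mean": float(acc_ind.mean() / max(n_post, 1)),
            "tbase": acc_tbase / max(n_post, 1),
        },
        zero_zero_events=zero_zero,
        model_config=config,
        abc_config=abc,
    )


def summarize_posterior(chains: PosteriorChains, include_individuals: bool = True) -> pd.DataFrame:
    """Posterior summary table: mean, central 95% credible interval,
    split-chain R-hat and effective sample size per parameter."""
    import arviz as az

    mat = chains.draw_matrix(include_individuals)
    names = chains.parameter_names(include_individuals)
    m = mat.shape[0]
    if m < 4:
        raise ValueError(f"need at least 4 retained draws to summarize, got {m}")
    half = m // 2
    split = mat[: 2 * half].reshape(2, half, len(names))
    ds = az.convert_to_dataset(split)
    rhat = az.rhat(ds)["x"].to_numpy()
    ess = az.ess(ds)["x"].to_numpy()
    lo, hi = np.quantile(mat, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {
            "parameter": names,
            "mean": mat.mean(axis=0),
            "sd": mat.std(axis=0, ddof=1),
            "ci95_low": lo,
            "ci95_high": hi,
            "rhat": rhat,
            "ess": ess,
        }
    )


def run_abc_mh(
    observed,
    simulate,
    prior_logpdf,
    init,
    proposal_sd,
    delta,
    n_sim: int,
    iterations: int,
    burnin: int,
    seed,
    domain=None,
):
    """Generic single-level ABC Metropolis-Hastings chain.

    ``simulate(theta, n_sim, rng)`` must return an (n_sim, d) array of
    simulated summaries; the approximate likelihood is the average product
    of per-component Gaussian kernel weights against ``observed`` (length
    d) with tolerance ``delta``.  Used for validating the ABC machinery on
    models with tractable likelihoods.

    Returns (draws, acceptance_rate) with draws of shape
    (iterations - burnin, len(init)).
    """
    rng = np.random.default_rng(seed)
    theta = np.atleast_1d(np.asarray(init, dtype=float))
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    delta = np.broadcast_to(np.asarray(delta, dtype=float), obs.shape)
    proposal_sd = np.broadcast_to(np.asarray(proposal_sd, dtype=float), theta.shape)

    def weight(th):
        sims = np.atleast_2d(simulate(th, n_sim, rng))
        d = np.abs(sims - obs)
        return float(np.exp(-(d**2) / (2.0 * delta**2)).prod(axis=1).mean())

    w_cur = weight(theta)
    lp_cur = prior_logpdf(theta)
    draws = np.empty((iterations - burnin, theta.size))
    accepted = 0
    for it in range(iterations):
        prop = theta + proposal_sd * rng.standard_normal(theta.size)
        if domain is not None and not domain(prop):
            pass
        else:
            w_prop = weight(prop)
            log_wr, _ = _log_weight_ratio(w_prop, w_cur)
            lp_prop = prior_logpdf(prop)
            if np.log(rng.uniform()) < log_wr + lp_prop - lp_cur:
                theta, w_cur, lp_cur = prop, w_prop, lp_prop
                accepted += 1
        if it >= burnin:
            draws[it - burnin] = theta
    return draws, accepted / iterations


# ---------------------------------------------------------------------------
# model / results interface


class CueRetrievalABC:
    """Hierarchical individual-differences model for one dataset block.

    Parameters
    ----------
    data : DataFrame with columns dataset_id, dependency, participant_id,
        mean_rt_ms, effect_ms (one dataset x dependency block).
    model_config : fixed LV05 constants (noise SD, latency exponent, ...).
    abc_config : sampler settings.

    ``fit`` runs the Gibbs ABC sampler and returns a results object.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        model_config: LV05Config | None = None,
        abc_config: ABCConfig | None = None,
    ):
        _validate_one_block(data)
        self.data = data.reset_index(drop=True)
        self.model_config = model_config or LV05Config()
        self.abc_config = abc_config or ABCConfig()

    @classmethod
    def from_csv(
        cls,
        path,
        dataset_id: str | None = None,
        dependency: str | None = None,
        model_config: LV05Config | None = None,
        abc_config: ABCConfig | None = None,
        strict: bool = True,
    ) -> "CueRetrievalABC":
        from .pipeline import read_effects_table

        df = read_effects_table(path, strict=strict)
        if dataset_id is not None:
            df = df[df["dataset_id"] == dataset_id]
        if dependency is not None:
            df = df[df["dependency"] == dependency]
        return cls(df, model_config=model_config, abc_config=abc_config)

    def fit(self, seed: int | None = None) -> "CueRetrievalABCResults":
        abc = self.abc_config if seed is None else self.abc_config.replace(seed=seed)
        chains = run_gibbs_abc(self.data, self.model_config, abc)
        return CueRetrievalABCResults(self, chains)


class CueRetrievalABCResults:
    """Posterior chains plus summaries for one fitted dataset block."""

    def __init__(self, model: CueRetrievalABC, chains: PosteriorChains):
        self.model = model
        self.chains = chains

    @property
    def rho_draws(self) -> np.ndarray:
        """Posterior draws of the LF/CW population correlation."""
        return self.chains.rho_draws

    def summary(self, include_individuals: bool = False) -> pd.DataFrame:
        return summarize_posterior(self.chains, include_individuals)

    def posterior_predictive_effects(self, n_draws: int = 200) -> pd.DataFrame:
        """Per-participant posterior mean and 95% CrI of the predicted
        interference effect (deterministic expectation per draw).

        The per-draw expected effect is LF * e(CW) where e(CW) is the
        quadrature-oracle effect per unit latency factor, interpolated on a
        dense CW grid (the effect is exactly linear in LF).
        """
        from .retrieval import expected_effect_quadrature

        cw_grid = np.linspace(1.0, 8.0, 57)
        eff_per_lf = np.array(
            [
                expected_effect_quadrature(
                    ParticipantParams(LF=1.0, CW=cw), self.model.model_config
                )
                for cw in cw_grid
            ]
        )
        draws = self.chains.participant_draws
        step = max(1, draws.shape[0] // n_draws)
        sub = draws[::step]
        eff = sub[:, :, 0] * np.interp(np.clip(sub[:, :, 1], 1.0, 8.0), cw_grid, eff_per_lf)
        lo, hi = np.quantile(eff, [0.025, 0.975], axis=0)
        return pd.DataFrame(
            {
                "participant_id": self.chains.participant_ids,
                "pred_effect_mean_ms": eff.mean(axis=0),
                "pred_effect_ci95_low": lo,
                "pred_effect_ci95_high": hi,
            }
        )

    def write_outputs(self, outdir, stem: str) -> dict:
        """Write tidy chain draws and the summary table; returns paths."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        chains_path = outdir / f"{stem}_chains.csv"
        summary_path = outdir / f"{stem}_summary.csv"
        self.chains.to_tidy_frame().to_csv(chains_path, index=False)
        self.summary(include_individuals=True).to_csv(summary_path, index=False)
        return {"chains": str(chains_path), "summary": str(summary_path)}
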