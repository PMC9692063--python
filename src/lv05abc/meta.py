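"""Bayesian random-effects meta-analysis of correlations on the Fisher-z scale.

Each dataset fit yields posterior draws of rho, the population correlation
between latency factor and cue weighting.  These are summarized on the
Fisher-z scale (z_k = mean of arctanh(rho draws), s_k = their SD) and pooled
with the hierarchical model

    z_k ~ Normal(theta_k, s_k^2),   theta_k ~ Normal(mu_z, tau^2),

with a Normal(0, 1) prior on the pooled mean mu_z and a half-Normal(0, 0.2)
prior on the between-study SD tau.  mu_z and the theta_k have exact normal
conjugate conditionals; tau is updated by a griddy-Gibbs step on a fixed
grid, keeping every other update exact.  The pooled correlation is tanh
applied draw-wise to mu_z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MetaStudyInput",
    "MetaPriors",
    "MetaPosterior",
    "fisher_z_transform",
    "inverse_fisher_z",
    "dataset_z_input",
    "fit_random_effects",
    "pooled_summary",
    "FisherZMeta",
    "FisherZMetaResults",
]


def fisher_z_transform(r):
    """Fisher z = arctanh(r); maps correlations to an approximately normal
    scale.  Requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    """Inverse transform r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MetaStudyInput:
    """One dataset's correlation evidence on the Fisher-z scale."""

    dataset_id: str
    z_k: float
    s_k: float
    n_k: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.z_k):
            raise ValueError(f"z_k must be finite, got {self.z_k}")
        if not self.s_k > 0:
            raise ValueError(f"s_k must be > 0, got {self.s_k}")
        if self.n_k < 4:
            raise ValueError(f"n_k must be >= 4 (Fisher-z scale undefined below), got {self.n_k}")


def dataset_z_input(rho_draws, dataset_id: str, n_k: int) -> MetaStudyInput:
    """Summarize one dataset's posterior rho draws on the Fisher-z scale.

    z_k is the mean and s_k the SD of arctanh(rho).  Degenerate draws
    (SD = 0) get the classical floor 1 / sqrt(n_k - 3), with a logged note.
    """
    rho_draws = np.asarray(rho_draws, dtype=float)
    if rho_draws.size < 100:
        raise ValueError(f"need >= 100 posterior draws, got {rho_draws.size}")
    if np.any(np.abs(rho_draws) >= 1):
        raise ValueError("all rho draws must satisfy |rho| < 1")
    z = np.arctanh(rho_draws)
    s_k = float(z.std(ddof=1))
    if s_k < 1e-10:  # degenerate draws up to float round-off
        s_k = 1.0 / np.sqrt(n_k - 3)
        logger.info(
            "dataset %s: degenerate rho draws; flooring s_k at 1/sqrt(n-3) = %.4f",
            dataset_id,
            s_k,
        )
    return MetaStudyInput(dataset_id=dataset_id, z_k=float(z.mean()), s_k=s_k, n_k=n_k)


@dataclass(frozen=True)
class MetaPriors:
    """Priors for the random-effects model on the z scale."""

    mu_mean: float = 0.0
    mu_sd: float = 1.0
    tau_halfnormal_sd: float = 0.2
    tau_grid_max: float = 1.0
    tau_grid_points: int = 400

    def __post_init__(self) -> None:
        if self.mu_sd <= 0 or self.tau_halfnormal_sd <= 0:
            raise ValueError("prior scales must be > 0")
        if self.tau_grid_points < 10:
            raise ValueError("tau grid needs at least 10 points")

    @property
    def tau_grid(self) -> np.ndarray:
        # strictly positive grid; the lower edge stands in for tau -> 0
        return np.linspace(self.tau_grid_max / self.tau_grid_points, self.tau_grid_max,
                           self.tau_grid_points)


@dataclass
class MetaPosterior:
    """Draws from the random-effects posterior."""

    study_ids: list
    mu_z_draws: np.ndarray
    tau_draws: np.ndarray
    theta_draws: np.ndarray  # (n_kept, K)
    diagnostics: dict = field(default_factory=dict)

    @property
    def pooled_r_draws(self) -> np.ndarray:
        return np.tanh(self.mu_z_draws)


def _as_study_list(studies) -> list[MetaStudyInput]:
    out = list(studies)
    if len(out) < 2:
        raise ValueError(f"random-effects pooling needs >= 2 studies, got {len(out)}")
    return out


def fit_random_effects(
    studies,
    priors: MetaPriors | None = None,
    iterations: int = 4000,
    seed: int = 0,
    burnin: int | None = None,
) -> MetaPosterior:
    """Gibbs sampler for the Fisher-z random-effects model.

    theta_k and mu_z are drawn from their exact normal conditionals; tau
    from a griddy-Gibbs step: the half-Normal prior times the Normal
    likelihood of the current theta_k deviations, evaluated on a fixed
    positive grid and sampled as a categorical.  A split-chain R-hat above
    1.05 on mu_z or tau is recorded as a convergence warning in the
    diagnostics (never silently dropped).
    """
    studies = _as_study_list(studies)
    priors = priors or MetaPriors()
    if burnin is None:
        burnin = iterations // 4
    if not iterations > burnin >= 0:
        raise ValueError(f"need iterations > burnin >= 0, got {iterations}, {burnin}")
    rng = np.random.default_rng(seed)
    z = np.array([s.z_k for s in studies])
    s2 = np.array([s.s_k for s in studies]) ** 2
    K = z.size
    grid = priors.tau_grid
    log_prior_tau = -(grid**2) / (2.0 * priors.tau_halfnormal_sd**2)

    mu = float(z.mean())
    tau = priors.tau_halfnormal_sd
    theta = z.copy()

    n_kept = iterations - burnin
    mu_out = np.empty(n_kept)
    tau_out = np.empty(n_kept)
    theta_out = np.empty((n_kept, K))
    for it in range(iterations):
        # theta_k | mu, tau, z_k  (normal-normal conjugacy)
        v = 1.0 / (1.0 / s2 + 1.0 / tau**2)
        m = v * (z / s2 + mu / tau**2)
        theta = m + np.sqrt(v) * rng.standard_normal(K)
        # mu | theta, tau
        v_mu = 1.0 / (K / tau**2 + 1.0 / priors.mu_sd**2)
        m_mu = v_mu * (theta.sum() / tau**2 + priors.mu_mean / priors.mu_sd**2)
        mu = m_mu + np.sqrt(v_mu) * rng.standard_normal()
        # tau | theta, mu  (griddy Gibbs on the documented grid)
        ss = float(((theta - mu) ** 2).sum())
        logp = log_prior_tau - K * np.log(grid) - ss / (2.0 * grid**2)
        logp -= logp.max()
        p = np.exp(logp)
        p /= p.sum()
        tau = float(rng.choice(grid, p=p))
        if it >= burnin:
            mu_out[it - burnin] = mu
            tau_out[it - burnin] = tau
            theta_out[it - burnin] = theta

    diagnostics = _convergence_diagnostics(mu_out, tau_out)
    return MetaPosterior(
        study_ids=[s.dataset_id for s in studies],
        mu_z_draws=mu_out,
        tau_draws=tau_out,
        theta_draws=theta_out,
        diagnostics=diagnostics,
    )


def _split_rhat(draws: np.ndarray) -> float:
    import arviz as az

    half = draws.shape[0] // 2
    return float(az.rhat(az.convert_to_dataset(draws[: 2 * half].reshape(2, half)))["x"])


def _convergence_diagnostics(mu_out: np.ndarray, tau_out: np.ndarray) -> dict:
    rhat_mu = _split_rhat(mu_out)
    rhat_tau = _split_rhat(tau_out)
    warnings = []
    if rhat_mu > 1.05 or rhat_tau > 1.05:
        msg = f"split-chain R-hat above 1.05 (mu_z: {rhat_mu:.3f}, tau: {rhat_tau:.3f})"
        warnings.append(msg)
        logger.warning("meta-analysis convergence: %s", msg)
    return {"rhat_mu_z": rhat_mu, "rhat_tau": rhat_tau, "warnings": warnings}


def pooled_summary(meta: MetaPosterior) -> dict:
    """Pooled correlation: mean and central 95% CrI of tanh(mu_z draws)."""
    r = meta.pooled_r_draws
    if r.size == 0:
        raise ValueError("empty posterior draws")
    lo, hi = np.quantile(r, [0.025, 0.975])
    return {
        "pooled_r_mean": float(r.mean()),
        "ci95_low": float(lo),
        "ci95_high": float(hi),
        "tau_mean": float(meta.tau_draws.mean()),
    }


class FisherZMeta:
    """Random-effects meta-analysis model over per-dataset z estimates.

    Accepts either a sequence of :class:`MetaStudyInput` or a DataFrame with
    columns ``dataset_id, z_k, s_k, n_k`` (see :meth:`from_csv`).
    """

    def __init__(self, studies, priors: MetaPriors | None = None):
        if isinstance(studies, pd.DataFrame):
            studies = [
                MetaStudyInput(
                    dataset_id=str(row.dataset_id),
                    z_k=float(row.z_k),
                    s_k=float(row.s_k),
                    n_k=int(row.n_k),
                )
                for row in studies.itertuples()
            ]
        self.studies = _as_study_list(studies)
        self.priors = priors or MetaPriors()

    @classmethod
    def from_csv(cls, path, priors: MetaPriors | None = None) -> "FisherZMeta":
        return cls(pd.read_csv(path), priors=priors)

    def fit(self, iterations: int = 4000, seed: int = 0, burnin: int | None = None):
        posterior = fit_random_effects(
            self.studies, priors=self.priors, iterations=iterations, seed=seed, burnin=burnin
        )
        return FisherZMetaResults(self, posterior)


class FisherZMetaResults:
    def __init__(self, model: FisherZMeta, posterior: MetaPosterior):
        self.model = model
        self.posterior = posterior

    @property
    def pooled(self) -> dict:
        return pooled_summary(self.posterior)

    def summary(self) -> pd.DataFrame:
        """Study-level shrunken estimates plus the pooled row, on both the
        z and the correlation scales."""
        rows = []
        theta = self.posterior.theta_draws
        for k, sid in enumerate(self.posterior.study_ids):
            lo, hi = np.quantile(theta[:, k], [0.025, 0.975])
            rows.append(
                {
                    "dataset_id": sid,
                    "z_mean": float(theta[:, k].mean()),
                    "z_ci95_low": float(lo),
                    "z_ci95_high": float(hi),
                    "r_mean": float(np.tanh(theta[:, k]).mean()),
                }
            )
        p = self.pooled
        mu = self.posterior.mu_z_draws
        rows.append(
            {
                "dataset_id": "<pooled>",
                "z_mean": float(mu.mean()),
                "z_ci95_low": float(np.quantile(mu, 0.025)),
                "z_ci95_high": float(np.quantile(mu, 0.975)),
                "r_mean": p["pooled_r_mean"],
            }
        )
        return pd.DataFrame(rows)

    def write_outputs(self, outdir, stem: str = "meta") -> dict:
        from pathlib import Path
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        draws_path = outdir / f"{stem}_draws.csv"
        pd.DataFrame(
            {
                "iteration": np.arange(self.posterior.mu_z_draws.size),
                "mu_z": self.posterior.mu_z_draws,
                "tau": self.posterior.tau_draws,
            }
        ).to_csv(draws_path, index=False)
        summary_path = outdir / f"{stem}_pooled.json"
        payload = dict(self.pooled)
        payload["diagnostics"] = self.posterior.diagnostics
        summary_path.write_text(json.dumps(payload, indent=2))
        return {"draws": str(draws_path), "pooled": str(summary_path)}
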