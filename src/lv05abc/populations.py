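"""Synthetic populations of readers and simulated interference datasets.

Individual (latency factor, cue weighting) pairs are drawn from a bivariate
normal with population means (mu_LF, mu_CW), SDs (sd_LF, sd_CW) and
correlation rho, truncated by rejection to the model's domain
{LF > 0, CW >= 1}.  Observed per-participant summaries — mean reading time
and facilitatory interference effect, both in ms — are the model's
Monte-Carlo predictions plus additive Gaussian measurement noise emulating
the posterior uncertainty of shrunken by-participant estimates from a
hierarchical regression on raw reading times.

The bundled fixture emulates the structure of the 13 published
facilitatory-interference datasets (Dillon et al. 2013; Jäger et al. 2020;
Lago et al. 2015; Wagers et al. 2009): 11 subject-verb agreement blocks and
2 antecedent-reflexive blocks with the published participant counts, with
each block's mean latency factor calibrated so the simulated mean effect
lands near the published mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .retrieval import (
    LV05Config,
    ParticipantParams,
    expected_effect_quadrature,
    predict_summaries,
)

__all__ = [
    "PopulationParams",
    "PopulationSample",
    "ObservedDataset",
    "SUMMARY_COLUMNS",
    "sample_population",
    "simulate_observed_dataset",
    "make_table1_fixture",
    "TABLE1_LAYOUT",
    "write_summaries_csv",
]

SUMMARY_COLUMNS = [
    "dataset_id",
    "dependency",
    "participant_id",
    "mean_rt_ms",
    "effect_ms",
    "se_ms",
]

DEPENDENCIES = ("agreement", "reflexive")


@dataclass(frozen=True)
class PopulationParams:
    """Bivariate-normal population over (LF, CW)."""

    mu_LF: float
    mu_CW: float
    sd_LF: float
    sd_CW: float
    rho: float

    def __post_init__(self) -> None:
        if self.sd_LF < 0 or self.sd_CW < 0:
            raise ValueError(
                f"population SDs must be >= 0, got sd_LF={self.sd_LF}, sd_CW={self.sd_CW}"
            )
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"correlation rho must lie in (-1, 1), got {self.rho}")

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mu_LF, self.mu_CW])

    @property
    def cov(self) -> np.ndarray:
        off = self.rho * self.sd_LF * self.sd_CW
        return np.array([[self.sd_LF**2, off], [off, self.sd_CW**2]])


class TruncationError(RuntimeError):
    """Raised when rejection sampling accepts almost nothing."""


@dataclass(frozen=True)
class PopulationSample:
    """Accepted draws from the truncated bivariate normal."""

    LF: np.ndarray
    CW: np.ndarray
    acceptance_rate: float

    def __len__(self) -> int:
        return self.LF.shape[0]

    def __getitem__(self, j: int) -> ParticipantParams:
        return ParticipantParams(LF=float(self.LF[j]), CW=float(self.CW[j]))

    def __iter__(self):
        return (self[j] for j in range(len(self)))


_MIN_ACCEPT = 0.01
_GUARD_PROPOSALS = 10_000


def sample_population(pop: PopulationParams, n_participants: int, seed) -> PopulationSample:
    """Draw participants from the bivariate normal truncated to
    {LF > 0, CW >= 1} by rejection.

    Raises :class:`TruncationError` when fewer than 1% of proposals land in
    the domain — a sign the population parameters put essentially all mass
    outside the model's support and should be re-parameterized.
    """
    if n_participants < 0:
        raise ValueError(f"n_participants must be >= 0, got {n_participants}")
    if n_participants == 0:
        return PopulationSample(LF=np.empty(0), CW=np.empty(0), acceptance_rate=float("nan"))
    rng = np.random.default_rng(seed)
    accepted_lf: list[np.ndarray] = []
    accepted_cw: list[np.ndarray] = []
    n_accepted = 0
    n_proposed = 0
    batch = max(1000, 2 * n_participants)
    while n_accepted < n_participants:
        draws = rng.multivariate_normal(pop.mean, pop.cov, size=batch, method="svd")
        ok = (draws[:, 0] > 0) & (draws[:, 1] >= 1)
        n_proposed += batch
        n_accepted += int(ok.sum())
        accepted_lf.append(draws[ok, 0])
        accepted_cw.append(draws[ok, 1])
        if n_proposed >= _GUARD_PROPOSALS and n_accepted < _MIN_ACCEPT * n_proposed:
            raise TruncationError(
                f"rejection acceptance rate {n_accepted / n_proposed:.4f} < {_MIN_ACCEPT}: "
                f"population {pop} puts almost no mass on LF > 0, CW >= 1; "
                "re-parameterize the population"
            )
    lf = np.concatenate(accepted_lf)[:n_participants]
    cw = np.concatenate(accepted_cw)[:n_participants]
    return PopulationSample(LF=lf, CW=cw, acceptance_rate=n_accepted / n_proposed)


@dataclass(frozen=True)
class ObservedDataset:
    """Observed summaries plus the generating truth, for recovery studies."""

    summaries: pd.DataFrame  # SUMMARY_COLUMNS
    truth: pd.DataFrame  # dataset_id, participant_id, LF, CW, true_mean_rt_ms, true_effect_ms

    def write_csv(self, path) -> None:
        """Write the summaries CSV and a `_truth`-suffixed sibling."""
        path = str(path)
        self.summaries.to_csv(path, index=False)
        stem, dot, ext = path.rpartition(".")
        truth_path = f"{stem}_truth.{ext}" if dot else f"{path}_truth"
        self.truth.to_csv(truth_path, index=False)


def _empty_dataset() -> ObservedDataset:
    return ObservedDataset(
        summaries=pd.DataFrame(columns=SUMMARY_COLUMNS),
        truth=pd.DataFrame(
            columns=["dataset_id", "participant_id", "LF", "CW", "true_mean_rt_ms", "true_effect_ms"]
        ),
    )


def simulate_observed_dataset(
    participants,
    config: LV05Config,
    noise_se_ms: float,
    dataset_id: str,
    dependency: str,
    seed,
    tbase_ms: float = 0.0,
) -> ObservedDataset:
    """Simulate per-participant observed summaries for one dataset.

    Each participant's (mean RT, effect) is the model's Monte-Carlo
    prediction at their true parameters, shifted by a global non-retrieval
    offset ``tbase_ms``, plus independent Normal(0, noise_se_ms) measurement
    noise on each component.
    """
    if noise_se_ms < 0:
        raise ValueError(f"noise_se_ms must be >= 0, got {noise_se_ms}")
    if dependency not in DEPENDENCIES:
        raise ValueError(f"dependency must be one of {DEPENDENCIES}, got {dependency!r}")
    participants = list(participants)
    if not participants:
        return _empty_dataset()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    noise_rng = np.random.default_rng(root.spawn(1)[0])
    sim_seeds = root.spawn(len(participants))
    rows = []
    truth_rows = []
    for j, (p, s) in enumerate(zip(participants, sim_seeds)):
        pred = predict_summaries(p, config, s)
        obs_rt = pred.mean_rt_ms + tbase_ms + noise_se_ms * noise_rng.standard_normal()
        obs_eff = pred.effect_ms + noise_se_ms * noise_rng.standard_normal()
        pid = f"P{j + 1:03d}"
        rows.append(
            {
                "dataset_id": dataset_id,
                "dependency": dependency,
                "participant_id": pid,
                "mean_rt_ms": obs_rt,
                "effect_ms": obs_eff,
                "se_ms": noise_se_ms,
            }
        )
        truth_rows.append(
            {
                "dataset_id": dataset_id,
                "participant_id": pid,
                "LF": p.LF,
                "CW": p.CW,
                "true_mean_rt_ms": pred.mean_rt_ms + tbase_ms,
                "true_effect_ms": pred.effect_ms,
            }
        )
    return ObservedDataset(summaries=pd.DataFrame(rows), truth=pd.DataFrame(truth_rows))


def calibrate_mu_lf(
    target_effect_ms: float, mu_CW: float, config: LV05Config
) -> float:
    """Mean latency factor whose deterministic effect equals the target.

    1-D root find (Brent) on the quadrature-oracle effect as a function of
    LF at fixed CW; well-posed because the effect is linear in LF and
    strictly negative for sigma > 0.
    """
    if target_effect_ms >= 0:
        raise ValueError(f"target effect must be negative (facilitation), got {target_effect_ms}")

    def g(lf: float) -> float:
        return expected_effect_quadrature(ParticipantParams(LF=lf, CW=mu_CW), config) - target_effect_ms

    return float(brentq(g, 1e-4, 20.0, xtol=1e-8))


#: (dataset_id, dependency, n_participants, mean effect in ms) for the 13
#: published facilitatory-interference datasets.
TABLE1_LAYOUT = [
    ("dillon13_e1", "agreement", 40, -60.0),
    ("jaeger20", "agreement", 181, -27.0),
    ("lago15_e1", "agreement", 32, -27.0),
    ("lago15_e2", "agreement", 32, -23.0),
    ("lago15_e3a", "agreement", 32, -13.0),
    ("lago15_e3b", "agreement", 32, -13.0),
    ("wagers09_e2", "agreement", 28, -23.0),
    ("wagers09_e3_sing", "agreement", 60, -18.0),
    ("wagers09_e3_plur", "agreement", 60, -4.0),
    ("wagers09_e4", "agreement", 44, -28.0),
    ("wagers09_e5", "agreement", 60, -20.0),
    ("dillon13_e1", "reflexive", 40, -18.0),
    ("jaeger20", "reflexive", 181, -23.0),
]

# fixture population shape: agreement readers weight cues near-equally,
# reflexive readers lean more on the structural cue; rho matches the
# negative speed/weighting association seen across studies
_FIXTURE_MU_CW = {"agreement": 1.3, "reflexive": 1.8}
_FIXTURE_SD_CW = {"agreement": 0.4, "reflexive": 0.6}
_FIXTURE_RHO = -0.3
_FIXTURE_SD_LF_FRAC = 0.2
_FIXTURE_NOISE_SE_MS = 15.0


def make_table1_fixture(
    seed, config: LV05Config | None = None, n_trials: int = 4000
) -> ObservedDataset:
    """Synthetic 13-dataset fixture with the published participant counts.

    For each block, mu_LF is calibrated by a root find so the deterministic
    population-mean effect at (mu_LF, mu_CW) matches the published mean
    effect; participants are then drawn from the truncated bivariate normal
    and observed with 15-ms measurement noise.
    """
    config = (config or LV05Config()).replace(n_trials=n_trials)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    block_seeds = root.spawn(2 * len(TABLE1_LAYOUT))
    summaries = []
    truths = []
    for k, (dataset_id, dependency, n, target) in enumerate(TABLE1_LAYOUT):
        mu_cw = _FIXTURE_MU_CW[dependency]
        mu_lf = calibrate_mu_lf(target, mu_cw, config)
        pop = PopulationParams(
            mu_LF=mu_lf,
            mu_CW=mu_cw,
            sd_LF=_FIXTURE_SD_LF_FRAC * mu_lf,
            sd_CW=_FIXTURE_SD_CW[dependency],
            rho=_FIXTURE_RHO,
        )
        sample = sample_population(pop, n, block_seeds[2 * k])
        ds = simulate_observed_dataset(
            sample,
            config,
            noise_se_ms=_FIXTURE_NOISE_SE_MS,
            dataset_id=dataset_id,
            dependency=dependency,
            seed=block_seeds[2 * k + 1],
        )
        summaries.append(ds.summaries)
        truths.append(ds.truth.assign(dependency=dependency))
    return ObservedDataset(
        summaries=pd.concat(summaries, ignore_index=True),
        truth=pd.concat(truths, ignore_index=True),
    )


def write_summaries_csv(df: pd.DataFrame, path) -> None:
    """Write an ObservedSummaries table in the canonical column order."""
    df.loc[:, SUMMARY_COLUMNS].to_csv(path, index=False)
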