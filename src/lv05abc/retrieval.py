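"""Simplified Lewis & Vasishth (2005) cue-based retrieval simulator.

The model: at the moment a dependency (subject-verb agreement or
antecedent-reflexive) must be completed, candidate chunks in memory receive
spreading activation from the retrieval cues they match,

    A_i = B_i + sum_j W_j * S_ji + eps_i,      eps_i ~ Normal(0, sigma),

and the chunk with the highest realized activation is retrieved, taking

    RT = F * exp(-f * A_winner)

seconds, where F is the latency factor (a participant's general reading
speed) and f the latency exponent.  In the ungrammatical configurations of
interest there are exactly two chunks (the grammatical target and a
distractor) and two cues (a structural cue the target always matches, and a
number cue the distractor matches only in the multiple-match condition).
Facilitatory interference — a *speedup* in the multiple-match condition —
arises purely from statistical facilitation in this noisy race and is
modulated by the cue-weighting ratio CW = W_structural / W_number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, stats

__all__ = [
    "CHUNKS",
    "CUES",
    "CONDITIONS",
    "ConditionSchedule",
    "LV05Config",
    "ParticipantParams",
    "TrialRecord",
    "TrialRecords",
    "SummaryPrediction",
    "cue_weights_from_ratio",
    "mean_activations",
    "simulate_retrieval_trials",
    "predict_summaries",
    "expected_latency_quadrature",
    "expected_effect_quadrature",
    "effect_surface",
]

CHUNKS = ("target", "distractor")
CUES = ("structural", "number")
CONDITIONS = ("multiple_match", "single_match")

#: cue-match indicators, rows = chunks, cols = cues
_MATCH = {
    "multiple_match": np.array([[1, 0], [0, 1]], dtype=float),
    "single_match": np.array([[1, 0], [0, 0]], dtype=float),
}


class ScheduleError(ValueError):
    """Raised for a structurally invalid condition schedule."""


@dataclass(frozen=True)
class ConditionSchedule:
    """Cue-match layout of one experimental condition.

    ``match_matrix`` is a 2x2 binary array: rows follow :data:`CHUNKS`
    (target, distractor), columns follow :data:`CUES` (structural, number).
    The target matches the structural cue in both conditions and never the
    number cue; the distractor matches the number cue in ``multiple_match``
    only and nothing in ``single_match``.
    """

    condition: str
    match_matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ScheduleError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        m = np.asarray(self.match_matrix, dtype=float)
        if m.shape != (2, 2):
            raise ScheduleError(f"match_matrix must be 2x2, got shape {m.shape}")
        if not np.isin(m, (0.0, 1.0)).all():
            raise ScheduleError("match_matrix entries must be binary")
        if not np.array_equal(m, _MATCH[self.condition]):
            raise ScheduleError(
                f"match_matrix inconsistent with condition {self.condition!r}: "
                f"target must match only the structural cue, distractor must match "
                f"the number cue iff condition is multiple_match"
            )
        object.__setattr__(self, "match_matrix", m)

    @classmethod
    def for_condition(cls, condition: str) -> "ConditionSchedule":
        if condition not in _MATCH:
            raise ScheduleError(
                f"unknown condition {condition!r}; expected one of {CONDITIONS}"
            )
        return cls(condition=condition, match_matrix=_MATCH[condition].copy())


@dataclass(frozen=True)
class LV05Config:
    """Fixed model constants shared by all participants.

    Parameters
    ----------
    f : latency exponent (dimensionless), > 0.
    sigma : SD of the Gaussian activation noise, in activation units.
    S_assoc : associative strength S_ji for every matching cue-chunk pair.
    B_base : baseline activation B_i of both chunks.
    W_total : total cue-weight budget; the cue-weighting ratio CW splits it.
    n_trials : Monte-Carlo trials per condition when predicting summaries.
    threshold_enabled, threshold : optional ACT-R retrieval threshold; when
        enabled, trials whose winning activation falls below ``threshold``
        are *flagged* (not dropped).
    ms_per_second : fixed unit conversion for reported summaries.
    """

    f: float = 1.0
    sigma: float = 0.25
    S_assoc: float = 1.0
    B_base: float = 0.0
    W_total: float = 1.0
    n_trials: int = 100_000
    threshold_enabled: bool = False
    threshold: float = -1.0
    ms_per_second: float = 1000.0

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError(f"latency exponent f must be > 0, got {self.f}")
        if self.sigma < 0:
            raise ValueError(f"activation-noise sigma must be >= 0, got {self.sigma}")
        if self.S_assoc <= 0:
            raise ValueError(f"associative strength must be > 0, got {self.S_assoc}")
        if self.W_total <= 0:
            raise ValueError(f"weight budget W_total must be > 0, got {self.W_total}")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")

    def replace(self, **kwargs) -> "LV05Config":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ParticipantParams:
    """One reader's latency factor (seconds) and cue-weighting ratio."""

    LF: float
    CW: float

    def __post_init__(self) -> None:
        if not self.LF > 0:
            raise ValueError(f"latency factor LF must be > 0, got {self.LF}")
        if not self.CW >= 1:
            raise ValueError(
                f"cue-weighting ratio CW must be >= 1 (structural over number), got {self.CW}"
            )


def cue_weights_from_ratio(CW: float, W_total: float) -> tuple[float, float]:
    """Split the weight budget so that W_structural / W_number = CW.

    Budget conservation (W_structural + W_number = W_total) makes CW the
    only weighting degree of freedom: changing CW redistributes, never adds,
    activation.
    """
    if not CW >= 1:
        raise ValueError(f"cue-weighting ratio CW must be >= 1, got {CW}")
    if not W_total > 0:
        raise ValueError(f"weight budget W_total must be > 0, got {W_total}")
    w_number = W_total / (1.0 + CW)
    return W_total - w_number, w_number


def mean_activations(
    CW: float, config: LV05Config, schedule: ConditionSchedule
) -> np.ndarray:
    """Noise-free activations (target, distractor) under a schedule."""
    w_s, w_n = cue_weights_from_ratio(CW, config.W_total)
    weights = np.array([w_s, w_n])
    return config.B_base + config.S_assoc * (schedule.match_matrix @ weights)


@dataclass(frozen=True)
class TrialRecord:
    A_target: float
    A_distractor: float
    winner: str
    rt: float
    below_threshold: bool = False


@dataclass(frozen=True)
class TrialRecords:
    """Column-oriented container of simulated retrieval trials."""

    A_target: np.ndarray
    A_distractor: np.ndarray
    winner: np.ndarray  # array of "target" / "distractor"
    rt: np.ndarray  # seconds
    below_threshold: np.ndarray

    def __len__(self) -> int:
        return self.rt.shape[0]

    def __getitem__(self, i: int) -> TrialRecord:
        return TrialRecord(
            A_target=float(self.A_target[i]),
            A_distractor=float(self.A_distractor[i]),
            winner=str(self.winner[i]),
            rt=float(self.rt[i]),
            below_threshold=bool(self.below_threshold[i]),
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))


def simulate_retrieval_trials(
    params: ParticipantParams,
    config: LV05Config,
    schedule: ConditionSchedule,
    n: int,
    seed,
) -> TrialRecords:
    """Simulate ``n`` noisy retrieval races.

    Each trial draws independent activation noise per chunk, retrieves the
    chunk with the strictly larger realized activation (exact ties — a
    measure-zero event for sigma > 0 — go to the target; the latency is
    unaffected since tied activations give identical latencies), and records
    the retrieval time LF * exp(-f * A_winner).
    """
    if n < 1:
        raise ValueError(f"need at least one trial, got n={n}")
    rng = np.random.default_rng(seed)
    a = mean_activations(params.CW, config, schedule)
    A = a + config.sigma * rng.standard_normal((n, 2))
    distractor_wins = A[:, 1] > A[:, 0]  # ties -> target
    A_winner = np.where(distractor_wins, A[:, 1], A[:, 0])
    rt = params.LF * np.exp(-config.f * A_winner)
    if config.threshold_enabled:
        below = A_winner < config.threshold
    else:
        below = np.zeros(n, dtype=bool)
    winner = np.where(distractor_wins, CHUNKS[1], CHUNKS[0])
    return TrialRecords(
        A_target=A[:, 0],
        A_distractor=A[:, 1],
        winner=winner,
        rt=rt,
        below_threshold=below,
    )


@dataclass(frozen=True)
class SummaryPrediction:
    """Monte-Carlo summary prediction with its MC standard errors (ms)."""

    mean_rt_ms: float
    effect_ms: float
    se_mean_rt_ms: float
    se_effect_ms: float
    n_trials: int
    condition_means_ms: dict = field(default_factory=dict)


def _condition_seeds(seed) -> dict[str, np.random.SeedSequence]:
    """One root seed; one deterministic substream per condition, in the
    fixed order of :data:`CONDITIONS`."""
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(len(CONDITIONS))
    return dict(zip(CONDITIONS, children))


def predict_summaries(
    params: ParticipantParams, config: LV05Config, seed
) -> SummaryPrediction:
    """Predicted (mean RT, interference effect) in ms for one participant.

    effect_ms = mean(rt | multiple_match) - mean(rt | single_match); a
    negative value is facilitation.  mean_rt_ms is the average of the two
    condition means.  Both are Monte-Carlo estimates over
    ``config.n_trials`` races per condition, with per-condition random
    substreams spawned deterministically from ``seed``.
    """
    seeds = _condition_seeds(seed)
    means = {}
    variances = {}
    for cond in CONDITIONS:
        trials = simulate_retrieval_trials(
            params, config, ConditionSchedule.for_condition(cond), config.n_trials, seeds[cond]
        )
        rt_ms = trials.rt * config.ms_per_second
        means[cond] = rt_ms.mean()
        variances[cond] = rt_ms.var(ddof=1) / config.n_trials if config.n_trials > 1 else 0.0
    effect = means["multiple_match"] - means["single_match"]
    mean_rt = 0.5 * (means["multiple_match"] + means["single_match"])
    se_effect = float(np.sqrt(variances["multiple_match"] + variances["single_match"]))
    return SummaryPrediction(
        mean_rt_ms=float(mean_rt),
        effect_ms=float(effect),
        se_mean_rt_ms=0.5 * se_effect,
        se_effect_ms=se_effect,
        n_trials=config.n_trials,
        condition_means_ms={k: float(v) for k, v in means.items()},
    )


_QUAD_ABS_TOL = 1e-9  # seconds; well inside the documented 1e-6 s contract


class QuadratureError(RuntimeError):
    """Raised when the latency integral fails to converge."""


def expected_latency_quadrature(
    params: ParticipantParams, config: LV05Config, schedule: ConditionSchedule
) -> float:
    """Deterministic mean retrieval latency (seconds) by 1-D quadrature.

    Integrates LF * exp(-f * x) against the density of the maximum of the
    two independent normal activations,
    ``p_max(x) = phi_t(x) Phi_d(x) + phi_d(x) Phi_t(x)``.
    Absolute tolerance is better than 1e-6 s.  With sigma = 0 the maximum is
    deterministic and the closed form is returned.
    """
    a_t, a_d = mean_activations(params.CW, config, schedule)
    f, s = config.f, config.sigma
    if s == 0.0:
        return float(params.LF * np.exp(-f * max(a_t, a_d)))

    # E[g(max)] split over which chunk wins; each term integrated in the
    # winner's standardized coordinate so the scale is right for any sigma
    def term(a_win, a_lose):
        def integrand(u):
            x = a_win + s * u
            return (
                params.LF
                * np.exp(-f * x)
                * stats.norm.pdf(u)
                * stats.norm.cdf((x - a_lose) / s)
            )

        return integrate.quad(integrand, -10.0, 10.0, epsabs=_QUAD_ABS_TOL / 2, limit=200)

    v1, e1 = term(a_t, a_d)
    v2, e2 = term(a_d, a_t)
    err = e1 + e2  # mass outside +-10 standardized units is < 1e-23
    if err > 1e-6:
        raise QuadratureError(
            f"latency quadrature error estimate {err:.2e} s exceeds 1e-6 s "
            f"(a_t={a_t}, a_d={a_d}, f={f}, sigma={s})"
        )
    return float(v1 + v2)


def expected_effect_quadrature(params: ParticipantParams, config: LV05Config) -> float:
    """Deterministic interference effect (ms): E[rt|mm] - E[rt|sm]."""
    mm = expected_latency_quadrature(
        params, config, ConditionSchedule.for_condition("multiple_match")
    )
    sm = expected_latency_quadrature(
        params, config, ConditionSchedule.for_condition("single_match")
    )
    return float((mm - sm) * config.ms_per_second)


def expected_mean_rt_quadrature(params: ParticipantParams, config: LV05Config) -> float:
    """Deterministic grand-mean RT (ms) across the two conditions."""
    mm = expected_latency_quadrature(
        params, config, ConditionSchedule.for_condition("multiple_match")
    )
    sm = expected_latency_quadrature(
        params, config, ConditionSchedule.for_condition("single_match")
    )
    return float(0.5 * (mm + sm) * config.ms_per_second)


def effect_surface(
    lf_grid, cw_grid, config: LV05Config | None = None
):
    """Interference-effect surface over a latency-factor x cue-weighting grid.

    Returns a tidy DataFrame (LF, CW, effect_ms) computed with the
    deterministic quadrature oracle: the effect grows linearly in LF and
    attenuates as CW rises.
    """
    import pandas as pd

    config = config or LV05Config()
    rows = []
    for lf in np.asarray(lf_grid, dtype=float):
        for cw in np.asarray(cw_grid, dtype=float):
            eff = expected_effect_quadrature(ParticipantParams(LF=lf, CW=cw), config)
            rows.append({"LF": lf, "CW": cw, "effect_ms": eff})
    return pd.DataFrame(rows)
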