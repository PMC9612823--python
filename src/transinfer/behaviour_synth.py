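"""Synthetic behavioural cohorts for the in-scanner task.

Generates trial-level response tables with the statistical structure the
downstream analyses assume: binomial premise/inference counts over 8
repetitions per discrimination driven by participant-level retrieval
probabilities, a controllable AND or OR generative regime with a true kappa,
independent missing responses (default 1.81% of trials), and
gamma-distributed latencies truncated at the 3-second response window.

The default cohort mirrors the study design: 34 participants, training
method (interleaved vs progressive) between subjects, session (recent vs
remote) within subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .inference_models import generalisation_prob, mediating_sets
from .task_design import (
    N_SCAN_REPS,
    SESSIONS,
    inferred_pairs,
    premise_pairs,
)

DEFAULT_N_PARTICIPANTS = 34
DEFAULT_MISS_RATE = 0.0181
RESPONSE_WINDOW_S = 3.0

#: Population distribution of true retrieval probabilities.  Premise accuracy
#: in the study was near ceiling in every condition, so r_p is drawn from
#: Beta(8, 2) (mean 0.8) by default; configurable.
DEFAULT_RETRIEVAL_BETA = (8.0, 2.0)

#: Latency model: gamma with fixed shape; the mean is log-linear in trial
#: type (inferred trials slower by the given multiplier).
DEFAULT_LATENCY_SHAPE = 6.0
DEFAULT_PREMISE_MEAN_S = 1.1
DEFAULT_INFERRED_MULTIPLIER = 1.25


@dataclass
class ParticipantProfile:
    """Ground-truth generative parameters for one synthetic participant."""

    id: int
    training_method: str  # interleaved | progressive
    regime: str  # AND | OR
    kappa_true: float
    retrieval_probs: dict[str, dict[str, float]]  # session -> premise -> r
    miss_rate: float = DEFAULT_MISS_RATE
    latency_shape: float = DEFAULT_LATENCY_SHAPE
    latency_mean_premise: float = DEFAULT_PREMISE_MEAN_S
    latency_inferred_multiplier: float = DEFAULT_INFERRED_MULTIPLIER

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa_true <= 1.0:
            raise ValueError("kappa_true must lie in [0, 1]")
        if not 0.0 <= self.miss_rate < 1.0:
            raise ValueError("miss_rate must lie in [0, 1)")
        for session, probs in self.retrieval_probs.items():
            if len(probs) != 6:
                raise ValueError(f"expected 6 retrieval probs for {session}")
            for r in probs.values():
                if not 0.0 <= r <= 1.0:
                    raise ValueError("retrieval probabilities must lie in [0, 1]")


def simulate_premise_responses(r: float, n: int, rng) -> int:
    """Correct count from the retrieve-then-guess process at rate r.

    Each trial is correct with probability r + (1 - r)/2 = (1 + r)/2.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    return int(rng.binomial(n, (1.0 + r) / 2.0))


def simulate_inference_responses(
    profile: ParticipantProfile, session: str, rng, n: int = N_SCAN_REPS
) -> dict[str, int]:
    """Correct counts per inferred pair under the profile's regime.

    g is computed from the profile's true retrieval probabilities and kappa
    (AND: product over the mediating chain; OR: either end premise), then
    counts are drawn from the g-then-guess process.
    """
    rng = np.random.default_rng(rng)
    probs = profile.retrieval_probs[session]
    out = {}
    for disc in inferred_pairs(session):
        a_names, o_names = mediating_sets(disc)
        g = generalisation_prob(
            profile.regime,
            profile.kappa_true,
            [probs[p] for p in a_names],
            [probs[p] for p in o_names],
        )
        out[disc.name] = int(rng.binomial(n, (1.0 + g) / 2.0))
    return out


def simulate_missingness(
    dataset: pd.DataFrame, miss_rate: float = DEFAULT_MISS_RATE, seed: int = 0
) -> pd.DataFrame:
    """Flag each trial missing independently with probability miss_rate.

    Missing trials get correct = NaN and latency = NaN.
    """
    if not 0.0 <= miss_rate < 1.0:
        raise ValueError("miss_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    miss = rng.uniform(size=len(out)) < miss_rate
    out.loc[miss, "correct"] = np.nan
    if "latency" in out.columns:
        out.loc[miss, "latency"] = np.nan
    return out


def _truncated_gamma(shape: float, mean: float, size: int, rng,
                     upper: float = RESPONSE_WINDOW_S) -> np.ndarray:
    """Gamma draws conditioned on being below the response window."""
    if shape <= 0 or mean <= 0:
        raise ValueError("gamma parameters must be positive")
    scale = mean / shape
    f_upper = gamma_dist.cdf(upper, shape, scale=scale)
    u = rng.uniform(0.0, f_upper, size=size)
    return gamma_dist.ppf(u, shape, scale=scale)


def simulate_latencies(profile: ParticipantProfile, dataset: pd.DataFrame,
                       seed: int = 0) -> pd.DataFrame:
    """Attach gamma latencies to responded trials.

    Mean latency is multiplicative in trial type (log-linear, matching the
    gamma/log-link analysis model); draws are truncated at the 3 s window.
    """
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    out["latency"] = np.nan
    responded = out["correct"].notna()
    for ttype, mult in (("premise", 1.0),
                        ("inferred", profile.latency_inferred_multiplier)):
        sel = responded & (out["trial_type"] == ttype)
        out.loc[sel, "latency"] = _truncated_gamma(
            profile.latency_shape, profile.latency_mean_premise * mult,
            int(sel.sum()), rng,
        )
    return out


@dataclass
class CohortConfig:
    """Generative settings for a synthetic cohort."""

    n_participants: int = DEFAULT_N_PARTICIPANTS
    regime: str = "OR"
    kappa: float = 0.9
    retrieval_beta: tuple[float, float] = DEFAULT_RETRIEVAL_BETA
    miss_rate: float = DEFAULT_MISS_RATE
    latency_shape: float = DEFAULT_LATENCY_SHAPE
    latency_mean_premise: float = DEFAULT_PREMISE_MEAN_S
    latency_inferred_multiplier: float = DEFAULT_INFERRED_MULTIPLIER
    #: Optional per-method kappa override, e.g. {"interleaved": 0.6,
    #: "progressive": 0.95}, for cohorts with a method effect.
    kappa_by_method: dict[str, float] | None = None


def make_profiles(config: CohortConfig, seed: int = 0) -> list[ParticipantProfile]:
    """Draw participant profiles; training method alternates between subjects."""
    rng = np.random.default_rng(seed)
    a, b = config.retrieval_beta
    profiles = []
    for pid in range(1, config.n_participants + 1):
        method = "interleaved" if pid % 2 else "progressive"
        kappa = config.kappa
        if config.kappa_by_method is not None:
            kappa = config.kappa_by_method[method]
        probs = {
            session: {d.name: float(rng.beta(a, b)) for d in premise_pairs(session)}
            for session in SESSIONS
        }
        profiles.append(
            ParticipantProfile(
                id=pid, training_method=method, regime=config.regime,
                kappa_true=kappa, retrieval_probs=probs,
                miss_rate=config.miss_rate,
                latency_shape=config.latency_shape,
                latency_mean_premise=config.latency_mean_premise,
                latency_inferred_multiplier=config.latency_inferred_multiplier,
            )
        )
    return profiles


def simulate_participant(profile: ParticipantProfile, seed: int = 0) -> pd.DataFrame:
    """Trial-level table for one participant across both sessions."""
    rng = np.random.default_rng(seed)
    rows = []
    for session in SESSIONS:
        probs = profile.retrieval_probs[session]
        for disc in premise_pairs(session):
            k = simulate_premise_responses(probs[disc.name], N_SCAN_REPS, rng)
            correct = rng.permutation(
                np.concatenate([np.ones(k), np.zeros(N_SCAN_REPS - k)])
            )
            for t in range(N_SCAN_REPS):
                rows.append((profile.id, profile.training_method, session,
                             disc.name, "premise", disc.distance, t + 1,
                             correct[t]))
        inf_counts = simulate_inference_responses(profile, session, rng)
        for disc in inferred_pairs(session):
            k = inf_counts[disc.name]
            correct = rng.permutation(
                np.concatenate([np.ones(k), np.zeros(N_SCAN_REPS - k)])
            )
            for t in range(N_SCAN_REPS):
                rows.append((profile.id, profile.training_method, session,
                             disc.name, "inferred", disc.distance, t + 1,
                             correct[t]))
    df = pd.DataFrame(
        rows,
        columns=["participant", "training_method", "session", "pair",
                 "trial_type", "distance", "trial", "correct"],
    )
    df = simulate_missingness(df, profile.miss_rate,
                              seed=int(rng.integers(2**31)))
    df = simulate_latencies(profile, df, seed=int(rng.integers(2**31)))
    return df


def generate_cohort(config: CohortConfig | None = None, seed: int = 0
                    ) -> tuple[pd.DataFrame, list[ParticipantProfile]]:
    """Full synthetic cohort: concatenated trial tables + ground truth.

    Reproducible: identical (config, seed) give identical datasets.
    """
    config = config or CohortConfig()
    profiles = make_profiles(config, seed=seed)
    ss = np.random.SeedSequence(seed)
    part_seeds = ss.spawn(len(profiles))
    frames = [
        simulate_participant(prof, seed=int(s.generate_state(1)[0] % 2**31))
        for prof, s in zip(profiles, part_seeds)
    ]
    return pd.concat(frames, ignore_index=True), profiles
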