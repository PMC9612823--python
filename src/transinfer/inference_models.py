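"""AND/OR descriptive models of transitive-inference performance.

Both models predict a participant's inference accuracy from their premise
accuracy alone.  Memory for each premise discrimination p is parameterised by
a retrieval probability r_p; the probability of k_p correct responses out of
n = 8 test trials follows a retrieve-then-guess process (correct with
probability r_p, otherwise a coin flip).  Normalising the resulting function
of r_p gives a likelihood, from which plausible r_p values are drawn by
inverse-transform sampling.

For an inferred pair i the generalisation probability g_i is

* AND (retrieval-based): kappa * prod(r_p) over all mediating premises A_i —
  every link of the chain spanning the pair must be retrieved;
* OR (encoding-based): kappa * (1 - prod(1 - r_p)) over the two end premises
  O_i — recalling either the preferred or the avoided stimulus suffices.

kappa in [0, 1] is the probability of engaging memory-guided generalisation
at all (otherwise the participant guesses).  A single kappa per
participant/condition is fitted by minimising the cross-entropy H, the mean
negative log of the Monte-Carlo-averaged probability of the observed
inference counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import comb, gammaln
from scipy.stats import spearmanr

from .task_design import Discrimination, premise_pairs

N_TRIALS = 8
GRID_SIZE = 2001
MODELS = ("AND", "OR")


def premise_prob(k, n, r):
    """Probability of k of n correct under retrieve-then-guess with rate r.

    Closed form: C(n, k) ((1+r)/2)^k ((1-r)/2)^(n-k) — a binomial with
    per-trial success probability r + (1-r)/2.
    """
    k = np.asarray(k)
    r = np.asarray(r, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("k must satisfy 0 <= k <= n")
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("r must lie in [0, 1]")
    p = (1.0 + r) / 2.0
    return comb(n, k) * p**k * (1.0 - p) ** (n - k)


def premise_prob_sum(k: int, n: int, r: float) -> float:
    """Literal sum over the number of successfully retrieved trials m.

    Equivalent to :func:`premise_prob`; kept as the explicit two-stage
    formulation (m trials retrieved and correct, k-m of the n-m guesses
    correct) for cross-checking.
    """
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if r == 1.0:  # degenerate: every trial retrieved and correct
        return 1.0 if k == n else 0.0
    total = 0.0
    for m in range(k + 1):
        logcoef = (
            gammaln(n + 1) - gammaln(m + 1) - gammaln(k - m + 1) - gammaln(n - k + 1)
        )
        with np.errstate(divide="ignore"):
            term = np.exp(
                logcoef
                + m * np.log(r if r > 0 else 1.0)
                + (n - m) * np.log1p(-r)
                + (n - m) * np.log(0.5)
            )
        if r == 0 and m > 0:
            term = 0.0
        total += term
    return float(total)


def inference_prob(k, n, g):
    """Probability of k of n correct inference responses at generalisation g.

    Same retrieve-then-guess form as :func:`premise_prob` with g in place
    of r.
    """
    return premise_prob(k, n, g)


@dataclass
class PremiseLikelihood:
    """Normalised likelihood L(r | k, n) on a dense grid over [0, 1]."""

    k: int
    n: int
    r_grid: np.ndarray
    pr: np.ndarray
    c: float
    L: np.ndarray
    cdf: np.ndarray

    def sample(self, u) -> np.ndarray:
        """Inverse-transform sample: r such that the cumulative likelihood
        up to r equals u."""
        u = np.asarray(u, dtype=float)
        if np.any(u < 0) or np.any(u > 1):
            raise ValueError("u must lie in [0, 1]")
        return np.interp(u, self.cdf, self.r_grid)


def build_likelihood(k: int, n: int = N_TRIALS, grid_size: int = GRID_SIZE) -> PremiseLikelihood:
    """Construct L(r | k, n) by trapezoid quadrature on a dense r grid."""
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    r = np.linspace(0.0, 1.0, grid_size)
    pr = premise_prob(k, n, r)
    c = float(np.trapezoid(pr, r))
    L = pr / c
    cdf = np.concatenate([[0.0], np.cumsum((L[1:] + L[:-1]) * np.diff(r) / 2.0)])
    cdf /= cdf[-1]
    return PremiseLikelihood(k=k, n=n, r_grid=r, pr=pr, c=c, L=L, cdf=cdf)


def sample_r(likelihood: PremiseLikelihood, u) -> np.ndarray:
    return likelihood.sample(u)


def mediating_sets(discrimination: Discrimination) -> tuple[list[str], list[str]]:
    """Premise identities mediating an inferred pair.

    Returns (A, O): A is the chain of adjacent premises spanning the pair
    (|A| = transitive distance); O holds the first and last of that chain
    (the contingencies naming the preferred and the avoided stimulus).  At
    distance 2 the two coincide with the full chain.
    """
    if discrimination.trial_type != "inferred":
        raise ValueError("mediating sets are defined for inferred pairs only")
    names = [d.name for d in premise_pairs(discrimination.session)]
    i0 = discrimination.high.rank
    chain = names[i0 : i0 + discrimination.distance]
    return chain, [chain[0], chain[-1]]


def generalisation_prob(model: str, kappa: float, a_samples, o_samples=None):
    """g under the AND or OR model for one set of sampled retrieval probs."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if not 0 <= kappa <= 1:
        raise ValueError("kappa must lie in [0, 1]")
    a = np.asarray(a_samples, dtype=float)
    if a.size == 0:
        raise ValueError("empty sample set")
    if model == "AND":
        return kappa * np.prod(a, axis=-1)
    o = a if o_samples is None else np.asarray(o_samples, dtype=float)
    if o.size == 0:
        raise ValueError("empty sample set")
    return kappa * (1.0 - np.prod(1.0 - o, axis=-1))


@dataclass
class ModelFit:
    """One participant/condition fit of the AND or OR model."""

    model: str
    kappa_hat: float
    H: float
    per_inference: pd.DataFrame  # pair, distance, k_obs, prob, expected_k
    n_iter: int
    seed: int
    I: int
    converged: bool


def _iteration_factors(
    premise_counts: dict[str, int],
    inferences: list[tuple[Discrimination, int]],
    model: str,
    n_iter: int,
    rng: np.random.Generator,
    n: int = N_TRIALS,
) -> np.ndarray:
    """Per-iteration multiplier q such that g = kappa * q, per inference.

    Common random numbers: one (n_iter x 6) block of uniforms drives every
    kappa evaluation, keeping the Monte-Carlo objective smooth in kappa.
    Returns an array (n_inferences, n_iter).
    """
    names = sorted(premise_counts)
    likes = {p: build_likelihood(premise_counts[p], n) for p in names}
    u = rng.uniform(size=(n_iter, len(names)))
    draws = {p: likes[p].sample(u[:, j]) for j, p in enumerate(names)}
    q = np.empty((len(inferences), n_iter))
    for i, (disc, _k) in enumerate(inferences):
        a_names, o_names = mediating_sets(disc)
        if model == "AND":
            q[i] = np.prod([draws[p] for p in a_names], axis=0)
        else:
            q[i] = 1.0 - np.prod([1.0 - draws[p] for p in o_names], axis=0)
    return q


def fit_model(
    premise_counts: dict[str, int],
    inference_counts: list[tuple[Discrimination, int]],
    model: str,
    n_iter: int = 10_000,
    seed: int = 0,
    n: int = N_TRIALS,
) -> ModelFit:
    """Fit kappa for one participant/condition by Monte-Carlo cross-entropy.

    ``premise_counts`` maps premise name -> observed correct count; each
    inference is an (inferred Discrimination, observed count) pair.  Per
    iteration, retrieval probabilities are drawn from the premise
    likelihoods; the probability of each observed inference count is averaged
    over iterations and kappa minimises H = -(1/I) sum_i log mean_iter
    Pr(k_i | n, g_i(kappa)).  Bounded scalar optimisation with multi-start.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    rng = np.random.default_rng(seed)
    q = _iteration_factors(premise_counts, inference_counts, model, n_iter, rng, n)
    k_obs = np.array([k for _, k in inference_counts])
    I = len(inference_counts)

    def objective(kappa: float) -> float:
        g = kappa * q  # (I, n_iter)
        pr_hat = np.empty(I)
        for i in range(I):
            pr_hat[i] = inference_prob(k_obs[i], n, g[i]).mean()
        return float(-np.mean(np.log(pr_hat)))

    best = None
    converged = True
    for lo, hi in ((0.0, 0.5), (0.25, 0.75), (0.5, 1.0)):
        res = minimize_scalar(objective, bounds=(lo, hi), method="bounded")
        if not res.success:
            converged = False
        if best is None or res.fun < best.fun:
            best = res
    # Guard against flat objectives near the boundary.
    for edge in (0.0, 1.0):
        if objective(edge) < best.fun:
            best_x, best_fun = edge, objective(edge)
            break
    else:
        best_x, best_fun = float(best.x), float(best.fun)

    g_hat = best_x * q
    rows = []
    for i, (disc, k) in enumerate(inference_counts):
        prob = float(inference_prob(k, n, g_hat[i]).mean())
        expected = float(n * (1.0 + g_hat[i].mean()) / 2.0)
        rows.append(
            {"pair": disc.name, "session": disc.session, "distance": disc.distance,
             "k_obs": int(k), "prob": prob, "expected_k": expected}
        )
    return ModelFit(
        model=model, kappa_hat=best_x, H=best_fun,
        per_inference=pd.DataFrame(rows), n_iter=n_iter, seed=seed, I=I,
        converged=converged,
    )


def expected_correct(g, n: int = N_TRIALS):
    """Expected correct count at generalisation probability g: n(1+g)/2."""
    g = np.asarray(g, dtype=float)
    return n * (1.0 + g) / 2.0


def fit_participant(
    dataset: pd.DataFrame,
    participant,
    session: str,
    n_iter: int = 10_000,
    seed: int = 0,
) -> dict[str, ModelFit]:
    """Fit both models to one participant/session slice of a behavioural table.

    ``dataset`` uses the trial-level layout of :mod:`transinfer.behaviour_synth`
    (columns participant, session, pair, trial_type, correct).  Missing
    responses are resampled as fair guesses before counting, mirroring the
    accuracy analysis.
    """
    from .behaviour_stats import resample_missing
    from .task_design import inferred_pairs

    sl = dataset[(dataset["participant"] == participant) & (dataset["session"] == session)]
    sl = resample_missing(sl, seed=seed)
    counts = sl.groupby(["trial_type", "pair"])["correct"].sum()
    premise_counts = {
        name: int(counts.get(("premise", name), 0))
        for name in (d.name for d in premise_pairs(session))
    }
    inference_counts = [
        (d, int(counts.get(("inferred", d.name), 0))) for d in inferred_pairs(session)
    ]
    return {
        m: fit_model(premise_counts, inference_counts, m, n_iter=n_iter, seed=seed + j)
        for j, m in enumerate(MODELS)
    }


def compare_models(fits: pd.DataFrame, n_boot: int = 10_000, seed: int = 0) -> dict:
    """Cohort-level AND-vs-OR comparison.

    ``fits`` has one row per participant/session with columns participant,
    H_AND, H_OR, rho_AND, rho_OR (Spearman correlations between observed and
    model-expected inference counts; rows with undefined rho are excluded).
    Returns mean statistics and a bootstrapped paired t-test on
    rho_OR - rho_AND (participant-level resampling of the per-participant
    differences, seeded).
    """
    valid = fits.dropna(subset=["rho_AND", "rho_OR"])
    d = (valid["rho_OR"] - valid["rho_AND"]).to_numpy()
    rng = np.random.default_rng(seed)
    m = len(d)
    out = {
        "n": int(m),
        "n_excluded": int(len(fits) - m),
        "mean_H_AND": float(fits["H_AND"].mean()),
        "mean_H_OR": float(fits["H_OR"].mean()),
        "mean_rho_AND": float(valid["rho_AND"].mean()),
        "mean_rho_OR": float(valid["rho_OR"].mean()),
    }
    if m < 2 or np.allclose(d, d[0]):
        out.update({"t_boot": 0.0 if m and np.allclose(d, 0) else np.nan,
                    "se_boot": 0.0, "mean_diff": float(np.mean(d)) if m else np.nan})
        return out
    boot_means = np.empty(n_boot)
    for b in range(n_boot):
        boot_means[b] = d[rng.integers(0, m, size=m)].mean()
    se = float(boot_means.std(ddof=1))
    out.update(
        {"mean_diff": float(d.mean()), "se_boot": se,
         "t_boot": float(d.mean() / se) if se > 0 else np.inf,
         "ci95": [float(np.quantile(boot_means, 0.025)),
                  float(np.quantile(boot_means, 0.975))]}
    )
    return out


def spearman_observed_expected(fit: ModelFit) -> float:
    """Spearman rho between observed and expected inference counts.

    Returns NaN when either side is constant (undefined correlation); such
    rows are flagged and excluded at the cohort level.
    """
    tab = fit.per_inference
    if tab["k_obs"].nunique() < 2 or tab["expected_k"].nunique() < 2:
        return float("nan")
    rho, _ = spearmanr(tab["k_obs"], tab["expected_k"])
    return float(rho)
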