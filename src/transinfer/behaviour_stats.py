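"""Regression designs for in-scanner accuracy and latency.

Accuracy is modelled as a binomial count (correct responses out of 8 per
discrimination) with a logit link; latency (correct trials only) as gamma
with a log link.  Both designs share 12 fixed-effect columns: an intercept,
three binary-coded factors (trial type, training method, session), a
mean-centred transitive-distance covariate applied to inference trials only,
and all estimable interactions.  Missing responses are resampled as fair
guesses before the accuracy analysis.

Mixed-effects estimation is delegated to statsmodels.  When the mixed solver
is unavailable or fails, the fit downgrades to a fixed-effects GLM with
cluster-robust (by participant) standard errors, flagged in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: +-0.5 contrast coding keeps main effects interpretable at the grand mean.
BINARY_CODES = {
    "trial_type": {"premise": -0.5, "inferred": 0.5},
    "training_method": {"interleaved": -0.5, "progressive": 0.5},
    "session": {"recent": -0.5, "remote": 0.5},
}

FIXED_EFFECTS = [
    "intercept", "trial_type", "training_method", "session",
    "trial_type:training_method", "trial_type:session",
    "training_method:session", "trial_type:training_method:session",
    "distance", "distance:training_method", "distance:session",
    "distance:training_method:session",
]


def resample_missing(dataset: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Replace missing responses by fair random guesses (Bernoulli 1/2).

    Avoids accuracy biases from failures to respond; deterministic given the
    seed.  Latencies stay absent for resampled trials.
    """
    out = dataset.copy()
    miss = out["correct"].isna()
    if miss.any():
        rng = np.random.default_rng(seed)
        out.loc[miss, "correct"] = rng.integers(0, 2, size=int(miss.sum())).astype(float)
    return out


def transitive_slope(dataset: pd.DataFrame, participant, session: str) -> float:
    """Pearson correlation between transitive distance and inference accuracy.

    Computed per participant and session over the six inferred
    discriminations (distances 2, 2, 2, 3, 3, 4).  Positive slopes are the
    signature of encoding-based generalisation, negative of retrieval-based.
    Returns NaN (flagged null, excluded from covariate use) when accuracy
    has zero variance.
    """
    sl = dataset[
        (dataset["participant"] == participant)
        & (dataset["session"] == session)
        & (dataset["trial_type"] == "inferred")
    ]
    acc = sl.groupby("pair").agg(accuracy=("correct", "mean"),
                                 distance=("distance", "first"))
    if len(acc) < 2 or acc["accuracy"].nunique() < 2:
        return float("nan")
    return float(np.corrcoef(acc["distance"], acc["accuracy"])[0, 1])


@dataclass
class RegressionDesign:
    """A fixed-effects matrix plus outcome and random-effects metadata."""

    outcome: pd.DataFrame  # accuracy: columns (successes, failures); latency: latency
    X: pd.DataFrame  # 12 fixed-effect columns
    groups: pd.Series  # participant ids, for random effects / clustering
    family: str  # "binomial" | "gamma"
    random_effects: dict


def _fixed_effects(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("trial_type", "training_method", "session"):
        bad = set(df[col]) - set(BINARY_CODES[col])
        if bad:
            raise ValueError(f"unknown {col} labels: {sorted(bad)}")
    tt = df["trial_type"].map(BINARY_CODES["trial_type"]).to_numpy()
    me = df["training_method"].map(BINARY_CODES["training_method"]).to_numpy()
    se = df["session"].map(BINARY_CODES["session"]).to_numpy()
    inferred = df["trial_type"].eq("inferred").to_numpy()
    # Distance applies to inference trials only: centred over inference rows,
    # premise rows coded at the centred baseline (0).
    dist = df["distance"].to_numpy(dtype=float)
    dist = np.where(inferred, dist - dist[inferred].mean(), 0.0)
    X = pd.DataFrame(
        {
            "intercept": 1.0, "trial_type": tt, "training_method": me,
            "session": se, "trial_type:training_method": tt * me,
            "trial_type:session": tt * se, "training_method:session": me * se,
            "trial_type:training_method:session": tt * me * se,
            "distance": dist, "distance:training_method": dist * me,
            "distance:session": dist * se,
            "distance:training_method:session": dist * me * se,
        },
        index=df.index,
    )
    return X[FIXED_EFFECTS]


def build_accuracy_design(dataset: pd.DataFrame, seed: int = 0) -> RegressionDesign:
    """Binomial design: counts of 8 per participant x session x pair."""
    data = resample_missing(dataset, seed=seed)
    agg = (
        data.groupby(["participant", "training_method", "session", "pair",
                      "trial_type", "distance"], as_index=False)
        .agg(successes=("correct", "sum"), n=("correct", "size"))
    )
    agg["failures"] = agg["n"] - agg["successes"]
    X = _fixed_effects(agg)
    return RegressionDesign(
        outcome=agg[["successes", "failures"]].astype(float),
        X=X, groups=agg["participant"], family="binomial",
        random_effects={"participant": ["intercept", "within-subject slopes"],
                        "discrimination": ["intercept"]},
    )


def build_latency_design(dataset: pd.DataFrame) -> RegressionDesign:
    """Gamma/log design on correct-trial latencies."""
    data = dataset[(dataset["correct"] == 1) & dataset["latency"].notna()].copy()
    if (data["latency"] <= 0).any():
        raise ValueError("latencies must be positive")
    X = _fixed_effects(data)
    return RegressionDesign(
        outcome=data[["latency"]], X=X, groups=data["participant"],
        family="gamma",
        random_effects={"participant": ["intercept", "within-subject slopes"],
                        "discrimination": ["intercept"]},
    )


@dataclass
class GlmmResult:
    """Coefficient table plus estimation provenance."""

    coefficients: pd.DataFrame  # index = effect, columns coef, se, t, p
    engine: str  # "mixed" | "cluster-glm"
    downgraded: bool
    converged: bool


def _cluster_glm(design: RegressionDesign) -> GlmmResult:
    if design.family == "binomial":
        endog = design.outcome[["successes", "failures"]].to_numpy()
        family = sm.families.Binomial()
    else:
        endog = design.outcome["latency"].to_numpy()
        family = sm.families.Gamma(link=sm.families.links.Log())
    model = sm.GLM(endog, design.X.to_numpy(), family=family)
    res = model.fit(cov_type="cluster",
                    cov_kwds={"groups": design.groups.to_numpy()})
    # t reference with G-1 df: standard small-sample practice for clustered SEs.
    from scipy.stats import t as t_dist

    df = design.groups.nunique() - 1
    tvals = res.params / res.bse
    coefs = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "t": tvals,
         "p": 2 * t_dist.sf(np.abs(tvals), df)},
        index=design.X.columns,
    )
    return GlmmResult(coefficients=coefs, engine="cluster-glm",
                      downgraded=True, converged=res.converged)


def _mixed_binomial(design: RegressionDesign) -> GlmmResult:
    """Variational-Bayes binomial GLMM with participant random intercepts."""
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    # Expand counts to Bernoulli rows for the mixed solver.
    reps = (design.outcome["successes"] + design.outcome["failures"]).astype(int)
    rows, y = [], []
    for i, (s, n) in enumerate(zip(design.outcome["successes"].astype(int), reps)):
        rows.extend([i] * n)
        y.extend([1] * s + [0] * (n - s))
    rows = np.asarray(rows)
    exog = design.X.to_numpy()[rows]
    groups = design.groups.to_numpy()[rows]
    levels, codes = np.unique(groups, return_inverse=True)
    exog_vc = np.zeros((len(rows), len(levels)))
    exog_vc[np.arange(len(rows)), codes] = 1.0
    model = BinomialBayesMixedGLM(
        np.asarray(y, dtype=float), exog, exog_vc, ident=np.zeros(len(levels), dtype=int)
    )
    res = model.fit_vb()
    k = design.X.shape[1]
    coef = res.fe_mean
    se = res.fe_sd
    t = coef / se
    from scipy.stats import norm

    coefs = pd.DataFrame(
        {"coef": coef[:k], "se": se[:k], "t": t[:k],
         "p": 2 * norm.sf(np.abs(t[:k]))},
        index=design.X.columns,
    )
    return GlmmResult(coefficients=coefs, engine="mixed", downgraded=False,
                      converged=True)


def fit_glmm(design: RegressionDesign, engine: str = "auto") -> GlmmResult:
    """Estimate a design's coefficients.

    engine="mixed" requests the mixed-effects solver (binomial outcomes
    only; statsmodels has no gamma GLMM, so latency designs always
    downgrade).  engine="cluster" forces the fixed-effects GLM with
    cluster-robust errors.  "auto" tries the mixed solver first and
    downgrades on failure, flagging the result.
    """
    if engine not in ("auto", "mixed", "cluster"):
        raise ValueError("engine must be auto, mixed or cluster")
    if engine == "cluster":
        return _cluster_glm(design)
    if design.family == "binomial":
        try:
            return _mixed_binomial(design)
        except Exception:
            if engine == "mixed":
                raise
            return _cluster_glm(design)
    if engine == "mixed":
        raise ValueError("no mixed-effects solver available for gamma outcomes")
    return _cluster_glm(design)
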