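"""Texture-pattern decomposition and representational similarity analysis.

The 24 per-discrimination beta patterns are linearly decomposed into 14
wall-texture patterns (7 per session) plus one premise-vs-inferred nuisance
component, by multiplying with the pseudoinverse of a 24 x 15 occurrence
matrix.  Pairwise Pearson correlations between texture patterns (restricted
to B..F, since A and G only ever appear in premise trials) are
Fisher-transformed and modelled in linear mixed models as a function of
transitive distance, condition and behavioural covariates, with two nuisance
predictors: co-presentation overlap and simulation-derived correlations
induced by trial timing and the decomposition itself.  Outlying rows are
excluded by a sample-size-dependent standardised-residual rule.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .pattern_synth import (
    NoiseConfig,
    SimulatedScan,
    calibrate_adaptation,
    lss_estimate,
    make_ground_truth,
    simulate_scan,
    texture_order,
)
from .task_design import LABELS, SESSIONS, ScanTrialList, build_hierarchy

#: Textures admitted to the similarity analysis (interior of the hierarchy).
INTERIOR = "BCDEF"

Z_CLIP = float(np.arctanh(1.0 - 1e-12))


@dataclass
class OccurrenceDesign:
    """24 x 15 texture-occurrence matrix X and its pseudoinverse T."""

    X: pd.DataFrame  # rows = (session, pair), columns = texture/trial-type
    T: np.ndarray  # (15, 24)

    @property
    def columns(self) -> list:
        return list(self.X.columns)


def build_occurrence_design(trial_type_coding: float = 0.5) -> OccurrenceDesign:
    """Encode each discrimination's textures plus a trial-type contrast.

    Rows follow the (session, pair) order of the LSS output; the first 14
    columns are unit entries for the two presented textures (7 recent then 7
    remote), the 15th codes premise (-coding) vs inferred (+coding) trials.
    """
    order = texture_order()
    col_names = [f"{s}:{lab}" for s, lab in order] + ["trial_type"]
    rows = []
    index = []
    for session in SESSIONS:
        for disc in build_hierarchy(session):
            row = np.zeros(15)
            row[order.index((session, disc.high.label))] = 1.0
            row[order.index((session, disc.low.label))] = 1.0
            row[14] = trial_type_coding if disc.trial_type == "inferred" else -trial_type_coding
            rows.append(row)
            index.append((session, disc.name))
    X = pd.DataFrame(np.vstack(rows), columns=col_names,
                     index=pd.MultiIndex.from_tuples(index, names=["session", "pair"]))
    mat = X.to_numpy()
    if np.linalg.matrix_rank(mat) < 15:
        raise np.linalg.LinAlgError(
            "occurrence design is rank deficient; check the trial-type coding"
        )
    T = np.linalg.pinv(mat)
    return OccurrenceDesign(X=X, T=T)


def decompose_patterns(betas, design: OccurrenceDesign | None = None) -> pd.DataFrame:
    """T @ betas: 15 x V texture patterns (+ trial-type nuisance last row).

    Rows 1-14 are the per-texture voxel patterns; the final row captures the
    overall premise-vs-inferred BOLD difference and is dropped from all
    similarity computations.
    """
    design = design or build_occurrence_design()
    mat = np.asarray(betas)
    if mat.shape[0] != 24:
        raise ValueError(f"expected 24 beta rows, got {mat.shape[0]}")
    if not np.all(np.isfinite(mat)):
        raise ValueError("betas must be finite")
    out = design.T @ mat
    return pd.DataFrame(out, index=design.columns)


def _fisher(r: np.ndarray) -> np.ndarray:
    r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    return np.clip(np.arctanh(r), -Z_CLIP, Z_CLIP)


def _interior_keys(scope: str) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    if scope == "within":
        return [
            ((s, a), (s, b))
            for s in SESSIONS
            for a, b in itertools.combinations(INTERIOR, 2)
        ]
    if scope == "across":
        return [(("recent", a), ("remote", b)) for a in INTERIOR for b in INTERIOR]
    raise ValueError("scope must be 'within' or 'across'")


def pattern_similarity(patterns: pd.DataFrame, scope: str) -> pd.DataFrame:
    """Fisher-z similarities between interior texture patterns.

    within: same-session pairs among B..F (10 per session, distances 1-4);
    across: recent x remote pairs (25, distances 0-4).  Zero-variance
    patterns make the correlation undefined: those rows are flagged
    (``valid`` False) and excluded downstream.
    """
    tex = patterns.iloc[:14]
    if tex.shape[1] < 3:
        raise ValueError("need at least 3 voxels")
    order = texture_order()
    arr = tex.to_numpy()
    sd = arr.std(axis=1)
    rows = []
    for (s1, l1), (s2, l2) in _interior_keys(scope):
        i, j = order.index((s1, l1)), order.index((s2, l2))
        ok = sd[i] > 0 and sd[j] > 0
        r = float(np.corrcoef(arr[i], arr[j])[0, 1]) if ok else np.nan
        if ok and abs(r) >= 1.0 - 1e-12:
            warnings.warn(f"|r|=1 for {s1}:{l1} vs {s2}:{l2}; z clipped")
        rows.append(
            {"texture1": f"{s1}:{l1}", "texture2": f"{s2}:{l2}",
             "session1": s1, "session2": s2, "scope": scope,
             "distance": abs(LABELS.index(l1) - LABELS.index(l2)),
             "z": float(_fisher(np.array(r))) if ok else np.nan,
             "valid": bool(ok)}
        )
    return pd.DataFrame(rows)


def copresentation_nuisance() -> dict[frozenset, float]:
    """Fisher-z phi correlation between texture presence vectors.

    For each admissible texture pair, the binary vectors marking the
    discriminations each texture appears in are correlated over all 24
    discriminations (equal per-discrimination repetition counts make this
    identical to the 192-trial computation) and Fisher-transformed.
    """
    design = build_occurrence_design()
    pres = design.X.to_numpy()[:, :14]
    order = texture_order()
    out = {}
    keys = set(_interior_keys("within")) | set(_interior_keys("across"))
    for (s1, l1), (s2, l2) in keys:
        i, j = order.index((s1, l1)), order.index((s2, l2))
        phi = np.corrcoef(pres[:, i], pres[:, j])[0, 1]
        out[frozenset([f"{s1}:{l1}", f"{s2}:{l2}"])] = float(_fisher(np.array(phi)))
    return out


def simulation_nuisance(
    trial_list: ScanTrialList,
    n_iter: int = 100,
    snr: float = 1.0,
    n_voxels: int = 50,
    seed: int = 0,
    with_noise: bool = True,
    suppression_scale: float = 1.0,
) -> dict[frozenset, float]:
    """Timing/decomposition-induced nuisance correlations, by simulation.

    Per iteration: draw independent normal texture patterns, mix them into a
    scan per the trial timings (with the calibrated repetition suppression),
    re-estimate betas with LSS, decompose, and correlate the recovered
    interior patterns.  Returns the across-iteration mean Fisher z per pair.
    ``snr`` is the ground-truth amplitude over the noise SD.
    """
    if n_iter < 50:
        warnings.warn("n_iter < 50 gives an unstable nuisance estimate")
    rng = np.random.default_rng(seed)
    design = build_occurrence_design()
    adaptation = calibrate_adaptation()
    noise = NoiseConfig(sigma=1.0 if with_noise else 1e-12, rho=0.3)
    keys = set(_interior_keys("within")) | set(_interior_keys("across"))
    acc: dict[frozenset, list[float]] = {
        frozenset([f"{s1}:{l1}", f"{s2}:{l2}"]): [] for (s1, l1), (s2, l2) in keys
    }
    for _ in range(n_iter):
        gt = make_ground_truth(n_voxels=n_voxels, decay_lambda=None,
                               amplitude=snr, seed=int(rng.integers(2**31)))
        scan = simulate_scan(gt, trial_list, noise=noise, adaptation=adaptation,
                             suppression_scale=suppression_scale,
                             seed=int(rng.integers(2**31)))
        betas = lss_estimate(scan)
        patterns = decompose_patterns(betas, design)
        for scope in ("within", "across"):
            sim = pattern_similarity(patterns, scope)
            for _, row in sim.iterrows():
                acc[frozenset([row["texture1"], row["texture2"]])].append(row["z"])
    return {k: float(np.nanmean(v)) for k, v in acc.items()}


def outlier_threshold(n: int) -> float:
    """|Phi^-1((1 - 2^(-1/n)) / 2)|: the residual cut-off at sample size n.

    The bound of a standard normal that contains all n points of a random
    sample 50% of the time; ~2.7 at n = 100, ~3.4 at n = 1000.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(abs(norm.ppf(0.5 * (1.0 - 2.0 ** (-1.0 / n)))))


def behavioural_covariates(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per participant x session inference accuracy and transitive slope."""
    from .behaviour_stats import resample_missing, transitive_slope

    data = resample_missing(dataset, seed=0)
    inf = data[data["trial_type"] == "inferred"]
    acc = (
        inf.groupby(["participant", "session"], as_index=False)
        .agg(accuracy=("correct", "mean"),
             training_method=("training_method", "first"))
    )
    acc["slope"] = [
        transitive_slope(data, p, s)
        for p, s in zip(acc["participant"], acc["session"])
    ]
    return acc


def build_rsa_table(
    cohort_patterns: dict[int, pd.DataFrame],
    behaviour: pd.DataFrame,
    scope: str,
    nuisance_copres: dict[frozenset, float] | None = None,
    nuisance_sim: dict[frozenset, float] | None = None,
) -> pd.DataFrame:
    """Long similarity table ready for the mixed model.

    One row per participant x admissible texture pair, with distance,
    condition, behavioural covariates (session-specific within hierarchies,
    participant means across), and both nuisance predictors.  Rows with
    undefined similarity or missing covariates are dropped.
    """
    nuisance_copres = nuisance_copres or copresentation_nuisance()
    covs = behavioural_covariates(behaviour)
    frames = []
    for pid, patterns in cohort_patterns.items():
        sim = pattern_similarity(patterns, scope)
        sim = sim[sim["valid"]].copy()
        sim["participant"] = pid
        pc = covs[covs["participant"] == pid]
        if pc.empty:
            continue
        sim["training_method"] = pc["training_method"].iloc[0]
        if scope == "within":
            by_sess = pc.set_index("session")
            sim["accuracy"] = sim["session1"].map(by_sess["accuracy"])
            sim["slope"] = sim["session1"].map(by_sess["slope"])
            sim["session"] = sim["session1"]
        else:
            sim["accuracy"] = pc["accuracy"].mean()
            sim["slope"] = pc["slope"].mean()
            sim["session"] = ""
        key = [frozenset([a, b]) for a, b in zip(sim["texture1"], sim["texture2"])]
        sim["nuisance_copres"] = [nuisance_copres[k] for k in key]
        sim["nuisance_sim"] = (
            [nuisance_sim[k] for k in key] if nuisance_sim is not None else 0.0
        )
        frames.append(sim)
    table = pd.concat(frames, ignore_index=True)
    return table.dropna(subset=["z", "accuracy", "slope"]).reset_index(drop=True)


@dataclass
class RsaResult:
    """Mixed-model RSA output with outlier bookkeeping."""

    coefficients: pd.DataFrame  # coef, se, t, p per fixed effect
    n_rows: int
    n_excluded: int
    threshold: float
    engine: str  # "mixed" | "ols"
    downgraded: bool


def _interaction_terms(factors: list[str]) -> list[tuple[str, ...]]:
    """All interaction subsets, excluding any joining accuracy with slope."""
    terms = []
    for k in range(2, len(factors) + 1):
        for combo in itertools.combinations(factors, k):
            if "accuracy" in combo and "slope" in combo:
                continue
            terms.append(combo)
    return terms


def _rsa_design(table: pd.DataFrame, scope: str) -> pd.DataFrame:
    df = table.copy()
    df["method_c"] = df["training_method"].map(
        {"interleaved": -0.5, "progressive": 0.5}
    )
    df["distance_c"] = df["distance"] - df["distance"].mean()
    df["accuracy_c"] = df["accuracy"] - df["accuracy"].mean()
    df["slope_c"] = df["slope"] - df["slope"].mean()
    factors = {"distance": df["distance_c"], "method": df["method_c"],
               "accuracy": df["accuracy_c"], "slope": df["slope_c"]}
    if scope == "within":
        df["session_c"] = df["session"].map({"recent": -0.5, "remote": 0.5})
        factors["session"] = df["session_c"]
    X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    for name, col in factors.items():
        X[name] = col
    for combo in _interaction_terms(list(factors)):
        X[":".join(combo)] = np.prod([factors[f] for f in combo], axis=0)
    # Nuisance predictors enter only when they carry information (the
    # simulation nuisance is optional and may be a disabled constant).
    for col in ("nuisance_copres", "nuisance_sim"):
        if df[col].nunique() > 1:
            X[col] = df[col]
    return X


def _fit_once(y: np.ndarray, X: pd.DataFrame, groups: np.ndarray,
              dist: np.ndarray, engine: str):
    if engine == "mixed":
        exog_re = np.column_stack([np.ones(len(y)), dist])
        model = sm.MixedLM(y, X.to_numpy(), groups=groups, exog_re=exog_re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=False)
        k = X.shape[1]
        params, bse = res.fe_params, res.bse[:k]
        resid = res.resid
    else:
        res = sm.OLS(y, X.to_numpy()).fit(
            cov_type="cluster", cov_kwds={"groups": groups}
        )
        params, bse = res.params, res.bse
        resid = res.resid
    t = params / bse
    coefs = pd.DataFrame(
        {"coef": params, "se": bse, "t": t, "p": 2 * norm.sf(np.abs(t))},
        index=X.columns,
    )
    return coefs, np.asarray(resid)


def fit_rsa_lmm(
    table: pd.DataFrame,
    scope: str = "within",
    engine: str = "auto",
    exclude_delta1: bool = False,
) -> RsaResult:
    """Mixed-model RSA with one outlier-exclusion pass.

    Fixed effects: mean-centred distance, binary-coded method (and session,
    within hierarchies), accuracy and transitive slope, all their
    interactions except accuracy x slope, plus both nuisance predictors.
    Random effects: per-participant intercepts and distance slopes (the full
    study structure is unidentifiable at small voxel counts).  Rows whose
    absolute standardised residual exceeds ``outlier_threshold(n)`` are
    dropped once and the model refitted.  Falls back to OLS with clustered
    errors on mixed-solver failure, with a downgrade flag.
    """
    df = table[table["distance"] >= 2] if exclude_delta1 else table
    df = df.reset_index(drop=True)
    X = _rsa_design(df, scope)
    y = df["z"].to_numpy(dtype=float)
    groups = df["participant"].to_numpy()
    dist = X["distance"].to_numpy()

    def attempt(y_, X_, g_, d_):
        if engine in ("auto", "mixed"):
            try:
                c, r = _fit_once(y_, X_, g_, d_, "mixed")
                return c, r, "mixed", False
            except Exception:
                if engine == "mixed":
                    raise
        c, r = _fit_once(y_, X_, g_, d_, "ols")
        return c, r, "ols", engine != "ols"

    coefs, resid, used, downgraded = attempt(y, X, groups, dist)
    thr = outlier_threshold(len(y))
    std_resid = resid / resid.std(ddof=1)
    keep = np.abs(std_resid) <= thr
    n_excluded = int((~keep).sum())
    if n_excluded:
        coefs, resid, used, downgraded = attempt(
            y[keep], X[keep], groups[keep], dist[keep]
        )
    return RsaResult(coefficients=coefs, n_rows=int(keep.sum()),
                     n_excluded=n_excluded, threshold=thr, engine=used,
                     downgraded=downgraded)


def delta1_sensitivity(table: pd.DataFrame, scope: str = "within",
                       engine: str = "auto") -> RsaResult:
    """Refit the within-hierarchy RSA excluding distance-1 pairs.

    Checks that distance effects are not driven solely by textures shown
    together in the same premise pair.
    """
    return fit_rsa_lmm(table, scope=scope, engine=engine, exclude_delta1=True)
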