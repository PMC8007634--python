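"""The statistical pipeline for the 2AFC duration-discrimination data.

Per subject and law of motion, the probability of judging the comparison
longer is fitted with a binomial GLM (logit link),

    logit P(Y = 1) = eta0 + eta1 * D,

from which the point of subjective equivalence PSE = -eta0/eta1 and the just
noticeable difference JND = log(3)/eta1 follow (log 3 is the logit half-width
between the 25% and 75% points).  With a 1-s reference, the Weber fraction
equals the JND numerically.

Population-level analyses: an IQR outlier rule on per-subject JNDs, a one-way
repeated-measures ANOVA over laws with Holm-corrected paired t-tests, a
binomial-logit GLMM with by-subject random intercept and duration slope (law
dummies and interactions as fixed effects), parametric-bootstrap confidence
intervals for between-law JND/PSE differences, a control GLMM regressing on
initial horizontal distance over the duration-matched control conditions, BIC
selection over a nested model pool, and re-fits of the psychometric model on
alternative stimulus cues (initial speed, dilation rate, elevation rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from . import glmm
from .kinematics import (
    MotionLaw,
    T_REF,
    condition_table,
    get_condition,
    path_for_condition,
    state,
)
from .optics import ObserverGeometry, fixation_crossings, optic_state

logger = logging.getLogger(__name__)

LOG3 = float(np.log(3.0))

#: fixed law order: baseline first (constant tangential velocity)
LAW_ORDER = [
    MotionLaw.CONST_TANGENTIAL,
    MotionLaw.CONST_VERTICAL,
    MotionLaw.GRAVITATIONAL,
]

EXPERIMENTAL_IDS = [1, 2, 3, 4, 5, 6, 7]
CONTROL_SET_IDS = [3, 5, 8, 9]


# ---------------------------------------------------------------------------
# per-subject psychometric GLM


@dataclass(frozen=True)
class PsychometricFit:
    """A fitted per-subject psychometric function and its derived indices."""

    eta0: float
    eta1: float
    pse: float
    jnd: float
    wf: float
    law: MotionLaw | None
    subject_id: str | None
    converged: bool
    deviance: float
    n_trials: int


def fit_psychometric(
    trials: pd.DataFrame,
    predictor: str = "D_comp",
    law: MotionLaw | None = None,
    subject_id: str | None = None,
    require_positive_slope: bool = True,
) -> PsychometricFit:
    """Binomial-logit GLM of ``comparison_longer`` on ``predictor``.

    Expects filtered trials of one subject and law.  Fits flagged as not
    converged (separation, non-positive slope, or fewer than two distinct
    predictor values) should be excluded downstream.

    ``require_positive_slope=False`` is used for putative-cue re-fits, where
    a cue may be anti-correlated with the response and precision is about the
    slope magnitude: the JND is then log(3)/|eta1|.
    """
    agg = (
        trials.groupby(predictor)["comparison_longer"]
        .agg(successes="sum", trials="count")
        .reset_index()
    )
    n_trials = int(agg["trials"].sum())
    if len(agg) < 2:
        return PsychometricFit(
            np.nan, np.nan, np.nan, np.nan, np.nan, law, subject_id, False,
            np.nan, n_trials,
        )
    X = sm.add_constant(agg[predictor].to_numpy(float))
    endog = np.column_stack(
        [agg["successes"].to_numpy(float),
         (agg["trials"] - agg["successes"]).to_numpy(float)]
    )
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with warnings.catch_warnings():
            # near-separation is expected for very steep observers; such fits
            # are caught by the slope sanity check below
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            res = model.fit(maxiter=200)
        eta0, eta1 = float(res.params[0]), float(res.params[1])
        deviance = float(res.deviance)
        ok = bool(res.converged) and np.isfinite(eta1) and abs(eta1) < 1e3
    except Exception as exc:  # separation and friends
        logger.warning("psychometric fit failed (%s/%s): %s", subject_id, law, exc)
        return PsychometricFit(
            np.nan, np.nan, np.nan, np.nan, np.nan, law, subject_id, False,
            np.nan, n_trials,
        )
    bad_sign = eta1 <= 0 if require_positive_slope else eta1 == 0
    if bad_sign or not ok:
        logger.warning(
            "psychometric fit flagged (%s/%s, predictor=%s): eta1=%.3g converged=%s",
            subject_id, law, predictor, eta1, ok,
        )
        return PsychometricFit(
            eta0, eta1, np.nan, np.nan, np.nan, law, subject_id, False,
            deviance, n_trials,
        )
    pse = -eta0 / eta1
    jnd = LOG3 / abs(eta1)
    return PsychometricFit(
        eta0, eta1, pse, jnd, jnd / T_REF, law, subject_id, True, deviance,
        n_trials,
    )


def fit_all_subjects(
    trials: pd.DataFrame, condition_ids: Sequence[int] = EXPERIMENTAL_IDS
) -> pd.DataFrame:
    """Per-subject, per-law psychometric fits on the experimental conditions."""
    sub = trials[trials["condition_id"].isin(condition_ids)]
    rows = []
    for (sid, law_val), grp in sub.groupby(["subject_id", "law"], sort=True):
        f = fit_psychometric(grp, law=MotionLaw(law_val), subject_id=str(sid))
        rows.append(
            {
                "subject_id": sid,
                "law": law_val,
                "eta0": f.eta0,
                "eta1": f.eta1,
                "pse": f.pse,
                "jnd": f.jnd,
                "wf": f.wf,
                "converged": f.converged,
                "deviance": f.deviance,
                "n_trials": f.n_trials,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# outliers, ANOVA, post hocs


def detect_outliers(values: Sequence[float]) -> np.ndarray:
    """IQR rule: flag values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation of order statistics (type 7).
    """
    v = np.asarray(values, float)
    if v.size < 4:
        raise ValueError("need at least 4 values for the quartile rule")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v > q3 + 1.5 * iqr) | (v < q1 - 1.5 * iqr)


class RMAnovaResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float
    shapiro_p: tuple[float, ...]  # per-column normality check


def rm_anova(values: np.ndarray) -> RMAnovaResult:
    """One-way repeated-measures ANOVA (subjects x conditions matrix).

    No sphericity correction is applied; per-condition Shapiro-Wilk p-values
    are returned alongside as a normality check.
    """
    v = np.asarray(values, float)
    if v.ndim != 2 or np.isnan(v).any():
        raise ValueError("need a complete subjects x conditions matrix")
    n, k = v.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 conditions")
    shapiro_p = tuple(float(stats.shapiro(v[:, j]).pvalue) for j in range(k))
    # degenerate design: no between-condition variation means no effect
    ss_cond = n * np.sum((v.mean(axis=0) - v.mean()) ** 2)
    if ss_cond < 1e-12 * max(np.var(v), 1e-30) * v.size:
        return RMAnovaResult(0.0, k - 1, (k - 1) * (n - 1), 1.0, shapiro_p)
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "cond": np.tile(np.arange(k), n),
            "value": v.ravel(),
        }
    )
    res = AnovaRM(long, "value", "subject", within=["cond"]).fit()
    row = res.anova_table.iloc[0]
    return RMAnovaResult(
        F=float(row["F Value"]),
        df1=int(row["Num DF"]),
        df2=int(row["Den DF"]),
        p=float(row["Pr > F"]),
        shapiro_p=shapiro_p,
    )


def pairwise_holm(values: np.ndarray, labels: Sequence[str] | None = None) -> pd.DataFrame:
    """All two-sided paired t-tests between columns, Holm step-down adjusted."""
    v = np.asarray(values, float)
    n, k = v.shape
    labels = list(labels) if labels is not None else [str(j) for j in range(k)]
    pairs = list(combinations(range(k), 2))
    raw = []
    tstats = []
    for i, j in pairs:
        t = stats.ttest_rel(v[:, i], v[:, j])
        tstats.append(float(t.statistic) if np.isfinite(t.statistic) else 0.0)
        raw.append(float(t.pvalue) if np.isfinite(t.pvalue) else 1.0)
    adj = multipletests(raw, method="holm")[1]
    return pd.DataFrame(
        {
            "pair": [f"{labels[i]} vs {labels[j]}" for i, j in pairs],
            "t": tstats,
            "p_raw": raw,
            "p_holm": adj,
        }
    )


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment of a vector of p-values."""
    return multipletests(list(pvalues), method="holm")[1]


# ---------------------------------------------------------------------------
# main GLMM (duration x law)


@dataclass
class GlmmFitMain:
    """Main GLMM: duration x law fixed effects, by-subject intercept+slope."""

    result: glmm.MixedGLMResult
    baseline: MotionLaw
    law_order: list[MotionLaw]
    design: dict = field(repr=False, default_factory=dict)

    @property
    def beta(self) -> np.ndarray:
        return self.result.beta

    @property
    def bic(self) -> float:
        return self.result.bic

    @property
    def converged(self) -> bool:
        return self.result.converged

    def coefficients(self) -> pd.DataFrame:
        names = self.result.x_names or [f"b{i}" for i in range(len(self.beta))]
        return pd.DataFrame({"term": names, "estimate": self.beta})

    def per_law_intercept_slope(self) -> dict[MotionLaw, tuple[float, float]]:
        b = self.beta
        out = {self.law_order[0]: (b[0], b[1])}
        for k, law in enumerate(self.law_order[1:]):
            out[law] = (b[0] + b[2 + k], b[1] + b[4 + k])
        return out


def _main_design(trials: pd.DataFrame, baseline: MotionLaw):
    """Aggregated design for the main GLMM on conditions 1-7."""
    sub = trials[trials["condition_id"].isin(EXPERIMENTAL_IDS)].copy()
    if sub.empty:
        raise ValueError("no experimental-condition trials")
    law_order = [baseline] + [l for l in LAW_ORDER if l is not baseline]
    agg = (
        sub.groupby(["subject_id", "law", "D_comp"])["comparison_longer"]
        .agg(successes="sum", trials="count")
        .reset_index()
    )
    subjects = sorted(agg["subject_id"].unique())
    groups = agg["subject_id"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    D = agg["D_comp"].to_numpy(float)
    m1 = (agg["law"] == law_order[1].value).to_numpy(float)
    m2 = (agg["law"] == law_order[2].value).to_numpy(float)
    X = np.column_stack([np.ones(len(agg)), D, m1, m2, D * m1, D * m2])
    Z = X[:, :2]
    names = ["intercept", "D", "M1", "M2", "D:M1", "D:M2"]
    return dict(
        X=X,
        Z=Z,
        groups=groups,
        successes=agg["successes"].to_numpy(float),
        trials=agg["trials"].to_numpy(float),
        subjects=subjects,
        x_names=names,
        law_order=law_order,
    )


def fit_glmm_main(
    trials: pd.DataFrame,
    baseline: MotionLaw = MotionLaw.CONST_TANGENTIAL,
    random: str = "intercept_slope",
    interactions: bool = True,
) -> GlmmFitMain:
    """Fit the population psychometric GLMM on conditions 1-7.

    ``random`` selects the by-subject structure ("intercept" or
    "intercept_slope"); ``interactions`` drops the duration x law terms when
    False (used by the BIC model pool).
    """
    des = _main_design(trials, baseline)
    X, names = des["X"], list(des["x_names"])
    if not interactions:
        X = X[:, :4]
        names = names[:4]
    Z = des["Z"][:, : (2 if random == "intercept_slope" else 1)]
    res = glmm.fit_binomial_mixed(
        X, Z, des["groups"], des["successes"], des["trials"], x_names=names
    )
    if not res.converged:
        logger.warning("main GLMM optimizer: %s", res.message)
    des_out = dict(des)
    des_out["X"] = X
    des_out["Z"] = Z
    des_out["x_names"] = names
    return GlmmFitMain(
        result=res, baseline=baseline, law_order=des["law_order"], design=des_out
    )


def glmm_pse_jnd(fit: GlmmFitMain) -> dict[MotionLaw, tuple[float, float]]:
    """Per-law (PSE, JND) from the composite intercepts and slopes."""
    out = {}
    for law, (b0, b1) in fit.per_law_intercept_slope().items():
        if b1 <= 0:
            logger.warning("non-positive slope for %s; PSE/JND flagged", law)
            out[law] = (np.nan, np.nan)
        else:
            out[law] = (-b0 / b1, LOG3 / b1)
    return out


def bootstrap_differences(
    fit: GlmmFitMain,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Parametric-bootstrap CIs for between-law JND and PSE differences.

    Responses are resampled from the fitted model (fixed effects plus freshly
    drawn random effects), the GLMM is refitted (warm-started at the original
    solution), and percentile intervals of the per-law differences are formed.
    Failed refits are dropped and counted.
    """
    des = fit.design
    rng = np.random.default_rng(seed)
    laws = fit.law_order
    pairs = list(combinations(range(len(laws)), 2))
    jnd_reps: list[dict] = []
    pse_reps: list[dict] = []
    failures = 0
    for _ in range(B):
        y_star = glmm.simulate_from_fit(
            fit.result, des["X"], des["Z"], des["groups"], des["trials"], rng
        )
        try:
            res_b = glmm.fit_binomial_mixed(
                des["X"], des["Z"], des["groups"], y_star, des["trials"],
                start_beta=fit.result.beta, start_theta=fit.result.theta,
                x_names=des["x_names"],
            )
            fit_b = GlmmFitMain(res_b, fit.baseline, laws, {})
            pj = glmm_pse_jnd(fit_b)
            if any(not np.isfinite(v[1]) for v in pj.values()):
                failures += 1
                continue
            jnd_reps.append({law: pj[law][1] for law in laws})
            pse_reps.append({law: pj[law][0] for law in laws})
        except Exception:
            failures += 1
    alpha = (1.0 - level) / 2.0
    out = {"n_replicates": len(jnd_reps), "n_failures": failures, "pairs": {}}
    for i, j in pairs:
        key = f"{laws[i].value} - {laws[j].value}"
        entry = {}
        for name, reps in (("jnd", jnd_reps), ("pse", pse_reps)):
            diffs = np.array([r[laws[i]] - r[laws[j]] for r in reps])
            if diffs.size == 0:
                entry[name] = None
                continue
            lo, hi = np.percentile(diffs, [100 * alpha, 100 * (1 - alpha)])
            entry[name] = {
                "mean": float(diffs.mean()),
                "ci": [float(lo), float(hi)],
                "excludes_zero": bool(lo > 0 or hi < 0),
            }
        out["pairs"][key] = entry
    return out


# ---------------------------------------------------------------------------
# control GLMM (distance vs duration)


@dataclass
class GlmmFitControl:
    """Control GLMM on conditions 3/5 (experimental) vs 8/9 (duration-matched)."""

    result: glmm.MixedGLMResult
    design: dict = field(repr=False, default_factory=dict)

    @property
    def beta(self) -> np.ndarray:
        return self.result.beta

    @property
    def slope_experimental(self) -> float:
        return float(self.beta[1])

    @property
    def slope_control(self) -> float:
        return float(self.beta[1] + self.beta[3])

    def coefficients(self) -> pd.DataFrame:
        names = self.result.x_names or [f"b{i}" for i in range(len(self.beta))]
        return pd.DataFrame({"term": names, "estimate": self.beta})


def fit_glmm_control(trials: pd.DataFrame) -> GlmmFitControl:
    """Regress 'comparison longer' on horizontal distance H with a control dummy.

    Uses conditions 3, 5 (duration varies with H) and 8, 9 (duration fixed at
    the reference): logit P = b0 + u0 + b1 H + b2 C + b3 H C.  A duration-only
    responder implies b3 = -b1 (flat control slope); a distance-only responder
    implies b3 = 0.
    """
    sub = trials[trials["condition_id"].isin(CONTROL_SET_IDS)].copy()
    missing = set(CONTROL_SET_IDS) - set(sub["condition_id"].unique())
    if missing:
        raise ValueError(f"control analysis needs conditions {CONTROL_SET_IDS}; missing {sorted(missing)}")
    sub["C"] = sub["condition_id"].isin([8, 9]).astype(float)
    agg = (
        sub.groupby(["subject_id", "C", "H_comp"])["comparison_longer"]
        .agg(successes="sum", trials="count")
        .reset_index()
    )
    subjects = sorted(agg["subject_id"].unique())
    groups = agg["subject_id"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    H = agg["H_comp"].to_numpy(float)
    C = agg["C"].to_numpy(float)
    X = np.column_stack([np.ones(len(agg)), H, C, H * C])
    Z = X[:, :1]
    res = glmm.fit_binomial_mixed(
        X, Z, groups, agg["successes"].to_numpy(float),
        agg["trials"].to_numpy(float),
        x_names=["intercept", "H", "C", "H:C"],
    )
    return GlmmFitControl(result=res, design=dict(X=X, Z=Z, groups=groups, subjects=subjects))


# ---------------------------------------------------------------------------
# BIC model selection


def bic_select(
    trials: pd.DataFrame,
    candidates: Sequence[dict] | None = None,
    baseline: MotionLaw = MotionLaw.CONST_TANGENTIAL,
) -> tuple[dict, GlmmFitMain, pd.DataFrame]:
    """Fit a nested pool of main-GLMM specs; return the minimum-BIC one.

    The default pool crosses {random intercept, random intercept+slope} with
    {with, without duration x law interactions}.  Ties break to the first
    (lowest-index) candidate.
    """
    if candidates is None:
        candidates = [
            {"random": r, "interactions": i}
            for r in ("intercept", "intercept_slope")
            for i in (False, True)
        ]
    if len(candidates) < 2:
        raise ValueError("need at least two candidate specs")
    fits: list[GlmmFitMain | None] = []
    rows = []
    for spec in candidates:
        try:
            f = fit_glmm_main(trials, baseline=baseline, **spec)
            fits.append(f)
            rows.append({**spec, "bic": f.bic, "converged": f.converged})
        except Exception as exc:
            logger.warning("candidate %s failed: %s", spec, exc)
            fits.append(None)
            rows.append({**spec, "bic": np.inf, "converged": False})
    table = pd.DataFrame(rows)
    if not np.isfinite(table["bic"]).any():
        raise RuntimeError("all candidate models failed")
    best = int(np.argmin(table["bic"].to_numpy()))
    return dict(candidates[best]), fits[best], table


# ---------------------------------------------------------------------------
# alternative-cue re-analysis


CUE_CHOICES = ("duration", "initial-tangential-velocity", "dilation-rate", "elevation-rate")
EVAL_POINTS = ("start", "ascending_cross", "descending_cross", "destination")


def _cue_value(
    cond_id: int,
    law: MotionLaw,
    cue: str,
    eval_point: str,
    obs: ObserverGeometry,
    g: float,
) -> float | None:
    """Stimulus cue value for one condition and law at an evaluation point."""
    cond = get_condition(cond_id)
    if cue == "duration":
        return cond.D
    path = path_for_condition(cond, g)
    if eval_point == "start":
        t = 0.0
    elif eval_point == "destination":
        t = path.D
    else:
        cross = fixation_crossings(path, law, obs)
        t = cross.ascending if eval_point == "ascending_cross" else cross.descending
        if t is None:
            return None
    st = state(path, law, t)
    if cue == "initial-tangential-velocity":
        return st.v
    o = optic_state(st, path, obs)
    if cue == "dilation-rate":
        return o.theta_dot
    if cue == "elevation-rate":
        return o.gamma_dot
    raise ValueError(f"unknown cue {cue!r}")


def cue_reanalysis(
    trials: pd.DataFrame,
    cue: str,
    eval_point: str = "start",
    obs: ObserverGeometry | None = None,
    g: float | None = None,
) -> pd.DataFrame:
    """Refit the psychometric model with a normalized stimulus cue as predictor.

    The cue value of each comparison condition is divided by the same-law
    reference value, so the reference maps to exactly 1 and the returned JNDs
    are on the normalized-cue scale.  Conditions where the cue is undefined at
    the evaluation point (e.g. an absent crossing) are skipped with a log
    entry.
    """
    from .kinematics import G_DEFAULT

    if cue not in CUE_CHOICES:
        raise ValueError(f"cue must be one of {CUE_CHOICES}")
    if eval_point not in EVAL_POINTS:
        raise ValueError(f"eval_point must be one of {EVAL_POINTS}")
    obs = obs or ObserverGeometry()
    g = G_DEFAULT if g is None else g
    sub = trials[trials["condition_id"].isin(EXPERIMENTAL_IDS)].copy()
    cue_map: dict[tuple[int, str], float] = {}
    for law in LAW_ORDER:
        ref_val = _cue_value(4, law, cue, eval_point, obs, g)
        if ref_val is None or ref_val == 0.0:
            logger.warning("reference cue undefined for %s at %s", law, eval_point)
            continue
        for cid in EXPERIMENTAL_IDS:
            val = _cue_value(cid, law, cue, eval_point, obs, g)
            if val is None:
                logger.warning(
                    "cue %s undefined for condition %s/%s at %s; skipped",
                    cue, cid, law.value, eval_point,
                )
                continue
            cue_map[(cid, law.value)] = abs(val) / abs(ref_val)
    sub["cue_value"] = [
        cue_map.get((cid, law_val), np.nan)
        for cid, law_val in zip(sub["condition_id"], sub["law"])
    ]
    sub = sub.dropna(subset=["cue_value"])
    rows = []
    for (sid, law_val), grp in sub.groupby(["subject_id", "law"], sort=True):
        f = fit_psychometric(
            grp, predictor="cue_value", law=MotionLaw(law_val),
            subject_id=str(sid), require_positive_slope=False,
        )
        rows.append(
            {
                "subject_id": sid,
                "law": law_val,
                "cue": cue,
                "eval_point": eval_point,
                "eta0": f.eta0,
                "eta1": f.eta1,
                "pse": f.pse,
                "jnd": f.jnd,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)
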