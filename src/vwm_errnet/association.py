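"""Brain-behavior association via linear mixed-effects models.

Each behavioral error measure (σ_vM, P_NT or P_G) is regressed on the
network-connectivity features under a within-subject two-task design:

    response ~ 1 + task + FC terms + task×FC terms + (1 | subject)

The most parsimonious model is found by a greedy step-up search: candidate
additions (FC main effects; interactions bring their main effect along) are
ranked by the REML log-likelihood of the augmented model, and the
best-ranked addition whose ML-refit likelihood-ratio test clears α = 0.05 is
accepted, repeating until nothing clears. Satterthwaite t-tests, parametric
percentile bootstrap CIs, simple slopes per task and leave-one-subject-out
influence diagnostics complete the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import MixedModelFit, build_design, fit_mixed_model, lr_test
from .synthesize import feature_names

__all__ = [
    "build_association_dataset",
    "build_base_model",
    "StepUpSelector",
    "step_up_select",
    "fixed_effect_inference",
    "bootstrap_ci",
    "simple_slopes",
    "influence_analysis",
]

RESPONSES = ("sigma_vm", "p_nontarget", "p_guess")


def build_association_dataset(behavior_fits: pd.DataFrame,
                              features: pd.DataFrame,
                              response: str) -> pd.DataFrame:
    """Join per-subject×task behavioral estimates with FC features.

    FC features are constant within subject (resting-state measures) and are
    z-scored across subjects before entering any model, so coefficients are
    response units per SD of connectivity.
    """
    if response not in behavior_fits.columns:
        raise ValueError(f"response {response!r} not in behavioral table")
    feats = [c for c in features.columns if c.startswith(("fc_w_", "fc_b_"))]
    fstd = features.copy()
    for c in feats:
        x = fstd[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"feature {c!r} has zero variance")
        fstd[c] = (x - x.mean()) / sd
    df = behavior_fits[["subject", "task", response]].merge(
        fstd[["subject"] + feats], on="subject", how="inner")
    if df[response].isna().any():
        raise ValueError("missing responses after join")
    return df.sort_values(["subject", "task"]).reset_index(drop=True)


def build_base_model(data: pd.DataFrame, response: str) -> MixedModelFit:
    """The base model: fixed intercept + task effect + subject random intercept."""
    n_both = (data.groupby("subject")["task"].nunique() == 2).sum()
    if n_both < 10:
        raise ValueError("need >= 10 subjects observed in both tasks")
    return fit_mixed_model(data, response, ["intercept", "task"], reml=True)


@dataclass
class SelectionTraceEntry:
    round: int
    added: tuple
    llf_reml: float
    lr: float
    df: int
    p: float
    accepted: bool


class StepUpSelector:
    """Greedy forward model selection over FC terms and task interactions.

    Parameters
    ----------
    alpha : float
        LRT acceptance level per addition.
    candidates : list of str or None
        FC feature names to consider (default: all 21 within/between
        features). Each feature contributes a main-effect candidate and a
        task-interaction candidate; an interaction considered before its
        main effect is proposed as a joint (main + interaction) addition.

    Attributes (after ``fit``)
    --------------------------
    fit_ : MixedModelFit                 the selected model (REML)
    selected_terms_ : list of str
    trace_ : list of SelectionTraceEntry
    """

    def __init__(self, alpha: float = 0.05, candidates=None, max_rounds: int = 20):
        self.alpha = alpha
        self.candidates = candidates
        self.max_rounds = max_rounds

    def fit(self, data: pd.DataFrame, response: str):
        feats = (list(self.candidates) if self.candidates is not None
                 else [f for f in feature_names() if f in data.columns])
        current = build_base_model(data, response)
        trace = []
        for rnd in range(1, self.max_rounds + 1):
            proposals = []
            for f in feats:
                if f not in current.terms:
                    proposals.append((f,))
                if f"task:{f}" not in current.terms:
                    add = (f"task:{f}",) if f in current.terms else (f, f"task:{f}")
                    proposals.append(add)
            scored = []
            for add in proposals:
                try:
                    cand = fit_mixed_model(data, response,
                                           current.terms + list(add), reml=True)
                except np.linalg.LinAlgError:
                    warnings.warn(f"skipping rank-deficient addition {add}")
                    continue
                scored.append((cand.llf_reml, add, cand))
            scored.sort(key=lambda t: -t[0])
            accepted = None
            for llf, add, cand in scored:
                test = lr_test(current, cand)
                entry = SelectionTraceEntry(rnd, add, llf, test["lr"],
                                            test["df"], test["p"],
                                            test["p"] < self.alpha)
                trace.append(entry)
                if entry.accepted:
                    accepted = cand
                    break
            if accepted is None:
                break
            current = accepted
        self.fit_ = current
        self.selected_terms_ = list(current.terms)
        self.trace_ = trace
        return self


def step_up_select(data: pd.DataFrame, response: str, candidates=None,
                   alpha: float = 0.05) -> StepUpSelector:
    return StepUpSelector(alpha=alpha, candidates=candidates).fit(data, response)


def fixed_effect_inference(fit: MixedModelFit) -> pd.DataFrame:
    """Satterthwaite t-table for every fixed effect of a converged fit."""
    return fit.inference_table()


def bootstrap_ci(fit: MixedModelFit, n_sim: int = 10000, seed=None,
                 level: float = 0.95, max_failure_rate: float = 0.05) -> pd.DataFrame:
    """Parametric percentile bootstrap CIs for the fixed effects.

    Responses are simulated from the fitted model (fixed predictor, subject
    random intercepts, residual noise), the model refitted, and percentile
    intervals taken per coefficient. More than ``max_failure_rate`` refit
    failures aborts with the failure log.
    """
    rng = np.random.default_rng(seed)
    mu = fit.predict_fixed()
    groups, idx = np.unique(fit.groups, return_inverse=True)
    draws = np.empty((n_sim, len(fit.terms)))
    failures = []
    kept = 0
    data = fit.data.copy()
    for b in range(n_sim):
        bsub = rng.normal(0.0, np.sqrt(fit.sigma2_subject), len(groups))
        y = mu + bsub[idx] + rng.normal(0.0, np.sqrt(fit.sigma2_resid), len(mu))
        data[fit.response] = y
        try:
            ref = fit_mixed_model(data, fit.response, fit.terms, reml=True)
            draws[kept] = ref.params.to_numpy()
            kept += 1
        except Exception as exc:  # refit failure
            failures.append((b, repr(exc)))
    if len(failures) > max_failure_rate * n_sim:
        raise RuntimeError(f"bootstrap refit failure rate too high: "
                           f"{len(failures)}/{n_sim}: {failures[:5]}")
    draws = draws[:kept]
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    out = pd.DataFrame({
        "term": fit.terms,
        "estimate": fit.params.to_numpy(),
        "ci_lo": np.percentile(draws, lo, axis=0),
        "ci_hi": np.percentile(draws, hi, axis=0),
    })
    out.attrs["n_sim"] = n_sim
    out.attrs["n_failures"] = len(failures)
    return out


@dataclass
class SimpleSlopeResult:
    focal: str
    slopes: pd.DataFrame  # per task level: slope, se, df, p


def simple_slopes(fit: MixedModelFit, focal: str) -> SimpleSlopeResult:
    """Conditional slope of a focal FC term at each task level.

    With task coded 0 = orientation (reference) and 1 = location, the
    orientation slope is the main-effect coefficient and the location slope
    is main + interaction; SEs come from the coefficient covariance and p
    from Satterthwaite t-tests on the corresponding contrasts.
    """
    inter = f"task:{focal}"
    if focal not in fit.terms:
        raise ValueError(f"focal term {focal!r} not in model")
    if inter not in fit.terms:
        raise ValueError(f"model lacks the interaction {inter!r}")
    k = len(fit.terms)
    rows = []
    for task, code in (("orientation", 0.0), ("location", 1.0)):
        c = np.zeros(k)
        c[fit.terms.index(focal)] = 1.0
        c[fit.terms.index(inter)] = code
        res = fit.contrast_inference(c)
        rows.append(dict(task=task, slope=res["estimate"], se=res["se"],
                         df=res["df"], p=res["p"]))
    return SimpleSlopeResult(focal=focal, slopes=pd.DataFrame(rows))


def influence_analysis(fit: MixedModelFit, cooks_threshold: float | None = None):
    """Leave-one-subject-out influence diagnostics and a cleaned refit.

    Cook's distance per subject uses the generalized form
    D_i = (β̂ − β̂₋ᵢ)ᵀ Cov(β̂)⁻¹ (β̂ − β̂₋ᵢ) / k. Subjects above the
    threshold (default 4 / n_subjects) are flagged and the model refitted
    without them.
    """
    subjects = np.unique(fit.groups)
    n = len(subjects)
    if cooks_threshold is None:
        cooks_threshold = 4.0 / n
    beta = fit.params.to_numpy()
    cov_inv = np.linalg.inv(fit.cov_params.to_numpy())
    k = len(fit.terms)
    rows = []
    for s in subjects:
        sub = fit.data[fit.data["subject"] != s]
        ref = fit_mixed_model(sub, fit.response, fit.terms, reml=True)
        d = beta - ref.params.to_numpy()
        rows.append(dict(subject=s, cooks_d=float(d @ cov_inv @ d) / k))
    table = pd.DataFrame(rows)
    table["influential"] = table["cooks_d"] > cooks_threshold
    flagged = list(table.loc[table["influential"], "subject"])
    refit = None
    if flagged:
        kept = fit.data[~fit.data["subject"].isin(flagged)]
        if kept["subject"].nunique() < 10:
            raise ValueError("excluding influential subjects leaves < 10 subjects")
        refit = fit_mixed_model(kept, fit.response, fit.terms, reml=True)
    return table, refit
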