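"""Random-intercept linear mixed model with Satterthwaite inference.

Estimation is delegated to :class:`statsmodels` MixedLM (REML or ML); this
module adds the pieces the analysis needs on top of it: a named design
matrix built from term strings, Satterthwaite denominator degrees of
freedom for fixed-effect contrasts, and likelihood-ratio comparison of
nested models under ML refits.

For a model y = Xβ + Zb + ε with a single subject random intercept,
V(θ) = σ_e² I + σ_b² ZZᵀ. For a contrast c, Var(cᵀβ̂) = f(θ) = cᵀ(XᵀV⁻¹X)⁻¹c
and the Satterthwaite df is 2 f² / (gᵀ A g), where g = ∇f(θ) and A is the
asymptotic covariance of θ̂ from the REML information matrix
I_jk = ½ tr(P V_j P V_k) with P = V⁻¹ − V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = ["build_design", "MixedModelFit", "fit_mixed_model", "lr_test"]

TASK_REFERENCE = "orientation"  # task coded 0 at reference, 1 at location


def _fit_mixedlm(y, X, groups, reml: bool):
    model = sm.MixedLM(y, X, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, method="lbfgs")
        except Exception:
            res = model.fit(reml=reml, method="powell")
        if not getattr(res, "converged", True):
            res = model.fit(reml=reml, method="powell")
    return res


def build_design(data: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Design-matrix columns for term names.

    ``intercept`` -> 1; ``task`` -> 0/1 indicator (location = 1); a feature
    name -> that column; ``task:feat`` -> product. Raises on unknown terms.
    """
    cols = {}
    task = (data["task"] != TASK_REFERENCE).astype(float).to_numpy()
    for term in terms:
        if term == "intercept":
            cols[term] = np.ones(len(data))
        elif term == "task":
            cols[term] = task
        elif term.startswith("task:"):
            feat = term[5:]
            if feat not in data.columns:
                raise ValueError(f"unknown model term {term!r}")
            cols[term] = task * data[feat].to_numpy(dtype=float)
        elif term in data.columns:
            cols[term] = data[term].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown model term {term!r}")
    return pd.DataFrame(cols, index=data.index)


@dataclass
class MixedModelFit:
    """A fitted random-intercept model with its inference machinery."""

    response: str
    terms: list[str]
    params: pd.Series
    cov_params: pd.DataFrame
    sigma2_subject: float
    sigma2_resid: float
    llf_reml: float
    converged: bool
    zero_variance: bool
    data: pd.DataFrame = field(repr=False)
    X: pd.DataFrame = field(repr=False)
    y: np.ndarray = field(repr=False)
    groups: np.ndarray = field(repr=False)
    _llf_ml: float | None = field(default=None, repr=False)

    @property
    def llf_ml(self) -> float:
        """ML log-likelihood (refit on first access; LRTs need ML, not REML)."""
        if self._llf_ml is None:
            res = _fit_mixedlm(self.y, self.X.to_numpy(), self.groups, reml=False)
            self._llf_ml = float(res.llf)
        return self._llf_ml

    # -- Satterthwaite machinery ---------------------------------------
    def _v_pieces(self):
        n = len(self.y)
        g, idx = np.unique(self.groups, return_inverse=True)
        Z = np.zeros((n, len(g)))
        Z[np.arange(n), idx] = 1.0
        ZZt = Z @ Z.T
        V = self.sigma2_resid * np.eye(n) + self.sigma2_subject * ZZt
        return V, [ZZt, np.eye(n)]

    def contrast_inference(self, c) -> dict:
        """Estimate, SE, t, Satterthwaite df and p for a contrast cᵀβ."""
        c = np.asarray(c, dtype=float)
        X = self.X.to_numpy()
        V, Vd = self._v_pieces()
        Vi = np.linalg.inv(V)
        XtVi = X.T @ Vi
        C = np.linalg.inv(XtVi @ X)
        est = float(c @ self.params.to_numpy())
        f = float(c @ C @ c)
        se = np.sqrt(f)
        P = Vi - XtVi.T @ C @ XtVi
        # gradient of f wrt each variance component
        grad = np.array([float(c @ C @ XtVi @ Vj @ XtVi.T @ C @ c) for Vj in Vd])
        info = np.array([[0.5 * np.trace(P @ Vi_ @ P @ Vj_) for Vj_ in Vd]
                         for Vi_ in Vd])
        try:
            A = np.linalg.inv(info)
            denom = float(grad @ A @ grad)
        except np.linalg.LinAlgError:
            denom = 0.0
        if denom <= 0 or not np.isfinite(denom):
            df = float(len(self.y) - len(self.terms))
        else:
            df = 2.0 * f * f / denom
            df = min(max(df, 1.0), float(len(self.y) - len(self.terms)))
        t = est / se if se > 0 else np.inf * np.sign(est)
        p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
        return dict(estimate=est, se=se, t=float(t), df=df, p=p)

    def inference_table(self) -> pd.DataFrame:
        """Per-term Satterthwaite t-tests."""
        if not self.converged:
            raise RuntimeError("model did not converge; inference unavailable")
        rows = []
        for i, term in enumerate(self.terms):
            c = np.zeros(len(self.terms))
            c[i] = 1.0
            res = self.contrast_inference(c)
            res["term"] = term
            res["df_method"] = "satterthwaite"
            rows.append(res)
        return pd.DataFrame(rows)[
            ["term", "estimate", "se", "t", "df", "p", "df_method"]]

    def predict_fixed(self, X=None) -> np.ndarray:
        X = self.X if X is None else X
        return X.to_numpy() @ self.params.to_numpy()


def fit_mixed_model(data: pd.DataFrame, response: str, terms: list[str],
                    reml: bool = True) -> MixedModelFit:
    """Fit ``response ~ terms + (1 | subject)``.

    Both REML and ML log-likelihoods are stored (the ML refit feeds
    likelihood-ratio tests). A random-intercept variance estimated at ~0 is
    flagged via ``zero_variance`` rather than treated as an error.
    """
    if "subject" not in data or "task" not in data:
        raise ValueError("data must carry 'subject' and 'task' columns")
    if data[response].isna().any():
        raise ValueError("missing responses are not allowed")
    if data.groupby("subject").size().max() > 2:
        raise ValueError("each subject may contribute at most one row per task")
    X = build_design(data, terms)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank} < {X.shape[1]}) for terms {terms}")
    y = data[response].to_numpy(dtype=float)
    groups = data["subject"].to_numpy()
    primary = _fit_mixedlm(y, X.to_numpy(), groups, reml=reml)
    # statsmodels reports cov_re on the response scale
    sigma2_b = float(np.asarray(primary.cov_re)[0, 0])
    sigma2_e = float(primary.scale)
    params = pd.Series(np.asarray(primary.fe_params), index=list(X.columns))
    k = len(terms)
    cov = pd.DataFrame(np.asarray(primary.cov_params())[:k, :k],
                       index=list(X.columns), columns=list(X.columns))
    llf_reml = float(primary.llf) if reml else float(
        _fit_mixedlm(y, X.to_numpy(), groups, reml=True).llf)
    return MixedModelFit(
        response=response, terms=list(terms), params=params, cov_params=cov,
        sigma2_subject=max(sigma2_b, 0.0), sigma2_resid=sigma2_e,
        llf_reml=llf_reml,
        converged=bool(getattr(primary, "converged", True)),
        zero_variance=bool(sigma2_b < 1e-10),
        data=data, X=X, y=y, groups=groups,
        _llf_ml=float(primary.llf) if not reml else None,
    )


def lr_test(nested: MixedModelFit, full: MixedModelFit) -> dict:
    """Likelihood-ratio test of nested fixed-effect structures (ML refits)."""
    df = len(full.terms) - len(nested.terms)
    if df <= 0:
        raise ValueError("'full' must add terms over 'nested'")
    lr = 2.0 * (full.llf_ml - nested.llf_ml)
    lr = max(lr, 0.0)
    return dict(lr=float(lr), df=int(df), p=float(stats.chi2.sf(lr, df)))
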