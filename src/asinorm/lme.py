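"""Linear mixed-effects inference for hierarchical spine data.

Responses (ASI area, per-dendrite spine density, organelle volumes) are
modelled on a variance-stabilising scale (log for areas and volumes, square
root for densities) with Gaussian random intercepts for mouse and, for
spine-level responses, dendrite nested in mouse:

    y = X beta + Z u + eps,   u ~ N(0, Sigma),  eps ~ N(0, sigma^2 I)

Parameters are maximum-likelihood estimates (not REML) so that nested models
can be compared with likelihood-ratio tests.  Pairwise condition contrasts use
the fixed-effect covariance; the default multiplicity adjustment is a seeded
Monte-Carlo single-step max-|z| correction over the joint contrast
distribution, with Holm and Bonferroni as deterministic alternatives.

The estimation backend is statsmodels' MixedLM (mouse as the grouping factor,
dendrite as a variance component); the module surface is backend-agnostic.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator, model_validator
from scipy import stats

import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

_FIXED_COLUMNS = {
    "condition": "condition",
    "diameter": "diameter_um",
    "endosome": "has_endosome",
}


class ModelSpecError(ValueError):
    """Raised for invalid or non-nested model specifications."""


class ModelSpec(BaseModel):
    """Declarative description of one mixed model.

    ``fixed_effects`` may contain ``condition``, ``diameter``, ``endosome``
    and ``condition:endosome``; random intercepts are ``mouse`` alone or
    ``mouse`` plus ``dendrite`` (nested).  ``reference_level`` fixes the
    condition baseline (Table-style parameterisation).
    """

    response: str
    transform: Literal["log", "sqrt", "identity"] = "log"
    fixed_effects: list[str] = []
    random_intercepts: list[str] = ["mouse"]
    reference_level: str = ""

    @field_validator("fixed_effects")
    @classmethod
    def _known_fixed(cls, v):
        allowed = {"condition", "diameter", "endosome", "condition:endosome"}
        unknown = set(v) - allowed
        if unknown:
            raise ValueError(f"unknown fixed effects: {sorted(unknown)}")
        return v

    @model_validator(mode="after")
    def _check(self):
        if "condition:endosome" in self.fixed_effects and not {
            "condition",
            "endosome",
        } <= set(self.fixed_effects):
            raise ValueError("interaction requires both main effects")
        if "dendrite" in self.random_intercepts and "mouse" not in self.random_intercepts:
            raise ValueError("dendrite random intercept requires mouse")
        if not set(self.random_intercepts) <= {"mouse", "dendrite"}:
            raise ValueError("random intercepts limited to mouse and nested dendrite")
        if "condition" in self.fixed_effects and not self.reference_level:
            raise ValueError("condition effect requires an explicit reference level")
        return self

    def formula(self) -> str:
        terms = []
        for f in self.fixed_effects:
            if f == "condition":
                terms.append(f"C(condition, Treatment('{self.reference_level}'))")
            elif f == "condition:endosome":
                terms.append(
                    f"C(condition, Treatment('{self.reference_level}')):has_endosome"
                )
            else:
                terms.append(_FIXED_COLUMNS[f])
        rhs = " + ".join(terms) if terms else "1"
        return f"_y ~ {rhs}"


@dataclass
class LmeFit:
    """Estimated mixed model: fixed effects, variance components, likelihood."""

    params: pd.Series
    se: pd.Series
    cov_params: pd.DataFrame
    sd_mouse: float
    sd_dendrite: Optional[float]
    sd_residual: float
    loglik: float
    n_obs: int
    converged: bool
    spec: ModelSpec
    condition_levels: list[str] = field(default_factory=list)
    _result: object = field(default=None, repr=False, compare=False)

    @property
    def n_fixed(self) -> int:
        return len(self.params)


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ContrastResult:
    """All pairwise level differences with multiplicity-adjusted p-values.

    ``pairs`` rows: (level_i, level_j, estimate, se, z, p_unadjusted, p_adjusted).
    """

    pairs: pd.DataFrame
    method: str


class InputError(ValueError):
    """Raised for responses incompatible with the requested transform."""


def _transform(y: pd.Series, transform: str) -> pd.Series:
    y = y.astype(float)
    if transform == "log":
        if (y <= 0).any():
            raise InputError("log transform requires strictly positive responses")
        return np.log(y)
    if transform == "sqrt":
        if (y < 0).any():
            raise InputError("sqrt transform requires non-negative responses")
        return np.sqrt(y)
    return y


def fit_lme(data: pd.DataFrame, spec: ModelSpec, backend: str = "profiled") -> LmeFit:
    """Fit one mixed model by maximum likelihood.

    Rows with a missing response are dropped (oblique spines have no measured
    ASI).  Variance components are bounded at zero; non-convergence is
    reported through ``converged`` rather than raised.

    ``backend="profiled"`` (default) uses the package's exact profiled-ML
    optimizer for nested random intercepts; ``backend="statsmodels"`` fits the
    identical likelihood through statsmodels MixedLM and is kept as an
    independent cross-check route.
    """
    df = data.dropna(subset=[spec.response]).copy()
    if df["mouse_id"].nunique() < 2:
        raise InputError("mixed model needs >=2 mice")
    if "condition" in spec.fixed_effects:
        levels = sorted(df["condition"].unique())
        if spec.reference_level not in levels:
            raise ModelSpecError(
                f"reference level {spec.reference_level!r} absent from data"
            )
    else:
        levels = []
    df["_y"] = _transform(df[spec.response], spec.transform)
    if "has_endosome" in df.columns:
        df["has_endosome"] = df["has_endosome"].astype(int)
    has_dend = "dendrite" in spec.random_intercepts

    if backend == "profiled":
        from patsy import dmatrices

        from ._nested_ml import fit_nested_ml

        sort_cols = ["mouse_id", "dendrite_id"] if has_dend else ["mouse_id"]
        df = df.sort_values(sort_cols, kind="stable").reset_index(drop=True)
        ydm, xdm = dmatrices(spec.formula(), df, return_type="dataframe")
        names = list(xdm.columns)
        mouse_codes = pd.factorize(df["mouse_id"])[0]
        dend_codes = pd.factorize(df["dendrite_id"])[0] if has_dend else None
        res = fit_nested_ml(
            ydm.to_numpy().ravel(), xdm.to_numpy(), mouse_codes, dend_codes
        )
        params = pd.Series(res.beta, index=names)
        cov = pd.DataFrame(res.cov_beta, index=names, columns=names)
        return LmeFit(
            params=params,
            se=pd.Series(np.sqrt(np.diag(res.cov_beta)), index=names),
            cov_params=cov,
            sd_mouse=res.sigma_mouse,
            sd_dendrite=res.sigma_dendrite,
            sd_residual=res.sigma_resid,
            loglik=res.loglik,
            n_obs=len(df),
            converged=res.converged,
            spec=spec,
            condition_levels=levels,
            _result=res,
        )
    if backend != "statsmodels":
        raise ValueError(f"unknown backend {backend!r}")

    if has_dend:
        # Dendrites are nested in mice: recoding them 0..k within each mouse
        # collapses the variance-component design to max-dendrites-per-mouse
        # columns without changing the model.
        df["_dendrite"] = df.groupby("mouse_id")["dendrite_id"].transform(
            lambda s: pd.factorize(s)[0]
        )
        vc = {"dendrite": "0 + C(_dendrite)"}
    else:
        vc = None
    model = smf.mixedlm(
        spec.formula(), df, groups="mouse_id", re_formula="1", vc_formula=vc
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        # The profiled likelihood is awkward near variance boundaries and no
        # single optimizer dominates; keep the best of two.
        result = None
        for method in ("lbfgs", "powell"):
            candidate = model.fit(reml=False, maxiter=500, method=method)
            if result is None or candidate.llf > result.llf:
                result = candidate

    k_fe = model.k_fe
    params = result.params.iloc[:k_fe]
    cov = pd.DataFrame(
        np.asarray(result.cov_params())[:k_fe, :k_fe],
        index=params.index,
        columns=params.index,
    )
    se = pd.Series(np.sqrt(np.diag(cov)), index=params.index)
    return LmeFit(
        params=params,
        se=se,
        cov_params=cov,
        sd_mouse=float(np.sqrt(max(result.cov_re.iloc[0, 0], 0.0))),
        sd_dendrite=(
            float(np.sqrt(max(result.vcomp[0], 0.0))) if vc is not None else None
        ),
        sd_residual=float(np.sqrt(result.scale)),
        loglik=float(result.llf),
        n_obs=int(model.nobs),
        converged=bool(result.converged),
        spec=spec,
        condition_levels=levels,
        _result=result,
    )


def lrt(full: LmeFit, reduced: LmeFit) -> LrtResult:
    """Likelihood-ratio test of nested ML fits; chi-square df equals the
    difference in fixed-effect parameter counts."""
    if not set(reduced.params.index) <= set(full.params.index):
        raise ModelSpecError("reduced model is not nested in the full model")
    if reduced.n_obs != full.n_obs:
        raise ModelSpecError("models were fit on different rows")
    df = full.n_fixed - reduced.n_fixed
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df == 0:  # identical fixed-effect structure: nothing to test
        return LrtResult(statistic=stat, df=0, p_value=1.0)
    return LrtResult(statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))


def _condition_effect_vector(fit: LmeFit, level: str, endosome: Optional[int]) -> np.ndarray:
    """Design-space vector whose inner product with beta gives the condition-level
    effect (relative to the reference), optionally within an endosome stratum."""
    c = np.zeros(fit.n_fixed)
    if level == fit.spec.reference_level:
        pass
    else:
        main = cross = None
        for i, name in enumerate(fit.params.index):
            m = re.fullmatch(r"C\(condition.*\)\[T\.(.+?)\]", name)
            if m and m.group(1) == level:
                main = i
            m = re.fullmatch(r"C\(condition.*\)\[T\.(.+?)\]:has_endosome", name)
            if m and m.group(1) == level:
                cross = i
        if main is None:
            raise ModelSpecError(f"condition level {level!r} not in the fit")
        c[main] = 1.0
        if endosome and cross is not None:
            c[cross] = float(endosome)
    return c


def pairwise_contrasts(
    fit: LmeFit,
    factor: str = "condition",
    method: str = "single-step",
    within_endosome: Optional[int] = None,
    seed: int = 0,
    n_draws: int = 50_000,
) -> ContrastResult:
    """All pairwise condition contrasts with multiplicity correction.

    ``within_endosome`` evaluates the condition differences inside one endosome
    stratum of an interaction model (0 or 1).  ``single-step`` approximates the
    joint max-|z| null by Monte Carlo from the estimated contrast correlation
    (seeded); ``holm`` and ``bonferroni`` are deterministic alternatives.
    """
    if factor != "condition" or "condition" not in fit.spec.fixed_effects:
        raise ModelSpecError(f"factor {factor!r} is not a fixed effect of this fit")
    levels = fit.condition_levels
    cov = fit.cov_params.to_numpy()
    pairs, cvecs = [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            ci = _condition_effect_vector(fit, levels[i], within_endosome)
            cj = _condition_effect_vector(fit, levels[j], within_endosome)
            cvecs.append(ci - cj)
            pairs.append((levels[i], levels[j]))
    C = np.array(cvecs)
    est = C @ fit.params.to_numpy()
    var = np.einsum("ij,jk,ik->i", C, cov, C)
    se = np.sqrt(np.maximum(var, 1e-300))
    z = est / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))

    m = len(pairs)
    if method == "bonferroni":
        p_adj = np.minimum(1.0, p_raw * m)
    elif method == "holm":
        order = np.argsort(p_raw)
        p_adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_raw[idx])
            p_adj[idx] = min(1.0, running)
    elif method == "single-step":
        cc = C @ cov @ C.T
        d = np.sqrt(np.diag(cc))
        corr = cc / np.outer(d, d)
        evals, evecs = np.linalg.eigh(corr)
        half = evecs * np.sqrt(np.clip(evals, 0.0, None))
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((n_draws, corr.shape[0])) @ half.T
        maxabs = np.abs(draws).max(axis=1)
        p_adj = np.array([(maxabs >= abs(zi)).mean() for zi in z])
        p_adj = np.maximum(p_adj, p_raw)  # single-step never beats the raw test
    else:
        raise ValueError(f"unknown adjustment method {method!r}")

    table = pd.DataFrame(
        {
            "level_i": [p[0] for p in pairs],
            "level_j": [p[1] for p in pairs],
            "estimate": est,
            "se": se,
            "z": z,
            "p_unadjusted": p_raw,
            "p_adjusted": p_adj,
        }
    )
    return ContrastResult(pairs=table, method=method)


def diagnostics(fit: LmeFit) -> dict:
    """Residual diagnostics on the transformed scale.

    Returns ``{"residuals": DataFrame(fitted, residual, observed),
    "qq": DataFrame(theoretical, sample)}`` using conditional residuals
    (observed minus fixed plus predicted random effects); no plotting here.
    """
    result = fit._result
    if hasattr(result, "fittedvalues"):  # statsmodels backend
        fitted = np.asarray(result.fittedvalues, dtype=float)
        observed = np.asarray(result.model.endog, dtype=float)
    else:
        fitted = np.asarray(result.fitted, dtype=float)
        observed = fitted + np.asarray(result.resid, dtype=float)
    resid = observed - fitted
    osm, osr = stats.probplot(resid, dist="norm", fit=False)
    return {
        "residuals": pd.DataFrame(
            {"fitted": fitted, "residual": resid, "observed": observed}
        ),
        "qq": pd.DataFrame({"theoretical": osm, "sample": osr}),
    }


def truncation_sweep(
    data: pd.DataFrame,
    spec: ModelSpec,
    pair: tuple[str, str],
    quantile_grid=None,
) -> dict:
    """Refit a two-condition comparison after pooled lower-tail truncation.

    For each quantile q (default 0%,10%,...,90%) the q fraction smallest
    responses pooled across the pair are removed, the model is refit and the
    pair difference tested (Wald z).  Returns the p-vs-q profile and the first
    q at which the difference stops being significant at 0.05 (None if it
    persists across the grid).
    """
    if quantile_grid is None:
        quantile_grid = np.arange(0.0, 1.0, 0.1)
    quantile_grid = np.asarray(list(quantile_grid), dtype=float)
    if quantile_grid.size == 0:
        raise ValueError("empty quantile grid")
    sub = data[data["condition"].isin(pair)].dropna(subset=[spec.response])
    if sub["condition"].nunique() < 2:
        raise ModelSpecError("both conditions of the pair must be present")
    spec = spec.model_copy(update={"reference_level": pair[1]})
    rows = []
    first_nonsig = None
    values = sub[spec.response].to_numpy(dtype=float)
    for q in quantile_grid:
        cut = np.quantile(values, q) if q > 0 else -np.inf
        kept = sub[sub[spec.response] >= cut]
        fit = fit_lme(kept, spec)
        c = _condition_effect_vector(fit, pair[0], None)
        est = float(c @ fit.params.to_numpy())
        se = float(np.sqrt(c @ fit.cov_params.to_numpy() @ c))
        p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else 1.0
        rows.append({"quantile": q, "n": fit.n_obs, "estimate": est, "p_value": p})
        if first_nonsig is None and p >= 0.05:
            first_nonsig = float(q)
    return {"profile": pd.DataFrame(rows), "first_nonsignificant_quantile": first_nonsig}
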