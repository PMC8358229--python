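"""Logistic-regression assessment of experimental and genetic parameters.

Success of a simulated secondary E&R (binary) is regressed on design and
population-genetic covariates with a binomial GLM (logit link).  Three
canonical models are provided:

* Model 1 - crossing schemes 1:1_1f and dil:mt across population sizes:
  ``cross + h + s + af + N + cross:h + h:af + cross:N + h:N + cross:h:N``
* Model 2 - the 1:1 variants (architecture) across population sizes:
  ``architecture + h + s + N + architecture:h + architecture:N + h:N +
  architecture:h:N`` (no ``af``: the focal starting frequency is always 50%)
* Model 3 - all five schemes at N = 300:
  ``cross + h + s + af + cross:h + h:af``

``cross``, ``architecture``, ``h`` and ``N`` are treatment-coded categorical
effects (first level = reference); ``s`` and ``af`` are continuous, multiplied
by 100 and z-transformed before fitting.  Explanatory variables are tested
with likelihood-ratio tests of the full model against the nested model
lacking the variable and all its interactions; per-term Type-II tests and
Nagelkerke's R2 quantify single-term contributions.  Complete separation is
handled by adding one pseudo-observation with the missing response to the
separated cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ModelSpec",
    "FitResult",
    "model_spec",
    "standardize_covariates",
    "fit_logistic",
    "lrt",
    "drop_variable",
    "nagelkerke_r2",
    "type2_term_tests",
    "add_pseudo_observation",
    "predict_success",
    "variable_lrt_table",
]

CATEGORICAL = ("cross", "architecture", "h", "N")
CONTINUOUS = ("s", "af")
_SEPARATION_COEF = 15.0


@dataclass(frozen=True)
class ModelSpec:
    """A logistic-model formula: response column and a list of terms, each a
    tuple of variable names (main effect = 1-tuple, interaction = k-tuple).
    Interactions must come with all their constituent main effects
    (marginality)."""

    response: str
    terms: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        names = {t for t in self.terms}
        for t in self.terms:
            if len(t) > 1:
                for v in t:
                    if (v,) not in names:
                        raise ValueError(
                            f"interaction {':'.join(t)} lacks main effect {v} (marginality)"
                        )

    @property
    def variables(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.terms:
            for v in t:
                if v not in seen:
                    seen.append(v)
        return tuple(seen)


def model_spec(model: int, success_kind: str = "B") -> ModelSpec:
    """The canonical model (1, 2 or 3) for the chosen success definition."""
    y = {"A": "success_a", "B": "success_b"}[success_kind.upper()]
    if model == 1:
        terms = [("cross",), ("h",), ("s",), ("af",), ("N",),
                 ("cross", "h"), ("h", "af"), ("cross", "N"), ("h", "N"),
                 ("cross", "h", "N")]
    elif model == 2:
        terms = [("architecture",), ("h",), ("s",), ("N",),
                 ("architecture", "h"), ("architecture", "N"), ("h", "N"),
                 ("architecture", "h", "N")]
    elif model == 3:
        terms = [("cross",), ("h",), ("s",), ("af",),
                 ("cross", "h"), ("h", "af")]
    else:
        raise ValueError("model must be 1, 2 or 3")
    return ModelSpec(response=y, terms=tuple(terms))


def prepare_records(df: pd.DataFrame) -> pd.DataFrame:
    """Rename record columns to model variable names (scheme -> cross,
    af_mean -> af) and drop rows with undefined covariates."""
    out = df.rename(columns={"scheme": "cross", "af_mean": "af"}).copy()
    out = out.dropna(subset=[c for c in ("s", "af") if c in out.columns])
    return out


def standardize_covariates(
    df: pd.DataFrame,
    cols: tuple[str, ...] = ("s", "af"),
    params: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Multiply the continuous covariates by 100 and z-transform them.

    Returns the transformed frame and the transform parameters (mean, sd on
    the x100 scale); pass ``params`` back in to apply a stored transform
    (e.g. at prediction time)."""
    out = df.copy()
    fitted = dict(params) if params else {}
    for c in cols:
        if c not in out.columns:
            continue
        x = out[c].to_numpy(dtype=float) * 100.0
        if params is None:
            mu, sd = float(np.mean(x)), float(np.std(x, ddof=0))
            if sd == 0:
                raise ValueError(f"covariate {c!r} has zero variance")
            fitted[c] = (mu, sd)
        mu, sd = fitted[c]
        out[c] = (x - mu) / sd
    return out, fitted


def _levels(df: pd.DataFrame, spec: ModelSpec) -> dict[str, list]:
    lv = {}
    for v in spec.variables:
        if v in CATEGORICAL:
            lv[v] = sorted(df[v].unique().tolist())
    return lv


def _term_columns(df: pd.DataFrame, term: tuple[str, ...], levels: dict):
    """Treatment-coded columns of one term: all products of the constituent
    variables' contrast columns (reference level dropped)."""
    pieces: list[tuple[str, np.ndarray]] = [("", np.ones(len(df)))]
    for v in term:
        new: list[tuple[str, np.ndarray]] = []
        if v in levels:
            for lvl in levels[v][1:]:
                col = (df[v] == lvl).to_numpy(dtype=float)
                for name, vec in pieces:
                    new.append((f"{name}:{v}[{lvl}]" if name else f"{v}[{lvl}]", vec * col))
        else:
            col = df[v].to_numpy(dtype=float)
            for name, vec in pieces:
                new.append((f"{name}:{v}" if name else v, vec * col))
        pieces = new
    return pieces


def build_design(df: pd.DataFrame, spec: ModelSpec, levels: dict | None = None):
    """Design matrix (with intercept) for a model spec; returns (X, levels)."""
    if levels is None:
        levels = _levels(df, spec)
    cols = {"Intercept": np.ones(len(df))}
    for term in spec.terms:
        for name, vec in _term_columns(df, term, levels):
            cols[name] = vec
    X = pd.DataFrame(cols, index=df.index)
    return X, levels


@dataclass
class FitResult:
    """A fitted binomial GLM: coefficients, their covariance, the
    log-likelihood and everything needed to predict at new settings."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    llf: float
    df_resid: int
    n: int
    converged: bool
    separation: bool
    levels: dict = field(default_factory=dict)
    scale_params: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.params)


def fit_logistic(
    df: pd.DataFrame,
    spec: ModelSpec,
    scale_params: dict | None = None,
) -> FitResult:
    """Maximum-likelihood fit via IRLS (deviance tolerance 1e-8, at most 100
    iterations).  Raises on a rank-deficient design; flags non-convergence
    and likely complete separation (|coefficient| > 15 on the logit scale)
    instead of failing silently."""
    X, levels = build_design(df, spec)
    y = df[spec.response].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient ({rank} < {X.shape[1]}); "
            "check factor levels and nesting"
        )
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-8)
    params = pd.Series(res.params, index=X.columns)
    separation = bool(np.max(np.abs(params)) > _SEPARATION_COEF)
    return FitResult(
        spec=spec,
        params=params,
        bse=pd.Series(res.bse, index=X.columns),
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        llf=float(res.llf),
        df_resid=int(res.df_resid),
        n=len(df),
        converged=bool(res.converged),
        separation=separation,
        levels=levels,
        scale_params=scale_params or {},
    )


def lrt(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits on the same records:
    chi2 = 2 (ll_full - ll_reduced), df = difference in parameter count."""
    if full.n != reduced.n:
        raise ValueError("models were fitted on different numbers of records")
    if not set(reduced.params.index) <= set(full.params.index):
        raise ValueError("reduced model is not nested in the full model")
    df = full.n_params - reduced.n_params
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def drop_variable(spec: ModelSpec, variable: str) -> ModelSpec:
    """The nested model lacking a variable and every interaction containing
    it -- the reduced model of the variable-level likelihood-ratio tests."""
    if all(variable not in t for t in spec.terms):
        raise ValueError(f"variable {variable!r} not in the model")
    return replace(spec, terms=tuple(t for t in spec.terms if variable not in t))


def nagelkerke_r2(full: FitResult, null: FitResult, n: int | None = None) -> float:
    """Nagelkerke's R2 of ``full`` against a reduced/null fit:
    [1 - exp((2/n)(ll_null - ll_full))] / [1 - exp((2/n) ll_null)]."""
    n = n or full.n
    if null.llf == 0:
        raise ValueError("degenerate null with zero log-likelihood")
    cox_snell = 1.0 - np.exp((2.0 / n) * (null.llf - full.llf))
    max_r2 = 1.0 - np.exp((2.0 / n) * null.llf)
    return float(cox_snell / max_r2)


def type2_term_tests(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Type-II likelihood-ratio test per term: each term is tested against
    the model of all terms that do not contain it (marginality respected)."""
    rows = []
    for term in spec.terms:
        base_terms = tuple(t for t in spec.terms if not set(term) <= set(t))
        base = fit_logistic(df, replace(spec, terms=base_terms))
        with_term = fit_logistic(df, replace(spec, terms=base_terms + (term,)))
        chi2, dof, p = lrt(with_term, base)
        rows.append({"term": ":".join(term), "chi2": chi2, "df": dof, "p": p})
    return pd.DataFrame(rows)


def find_separated_cells(
    df: pd.DataFrame, response: str, factors: tuple[str, ...]
) -> list[dict]:
    """Factor-level combinations in which every record has the same
    response (complete separation candidates)."""
    out = []
    for key, g in df.groupby(list(factors), observed=True):
        vals = g[response].unique()
        if len(vals) == 1:
            cell = dict(zip(factors, key if isinstance(key, tuple) else (key,)))
            cell["_response"] = vals[0]
            out.append(cell)
    return out


def add_pseudo_observation(
    df: pd.DataFrame, cell: dict, response: str, missing_response
) -> pd.DataFrame:
    """Append one pseudo-observation with the missing response to a
    completely separated cell; a no-op (with a warning) if the cell already
    has mixed responses."""
    mask = np.ones(len(df), dtype=bool)
    for k, v in cell.items():
        mask &= (df[k] == v).to_numpy()
    sub = df[mask]
    if len(sub) == 0:
        raise ValueError(f"no records in cell {cell}")
    if sub[response].nunique() > 1:
        import warnings

        warnings.warn(f"cell {cell} is not separated; no pseudo-observation added")
        return df
    row = sub.iloc[0].copy()
    for c in df.columns:
        if c not in cell and c != response and pd.api.types.is_numeric_dtype(df[c]):
            row[c] = sub[c].mean()
    row[response] = missing_response
    row["pseudo"] = True
    out = df.copy()
    if "pseudo" not in out.columns:
        out["pseudo"] = False
    return pd.concat([out, row.to_frame().T], ignore_index=True).infer_objects()


def predict_success(fit: FitResult, settings: dict) -> tuple[float, float, float]:
    """Success probability with a 95% CI at given covariate settings.

    Categorical settings must use fitted levels; continuous settings are
    given on the raw scale and transformed with the stored parameters.
    The CI comes from LP +/- 1.96 SE(LP), back-transformed with the inverse
    logit."""
    row = {}
    for v in fit.spec.variables:
        if v not in settings:
            raise ValueError(f"missing setting for {v!r}")
        val = settings[v]
        if v in fit.levels:
            if val not in fit.levels[v]:
                raise ValueError(f"unknown level {val!r} for factor {v!r}")
            row[v] = val
        elif v in fit.scale_params:
            mu, sd = fit.scale_params[v]
            row[v] = (float(val) * 100.0 - mu) / sd
        else:
            row[v] = float(val)
    X, _ = build_design(pd.DataFrame([row]), fit.spec, fit.levels)
    x = X.to_numpy()[0]
    lp = float(x @ fit.params.to_numpy())
    se = float(np.sqrt(x @ fit.cov.to_numpy() @ x))
    inv = lambda z: 1.0 / (1.0 + np.exp(-z))  # noqa: E731
    return inv(lp), inv(lp - 1.96 * se), inv(lp + 1.96 * se)


def variable_lrt_table(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Per-variable report: LRT of the full model against the model lacking
    the variable (and its interactions), plus Nagelkerke's R2 improvement of
    the full model over that reduced model."""
    full = fit_logistic(df, spec)
    rows = []
    for v in spec.variables:
        red = fit_logistic(df, drop_variable(spec, v))
        chi2, dof, p = lrt(full, red)
        rows.append({
            "variable": v, "chi2": chi2, "df": dof, "p": p,
            "nagelkerke_r2": nagelkerke_r2(full, red),
        })
    return pd.DataFrame(rows)
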