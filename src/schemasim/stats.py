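"""Mixed-effects models and reporting statistics.

Model fitting delegates to :class:`statsmodels.regression.mixed_linear_model.
MixedLM` (REML) behind an in-repo factorial design builder (sum-to-zero
coding), so that F tests, estimated marginal means, pairwise contrasts, the
Morey within-subject SE, and the normality/heteroskedasticity rule engine
are all defined — and testable — in this module.

Denominator degrees of freedom: Satterthwaite is not available in the
backend, so Wald F tests use the residual (containment-style) df
``n_obs - p_fixed``, labeled ``df_method='residual'`` in every output.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "FactorCoding",
    "ModelSpec",
    "ModelResult",
    "fit_mixed_model",
    "assumption_checks",
    "run_model_with_checks",
    "emmeans",
    "pairwise_contrasts",
    "morey_sem",
]


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# design coding
# ---------------------------------------------------------------------------

class FactorCoding:
    """Full-factorial sum-to-zero (deviation) coding with an intercept.

    Term column indices are exposed so Wald tests and EMM rows can be built
    against the same design.
    """

    def __init__(self, df: pd.DataFrame, factors: list):
        self.factors = list(factors)
        self.levels = {}
        for f in self.factors:
            if f not in df.columns:
                raise ValueError(f"factor {f!r} not in data")
            self.levels[f] = sorted(pd.unique(df[f]))
            if len(self.levels[f]) < 2:
                raise ValueError(f"factor {f!r} has a single level")
        self.terms: dict[str, list[int]] = {}
        self.column_names = ["Intercept"]
        col = 1
        for size in range(1, len(self.factors) + 1):
            for subset in itertools.combinations(self.factors, size):
                width = int(np.prod([len(self.levels[f]) - 1 for f in subset]))
                name = ":".join(subset)
                self.terms[name] = list(range(col, col + width))
                for combo in itertools.product(
                    *[range(len(self.levels[f]) - 1) for f in subset]
                ):
                    self.column_names.append(
                        ":".join(f"{f}[{c}]" for f, c in zip(subset, combo))
                    )
                col += width
        self.n_columns = col

    def _factor_codes(self, f: str, values) -> np.ndarray:
        levels = self.levels[f]
        k = len(levels)
        idx = {lv: i for i, lv in enumerate(levels)}
        out = np.zeros((len(values), k - 1))
        for r, v in enumerate(values):
            if v not in idx:
                raise ValueError(f"unknown level {v!r} for factor {f!r}")
            i = idx[v]
            if i < k - 1:
                out[r, i] = 1.0
            else:
                out[r, :] = -1.0
        return out

    def encode(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        X = np.ones((n, self.n_columns))
        blocks = {f: self._factor_codes(f, df[f].to_numpy()) for f in self.factors}
        for size in range(1, len(self.factors) + 1):
            for subset in itertools.combinations(self.factors, size):
                cols = self.terms[":".join(subset)]
                prod = np.ones((n, 1))
                pieces = [blocks[f] for f in subset]
                # kronecker-style expansion over the subset's coded columns
                out = pieces[0]
                for nxt in pieces[1:]:
                    out = np.einsum("ni,nj->nij", out, nxt).reshape(n, -1)
                X[:, cols] = out
        return X

    def cell_row(self, cell: dict) -> np.ndarray:
        df = pd.DataFrame([cell])
        return self.encode(df)[0]

    def cell_grid(self) -> pd.DataFrame:
        combos = list(itertools.product(*[self.levels[f] for f in self.factors]))
        return pd.DataFrame(combos, columns=self.factors)


# ---------------------------------------------------------------------------
# model spec / result
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    response: str
    factors: list
    participant: str = "participant"
    group: str = "group"  # counterbalancing group for random slopes
    transform: str = "identity"  # 'identity' | 'sqrt'
    group_slopes: bool = True
    #: factor(s) whose levels receive separate residual variances when the
    #: rule engine detects heteroskedasticity; None = the full fixed cell
    weight_by: list | None = None


@dataclass
class ModelResult:
    spec: ModelSpec
    coding: FactorCoding
    params: np.ndarray
    cov_params: np.ndarray
    anova: pd.DataFrame  # term, F, df_num, df_den, p, df_method
    resid: np.ndarray
    fitted: np.ndarray
    data: pd.DataFrame
    weights: np.ndarray | None  # per-row residual-sd scale, if weighted
    random_structure: str
    converged: bool
    df_resid: int
    notes: list = field(default_factory=list)

    @property
    def df_method(self) -> str:
        return "residual"


def _transform_response(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return y
    if transform == "sqrt":
        if (y < 0).any():
            raise ValueError("sqrt transform requires a non-negative response")
        return np.sqrt(y)
    raise ValueError(f"unknown transform {transform!r}")


def _fit_backend(y, X, df, spec, row_scale):
    """Fit MixedLM, trying the group-slope structure first, then reducing.

    ``row_scale`` whitens rows for per-level variance weights (1/sd).
    Returns (params, cov_params, fitted, structure label, converged, notes).
    """
    notes = []
    ys = y * row_scale
    Xs = X * row_scale[:, None]
    groups = df[spec.participant].to_numpy()
    weighted = not np.allclose(row_scale, 1.0)

    # Faithful structure: participants nested in counterbalancing groups,
    # with group-level random slopes on the fixed-effect codes.  With only
    # two groups this frequently fails to converge; any failure reduces to
    # the participant-intercept model below.  Variance-weighted refits skip
    # it (row whitening is not expressible through the formula interface).
    if (
        spec.group_slopes
        and not weighted
        and spec.group in df.columns
        and df[spec.group].nunique() > 1
    ):
        try:
            tmp = pd.DataFrame(
                {f"b{j}": X[:, j] for j in range(1, X.shape[1])}
            )
            tmp["y"] = y
            tmp["group"] = df[spec.group].to_numpy()
            tmp["participant"] = groups
            fixed = "y ~ " + " + ".join(tmp.columns[: X.shape[1] - 1])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM.from_formula(
                    fixed,
                    tmp,
                    groups="group",
                    re_formula="1 + " + " + ".join(tmp.columns[: X.shape[1] - 1]),
                    vc_formula={"participant": "0 + C(participant)"},
                )
                res = model.fit(reml=True, maxiter=200)
            if res.converged:
                p = X.shape[1]
                return (
                    np.asarray(res.fe_params),
                    np.asarray(res.cov_params())[:p, :p],
                    X @ np.asarray(res.fe_params),
                    "group slopes + nested participant intercept",
                    True,
                    notes,
                )
            notes.append("group-slope structure did not converge; reducing")
        except (np.linalg.LinAlgError, ValueError) as err:
            notes.append(f"group-slope structure failed: {err}; reducing")

    attempts = [("participant intercept", np.ones((len(df), 1)))]

    last_err = None
    for label, exog_re in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM(ys, Xs, groups=groups, exog_re=exog_re * row_scale[:, None])
                try:
                    res = model.fit(reml=True, maxiter=200)
                except np.linalg.LinAlgError:
                    res = model.fit(reml=True, method="powell", maxiter=500)
                if not res.converged:
                    res = model.fit(reml=True, method="powell", maxiter=500)
            if not res.converged:
                notes.append(f"structure {label!r} did not converge; reducing")
                last_err = ConvergenceError(label)
                continue
            fitted_s = Xs @ res.fe_params
            return (
                np.asarray(res.fe_params),
                np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]],
                fitted_s / row_scale,
                label,
                True,
                notes,
            )
        except (np.linalg.LinAlgError, ValueError, ConvergenceError) as err:
            notes.append(f"structure {label!r} failed: {err}; reducing")
            last_err = err

    # degenerate variance (e.g., constant response): plain OLS fallback
    if np.var(ys) < 1e-16 * max(1.0, np.abs(ys).mean()) ** 2:
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        resid = ys - Xs @ beta
        dfr = max(len(ys) - Xs.shape[1], 1)
        sigma2 = float(resid @ resid) / dfr
        cov = sigma2 * np.linalg.pinv(Xs.T @ Xs)
        notes.append("zero-variance response: OLS fallback")
        return beta, cov, (Xs @ beta) / row_scale, "OLS (degenerate variance)", True, notes
    raise ConvergenceError(f"mixed model failed to converge: {last_err}")


def _anova_table(coding, params, cov, df_resid):
    rows = []
    for term, cols in coding.terms.items():
        L = np.zeros((len(cols), coding.n_columns))
        for r, c in enumerate(cols):
            L[r, c] = 1.0
        est = L @ params
        V = L @ cov @ L.T
        if np.all(np.abs(est) < 1e-12):
            F = 0.0
        else:
            try:
                F = float(est @ np.linalg.solve(V, est)) / len(cols)
            except np.linalg.LinAlgError:
                F = np.nan
        p = float(sp_stats.f.sf(F, len(cols), df_resid)) if np.isfinite(F) else np.nan
        rows.append(
            {
                "term": term,
                "F": F,
                "df_num": len(cols),
                "df_den": df_resid,
                "p": p,
                "df_method": "residual",
            }
        )
    return pd.DataFrame(rows)


def fit_mixed_model(
    df: pd.DataFrame,
    spec: ModelSpec,
    level_sds: dict | None = None,
) -> ModelResult:
    """REML mixed model with full-factorial fixed effects.

    ``level_sds`` maps weight-cell label -> residual sd; when given, rows
    are whitened by 1/sd (the variance-structure refit of the rule engine).
    """
    df = df.reset_index(drop=True)
    if spec.response not in df.columns:
        raise ValueError(f"response {spec.response!r} not in data")
    y = _transform_response(df[spec.response].to_numpy(dtype=float), spec.transform)
    coding = FactorCoding(df, spec.factors)
    X = coding.encode(df)

    if level_sds is not None:
        cells = _weight_cells(df, spec)
        sds = np.array([level_sds[c] for c in cells])
        row_scale = 1.0 / sds
        weights = sds
    else:
        row_scale = np.ones(len(df))
        weights = None

    params, cov, fitted, structure, converged, notes = _fit_backend(
        y, X, df, spec, row_scale
    )
    resid = y - fitted
    df_resid = len(df) - coding.n_columns
    anova = _anova_table(coding, params, cov, df_resid)
    return ModelResult(
        spec, coding, params, cov, anova, resid, fitted, df,
        weights, structure, converged, df_resid, notes,
    )


# ---------------------------------------------------------------------------
# assumption rule engine
# ---------------------------------------------------------------------------

def _weight_cells(df: pd.DataFrame, spec: ModelSpec) -> pd.Series:
    by = spec.weight_by or spec.factors
    return df[by].astype(str).agg("/".join, axis=1)


def assumption_checks(result: ModelResult, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk on residuals and Levene across fixed-effect cells.

    Returns verdicts plus a recommendation dict the rule engine consumes.
    Small samples yield an 'untested' verdict rather than a guess.
    """
    resid = result.resid
    out = {"alpha": alpha}
    if len(resid) < 3:
        out["normality"] = "untested"
        out["shapiro_p"] = np.nan
    else:
        n = len(resid)
        sample = resid if n <= 4500 else np.sort(resid)[:: max(1, n // 4500)][:4500]
        W, p = sp_stats.shapiro(sample)
        out["normality"] = "normal" if p >= alpha else "non-normal"
        out["shapiro_p"] = float(p)
        out["shapiro_W"] = float(W)
    cells = _weight_cells(result.data, result.spec)
    groups = [resid[cells.to_numpy() == c] for c in sorted(cells.unique())]
    if len(groups) < 2 or min(len(g) for g in groups) < 3:
        out["heteroskedasticity"] = "untested"
        out["levene_p"] = np.nan
    else:
        W, p = sp_stats.levene(*groups)
        out["heteroskedasticity"] = (
            "heteroskedastic" if p < alpha else "homoskedastic"
        )
        out["levene_p"] = float(p)
        out["levene_W"] = float(W)
    out["recommend_sqrt"] = (
        out["normality"] == "non-normal"
        and result.spec.transform == "identity"
    )
    out["recommend_weights"] = out["heteroskedasticity"] == "heteroskedastic"
    return out


def _estimate_level_sds(result: ModelResult) -> dict:
    cells = _weight_cells(result.data, result.spec)
    sds = {}
    for c in sorted(cells.unique()):
        vals = result.resid[cells.to_numpy() == c]
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 1.0
        sds[c] = sd if sd > 0 else 1.0
    return sds


def run_model_with_checks(df: pd.DataFrame, spec: ModelSpec, alpha: float = 0.05):
    """Deterministic check -> transform -> recheck -> weights sequence.

    1. Fit; Shapiro-Wilk the residuals.  If non-normal (and the response is
       non-negative), refit on the square-root transform.
    2. Levene across fixed-effect cells on the current model's residuals; if
       heteroskedastic, refit with per-cell variance weights.

    Returns (final ModelResult, step log).
    """
    log = []
    result = fit_mixed_model(df, spec)
    checks = assumption_checks(result, alpha)
    log.append({"step": "initial fit", **checks})
    if checks["recommend_sqrt"]:
        try:
            spec2 = ModelSpec(**{**spec.__dict__, "transform": "sqrt"})
            result = fit_mixed_model(df, spec2)
            checks = assumption_checks(result, alpha)
            log.append({"step": "sqrt refit", **checks})
        except ValueError as err:
            log.append({"step": "sqrt refit skipped", "reason": str(err)})
    if checks.get("recommend_weights"):
        sds = _estimate_level_sds(result)
        result = fit_mixed_model(df, result.spec, level_sds=sds)
        log.append({"step": "variance-weight refit", "level_sds": sds})
    return result, log


# ---------------------------------------------------------------------------
# estimated marginal means and contrasts
# ---------------------------------------------------------------------------

def emmeans(result: ModelResult, margins: list | None = None) -> pd.DataFrame:
    """Estimated marginal means: equal weight to every design cell.

    ``margins`` selects the factors to keep (default: all factors -> cell
    means); remaining factors are averaged over with equal cell weight.
    """
    coding = result.coding
    margins = list(margins) if margins is not None else list(coding.factors)
    for m in margins:
        if m not in coding.factors:
            raise ValueError(f"unknown margin factor {m!r}")
    grid = coding.cell_grid()
    rows_X = coding.encode(grid)
    keys = grid[margins].astype(str).agg("/".join, axis=1) if margins else pd.Series(
        ["(all)"] * len(grid)
    )
    out = []
    for key in keys.unique():
        mask = (keys == key).to_numpy()
        L = rows_X[mask].mean(axis=0)
        est = float(L @ result.params)
        se = float(np.sqrt(L @ result.cov_params @ L))
        rec = {"margin": key, "emmean": est, "se": se, "df": result.df_resid}
        for f, v in zip(margins, key.split("/")):
            rec[f] = v
        out.append(rec)
    return pd.DataFrame(out)


def pairwise_contrasts(
    result: ModelResult, margins: list | None = None, conf: float = 0.95
) -> pd.DataFrame:
    """All pairwise margin differences with t tests on the model df."""
    coding = result.coding
    margins = list(margins) if margins is not None else list(coding.factors)
    grid = coding.cell_grid()
    rows_X = coding.encode(grid)
    keys = grid[margins].astype(str).agg("/".join, axis=1)
    Ls = {key: rows_X[(keys == key).to_numpy()].mean(axis=0) for key in keys.unique()}
    names = list(Ls)
    out = []
    tcrit = sp_stats.t.ppf(0.5 + conf / 2, result.df_resid)
    for a, b in itertools.combinations(names, 2):
        L = Ls[a] - Ls[b]
        est = float(L @ result.params)
        se = float(np.sqrt(L @ result.cov_params @ L))
        t = est / se if se > 0 else 0.0
        p = 2.0 * float(sp_stats.t.sf(abs(t), result.df_resid))
        out.append(
            {
                "contrast": f"{a} - {b}",
                "estimate": est,
                "se": se,
                "t": t,
                "df": result.df_resid,
                "p": p,
                "ci_low": est - tcrit * se,
                "ci_high": est + tcrit * se,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Morey within-subject error bars
# ---------------------------------------------------------------------------

def morey_sem(
    df: pd.DataFrame,
    participant: str,
    condition: str | list,
    value: str,
) -> pd.DataFrame:
    """Within-subject SEs: remove participant means, add the grand mean,
    take per-condition SEs, and scale by sqrt(M / (M - 1)) for M conditions.

    Participants missing any condition are dropped from the normalization
    (noted in the output attrs); multiple values per cell are pre-averaged.
    With M = 1 the correction is undefined and the plain SE is returned with
    a warning.
    """
    cond_cols = [condition] if isinstance(condition, str) else list(condition)
    cell = df[cond_cols].astype(str).agg("/".join, axis=1)
    tidy = pd.DataFrame(
        {"participant": df[participant], "condition": cell, "value": df[value]}
    )
    wide = tidy.pivot_table(
        index="participant", columns="condition", values="value", aggfunc="mean"
    )
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    M = wide.shape[1]
    if M == 1:
        warnings.warn("single condition: Morey correction undefined, plain SE")
        se = complete.std(ddof=1) / np.sqrt(len(complete))
        out = pd.DataFrame(
            {"condition": wide.columns, "mean": complete.mean(), "sem": se}
        ).reset_index(drop=True)
        out.attrs["dropped_participants"] = dropped
        return out
    normalized = (
        complete.sub(complete.mean(axis=1), axis=0) + complete.to_numpy().mean()
    )
    corr = np.sqrt(M / (M - 1))
    out = pd.DataFrame(
        {
            "condition": complete.columns,
            "mean": complete.mean().to_numpy(),
            "sem": (normalized.std(ddof=1) / np.sqrt(len(complete)) * corr).to_numpy(),
            "n": len(complete),
        }
    )
    out.attrs["dropped_participants"] = dropped
    return out
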