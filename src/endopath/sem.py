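"""Maximum-likelihood covariance-structure fitting of path models.

Fits a :class:`~endopath.models.PathModel` to a species trait table by
minimizing the ML discrepancy between the sample correlation matrix ``S`` and
the model-implied matrix ``Sigma(theta)``:

    F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

At the optimum, ``chi2 = (n - 1) F_min`` is referred to a chi-square
distribution on the model degrees of freedom; model comparison uses
``BIC = chi2 - df ln(n)`` (lower is better) and
``RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1)))`` (near 0 is adequate fit).
Standard errors come from the inverse Hessian of ``(n-1)/2 F`` at the optimum
and Wald z-tests use the normal reference; percentile bootstrap intervals over
species-row resamples are available for small samples, where they are more
trustworthy than the asymptotic tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import (
    Parameter,
    PathModel,
    count_df,
    implied_covariance,
)

__all__ = [
    "TRAIT_COLUMNS",
    "TraitTable",
    "FitOptions",
    "FitResult",
    "BootstrapResult",
    "DataError",
    "prepare",
    "sample_correlation",
    "ml_discrepancy",
    "fit_ml",
    "bic",
    "rmsea",
    "bootstrap_ci",
    "model_selection_table",
    "equations_report",
]

#: Default trait columns of the comparative analysis.
TRAIT_COLUMNS = ("mb", "BMR", "MMR", "T_b", "R_max")


class DataError(ValueError):
    """Trait data violate a precondition (non-positive value in a log column,
    constant column, too few species...)."""


@dataclass(frozen=True)
class TraitTable:
    """Species-by-trait data with its transformation state.

    ``data`` is indexed by species identifier; ``transform_state`` records,
    per column, one of ``"raw"``, ``"log10"`` or ``"standardized"``.
    """

    data: pd.DataFrame
    transform_state: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.data.isna().any().any():
            raise DataError("trait table contains missing values")
        state = dict(self.transform_state)
        for c in self.data.columns:
            state.setdefault(c, "raw")
        object.__setattr__(self, "transform_state", state)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @classmethod
    def from_csv(cls, path, species_column: str = "species") -> "TraitTable":
        df = pd.read_csv(path)
        if species_column in df.columns:
            df = df.set_index(species_column)
        return cls(df)

    def to_csv(self, path, species_column: str = "species") -> None:
        self.data.rename_axis(species_column).to_csv(path)


def prepare(table: TraitTable, log_columns: set | frozenset = frozenset()) -> TraitTable:
    """Log10-transform the listed columns, then center and scale every column
    to unit (sample) standard deviation.

    Raises :class:`DataError`, naming species and column, when a log column
    contains a non-positive value, and when any column is constant.
    """
    df = table.data.copy().astype(float)
    state = dict(table.transform_state)
    for c in log_columns:
        if c not in df.columns:
            raise DataError(f"log column {c!r} not in table")
        bad = df.index[df[c] <= 0]
        if len(bad):
            raise DataError(
                f"non-positive value in log column {c!r} for species "
                f"{list(map(str, bad))}"
            )
        df[c] = np.log10(df[c])
        state[c] = "log10"
    for c in df.columns:
        sd = df[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DataError(f"column {c!r} is constant; cannot standardize")
        df[c] = (df[c] - df[c].mean()) / sd
        state[c] = "standardized"
    return TraitTable(df, state)


def sample_correlation(table: TraitTable, variables=None) -> pd.DataFrame:
    """Sample correlation matrix of the requested columns.

    Warns when the matrix is numerically near-singular (collinear traits).
    """
    cols = list(variables) if variables is not None else list(table.columns)
    if table.n < 3:
        raise DataError(f"need at least 3 species, got {table.n}")
    X = table.data[cols].to_numpy(float)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [c for c, s in zip(cols, sds) if s == 0]
        raise DataError(f"constant column(s) {bad}; correlation undefined")
    S = np.corrcoef(X, rowvar=False)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    if np.linalg.eigvalsh(S).min() < 1e-10:
        warnings.warn("sample correlation matrix is singular or near-singular")
    return pd.DataFrame(S, index=cols, columns=cols)


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """ML discrepancy ``F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p``.

    Nonnegative, zero iff ``Sigma == S``.  Raises
    :class:`numpy.linalg.LinAlgError` when either matrix is not positive
    definite.
    """
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    p = S.shape[0]
    if Sigma.shape != (p, p):
        raise ValueError("S and Sigma must have the same order")
    L = np.linalg.cholesky(Sigma)  # raises if not PD
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(L)))
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("S is not positive definite")
    Sinv_term = np.trace(np.linalg.solve(Sigma, S))
    return float(logdet_sigma + Sinv_term - logdet_s - p)


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class FitOptions:
    """Optimizer configuration for :func:`fit_ml`.

    ``n_restarts`` seeded random restarts are run in addition to one start at
    OLS-initialized values; ``f_tol`` is the convergence tolerance on the
    discrepancy.  ``compute_se`` can be switched off when only the fit indices
    are needed (e.g. in model-selection sweeps), skipping the Hessian.
    """

    n_restarts: int = 10
    seed: int = 0
    f_tol: float = 1e-8
    max_iter: int = 500
    compute_se: bool = True


@dataclass(frozen=True)
class FitResult:
    """Outcome of one ML fit: estimates, tests and fit indices."""

    model_id: str | None
    parameters: tuple[Parameter, ...]
    estimates: dict[str, float]
    se: dict[str, float]
    z: dict[str, float]
    p_wald: dict[str, float]
    f_min: float
    chi2: float
    df: int
    p_chi2: float
    bic: float
    rmsea: float
    r2: dict[str, float]
    converged: bool
    heywood: bool
    n_used: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for prm in self.parameters:
            nm = prm.name
            rows.append(
                {
                    "parameter": nm,
                    "kind": prm.kind,
                    "estimate": self.estimates[nm],
                    "se": self.se.get(nm, np.nan),
                    "z": self.z.get(nm, np.nan),
                    "p": self.p_wald.get(nm, np.nan),
                }
            )
        return pd.DataFrame(rows)


def _ols_start(model: PathModel, S: pd.DataFrame) -> dict[str, float]:
    """Per-equation OLS on the correlation matrix as starting values; member
    edges of an equality group get the average of their separate estimates."""
    start: dict[str, list[float]] = {}
    resid: dict[str, float] = {}
    for v in model.endogenous:
        parents = list(model.parents(v))
        Spp = S.loc[parents, parents].to_numpy(float)
        Spv = S.loc[parents, v].to_numpy(float)
        try:
            b = np.linalg.solve(Spp, Spv)
        except np.linalg.LinAlgError:
            b = np.linalg.lstsq(Spp, Spv, rcond=None)[0]
        for (edge, coef) in zip(
            [e for e in model.directed_edges if e.target == v], b
        ):
            start.setdefault(model.parameter_of_label(edge.label), []).append(
                float(coef)
            )
        resid[v] = float(np.clip(1.0 - b @ Spv, 0.05, 1.5))
    theta = {k: float(np.mean(vals)) for k, vals in start.items()}
    for prm in model.free_parameters:
        if prm.kind == "cov":
            theta[prm.name] = 0.0
        elif prm.kind == "var":
            theta[prm.name] = resid.get(prm.members[0], 1.0)
    return theta


def _numerical_hessian(fun, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return H


_PENALTY = 1e8


def fit_ml(
    model: PathModel, table: TraitTable, options: FitOptions | None = None
) -> FitResult:
    """Fit a path model to a prepared trait table by maximum likelihood.

    The sample correlation matrix is computed over the model's variables (in
    model order); the discrepancy is minimized by quasi-Newton search from an
    OLS-informed start plus seeded random restarts.  Error variances are not
    constrained during optimization; a negative fitted error variance (Heywood
    case) is flagged on the result rather than hidden.
    """
    opts = options or FitOptions()
    missing = set(model.variables) - set(table.columns)
    if missing:
        raise DataError(f"model variables {sorted(missing)} absent from table")
    S_df = sample_correlation(table, model.variables)
    S = S_df.to_numpy(float)
    n = table.n
    p = len(model.variables)
    names = list(model.parameter_names)
    k = len(names)

    def unpack(x: np.ndarray) -> dict[str, float]:
        return dict(zip(names, map(float, x)))

    def objective(x: np.ndarray) -> float:
        theta = unpack(x)
        try:
            Sigma = implied_covariance(model, theta)
            return ml_discrepancy(S, Sigma)
        except np.linalg.LinAlgError:
            return _PENALTY * (1.0 + float(np.sum(x * x)))

    start = _ols_start(model, S_df)
    x0 = np.array([start[nm] for nm in names])
    starts = [x0]
    rng = np.random.default_rng(opts.seed)
    for _ in range(opts.n_restarts):
        xr = x0.copy()
        for i, prm in enumerate(model.free_parameters):
            if prm.kind == "var":
                xr[i] = rng.uniform(0.1, 1.2)
            else:
                xr[i] = x0[i] + rng.normal(0.0, 0.5)
        starts.append(xr)

    best = None
    for xs in starts:
        res = optimize.minimize(
            objective,
            xs,
            method="L-BFGS-B",
            options={
                "maxiter": opts.max_iter,
                "ftol": opts.f_tol * 1e-2,
                "gtol": 1e-9,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < opts.f_tol and count_df(model) == 0:
            break  # just-identified model already at its exact optimum

    theta_hat = unpack(best.x)
    f_min = max(float(best.fun), 0.0)
    # the optimizer's own flag is unreliable near an exact optimum (line
    # searches stall on machine noise); accept a perfect fit or a flat
    # gradient as convergence too
    converged = f_min < _PENALTY and (
        bool(best.success)
        or f_min <= opts.f_tol
        or float(np.max(np.abs(optimize.approx_fprime(best.x, objective, 1e-7)))) < 1e-5
    )
    df = count_df(model)
    chi2 = max((n - 1) * f_min, 0.0)
    if df > 0:
        p_chi2 = float(stats.chi2.sf(chi2, df))
    else:
        chi2 = 0.0 if chi2 < 1e-6 else chi2
        p_chi2 = float("nan")
    bic_val = bic(chi2, df, n)
    rmsea_val = rmsea(chi2, df, n) if df > 0 else float("nan")

    se: dict[str, float] = {}
    z: dict[str, float] = {}
    p_wald: dict[str, float] = {}
    if opts.compute_se and converged:
        H = _numerical_hessian(lambda x: 0.5 * (n - 1) * objective(x), best.x)
        with np.errstate(invalid="ignore"):
            cov = np.linalg.pinv(H)
            diag = np.diag(cov).copy()
            diag[diag < 0] = np.nan
            ses = np.sqrt(diag)
        for nm, s in zip(names, ses):
            se[nm] = float(s)
            z[nm] = float(theta_hat[nm] / s) if np.isfinite(s) and s > 0 else float("nan")
            p_wald[nm] = (
                float(2 * stats.norm.sf(abs(z[nm]))) if np.isfinite(z[nm]) else float("nan")
            )

    errvars = {
        prm.members[0]: theta_hat[prm.name]
        for prm in model.free_parameters
        if prm.kind == "var"
    }
    heywood = any(v < 0 for v in errvars.values())
    if heywood:
        warnings.warn(
            f"Heywood case in model {model.model_id}: negative error variance(s) "
            f"{ {k: v for k, v in errvars.items() if v < 0} }"
        )
    # Explained variance per dependent variable: 1 - (error variance / implied
    # variance).  Under the standardized fit implied variances are ~1, so this
    # reduces to 1 - error variance for endogenous variables.
    try:
        Sigma_hat = implied_covariance(model, theta_hat)
        vidx = {v: i for i, v in enumerate(model.variables)}
        r2 = {
            v: float(1.0 - errvars[v] / Sigma_hat[vidx[v], vidx[v]])
            for v in errvars
        }
    except np.linalg.LinAlgError:
        r2 = {v: float("nan") for v in errvars}

    return FitResult(
        model_id=model.model_id,
        parameters=model.free_parameters,
        estimates=theta_hat,
        se=se,
        z=z,
        p_wald=p_wald,
        f_min=f_min,
        chi2=float(chi2),
        df=df,
        p_chi2=p_chi2,
        bic=bic_val,
        rmsea=rmsea_val,
        r2=r2,
        converged=converged,
        heywood=heywood,
        n_used=n,
    )


# ----------------------------------------------------------------------
def bic(chi2: float, df: int, n: int) -> float:
    """SEM-form Bayesian Information Criterion, ``chi2 - df ln(n)``."""
    if n < 2 or df < 0:
        raise ValueError("require n >= 2 and df >= 0")
    return float(chi2 - df * np.log(n))


def rmsea(chi2: float, df: int, n: int) -> float:
    """Root mean square error of approximation,
    ``sqrt(max(chi2 - df, 0) / (df (n - 1)))``; not applicable at df = 0."""
    if df < 1:
        return float("nan")
    if n < 2:
        raise ValueError("require n >= 2")
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class BootstrapResult:
    """Percentile bootstrap confidence intervals per free parameter."""

    intervals: dict[str, tuple[float, float]]
    level: float
    n_replicates: int
    n_failed: int
    seed: int
    unreliable: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"parameter": k, "lower": lo, "upper": hi}
                for k, (lo, hi) in self.intervals.items()
            ]
        )


def bootstrap_ci(
    model: PathModel,
    table: TraitTable,
    n_replicates: int = 1999,
    alpha: float = 0.05,
    seed: int = 0,
    options: FitOptions | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap over species rows: resample with replacement,
    refit, and report percentile intervals at level ``1 - alpha``.

    Rows are canonically sorted by species name before index resampling, so
    the same seed gives identical intervals regardless of input row order.
    Replicates that fail (non-convergence or degenerate resample) are counted
    in ``n_failed`` and excluded; a result with more than half the replicates
    failed is flagged unreliable.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    opts = options or FitOptions(n_restarts=2, compute_se=False)
    opts = replace(opts, compute_se=False)
    data = table.data.sort_index(kind="stable")
    n = len(data)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n, size=(n_replicates, n))
    estimates: dict[str, list[float]] = {nm: [] for nm in model.parameter_names}
    n_failed = 0
    for idx in draws:
        sub = data.iloc[idx]
        sub = sub.reset_index(drop=True)
        try:
            fit = fit_ml(model, TraitTable(sub), opts)
            if not fit.converged:
                raise RuntimeError("non-convergence")
        except Exception:
            n_failed += 1
            continue
        for nm in estimates:
            estimates[nm].append(fit.estimates[nm])
    n_ok = n_replicates - n_failed
    unreliable = n_failed > n_replicates // 2
    if unreliable:
        warnings.warn(
            f"bootstrap unreliable: {n_failed}/{n_replicates} replicates failed"
        )
    intervals: dict[str, tuple[float, float]] = {}
    for nm, vals in estimates.items():
        if n_ok == 0:
            intervals[nm] = (float("nan"), float("nan"))
        else:
            lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            intervals[nm] = (float(lo), float(hi))
    return BootstrapResult(
        intervals=intervals,
        level=1 - alpha,
        n_replicates=n_replicates,
        n_failed=n_failed,
        seed=seed,
        unreliable=unreliable,
    )


# ----------------------------------------------------------------------
def model_selection_table(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fitted models by BIC (ascending); ties broken by larger df, then
    model id.  All fits must share the same sample size."""
    if not fits:
        raise ValueError("no fits to rank")
    ns = {f.n_used for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits mix sample sizes {sorted(ns)}; not comparable")
    rows = []
    for f in fits:
        rows.append(
            {
                "model_id": f.model_id,
                "chi2": f.chi2,
                "df": f.df,
                "p": f.p_chi2,
                "BIC": f.bic,
                "RMSEA": f.rmsea,
                "r2_R_max": f.r2.get("R_max", float("nan")),
            }
        )
    out = pd.DataFrame(rows)
    out["_negdf"] = -out["df"]
    out = (
        out.sort_values(["BIC", "_negdf", "model_id"], kind="stable")
        .drop(columns="_negdf")
        .reset_index(drop=True)
    )
    return out


def equations_report(fits: list[FitResult], models: dict[str, PathModel]) -> str:
    """Plain-text fitted structural equations, one block per model, in the
    layout ``R_max = 0.42 MMR (P = 0.059); BMR = 0.95 mb + ...``."""
    lines = []
    for fit in fits:
        model = models[fit.model_id]
        parts = []
        for v in model.endogenous:
            terms = []
            for e in model.directed_edges:
                if e.target != v:
                    continue
                nm = model.parameter_of_label(e.label)
                est = fit.estimates[nm]
                pv = fit.p_wald.get(nm, float("nan"))
                ptxt = f" (P = {pv:.3f})" if np.isfinite(pv) else ""
                terms.append(f"{est:+.3f} {e.source}{ptxt}")
            rhs = " ".join(terms).lstrip("+").strip() or "0"
            parts.append(f"{v} = {rhs}")
        for e in model.bidirectional_edges:
            nm = model.parameter_of_label(e.label)
            est = fit.estimates[nm]
            pv = fit.p_wald.get(nm, float("nan"))
            ptxt = f" (P = {pv:.3f})" if np.isfinite(pv) else ""
            parts.append(f"cov({e.var_a}, {e.var_b}) = {est:+.3f}{ptxt}")
        flags = []
        if not fit.converged:
            flags.append("NOT CONVERGED")
        if fit.heywood:
            flags.append("HEYWOOD")
        tag = f"  [{', '.join(flags)}]" if flags else ""
        lines.append(f"Model {fit.model_id}:{tag}")
        for part in parts:
            lines.append(f"  {part}")
        lines.append("")
    return "\n".join(lines)
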