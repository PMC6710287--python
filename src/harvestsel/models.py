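"""Candidate mixed models for the three behavioral traits.

Movement rate and the hunting-hour activity index are modeled with additive
(penalized-spline) Gaussian mixed models; daily distance to road with a
linear mixed model. Every candidate carries the same random structure —
bear-year nested in bear identity as random intercepts — and an AR1
residual correlation within bear-year, and candidates are ranked by AICc.

Two variables describe longevity and never co-occur in one candidate:
``fate`` (harvested this season or not) and ``remaining_lifespan`` (years
until the bear was harvested; defined only for hunting-killed bears).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .mixed import RandomBlock, fit_mixed
from .splines import SmoothBasis

CATEGORICAL_TERMS = {"fate"}
FATE_REFERENCE = "survived"


@dataclass(frozen=True)
class SmoothSpec:
    cov: str
    by: str | None = None
    k: int = 8

    def label(self) -> str:
        return f"s({self.cov})" if self.by is None else f"s({self.cov},by={self.by})"


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one candidate model."""

    name: str
    response: str
    linear_terms: tuple[str, ...] = ()
    smooth_terms: tuple[SmoothSpec, ...] = ()
    random: bool = True
    ar1: bool = True
    dataset: str = "all"  # "all" | "hunting_killed"

    def __post_init__(self):
        terms = set(self.linear_terms) | {s.cov for s in self.smooth_terms}
        if "fate" in terms and "remaining_lifespan" in terms:
            raise ValueError("fate and remaining_lifespan are alternative longevity terms")
        for s in self.smooth_terms:
            if s.by is not None and s.by not in self.linear_terms:
                raise ValueError(f"by-factor smooth {s.label()} requires {s.by} as a main effect")

    def columns(self) -> list[str]:
        cols = [self.response, *self.linear_terms]
        for s in self.smooth_terms:
            cols.append(s.cov)
            if s.by:
                cols.append(s.by)
        return list(dict.fromkeys(cols))


@dataclass
class FitResult:
    """A fitted candidate: coefficients, smooths, variance components, AICc."""

    spec: ModelSpec
    coefficients: pd.DataFrame        # term, estimate, se, lo, hi, p_value
    smooths: pd.DataFrame             # term, edf, p_value
    s2_bear: float
    s2_bearyear: float
    s2_resid: float
    ar1_phi: float
    loglik: float
    k: float
    n: int
    aicc: float
    marginal_r2: float
    converged: bool
    # prediction state
    _theta: np.ndarray = field(default=None, repr=False)
    _cov: np.ndarray = field(default=None, repr=False)
    _design: "_Design" = field(default=None, repr=False)
    _pred_cols: np.ndarray = field(default=None, repr=False)
    _data: pd.DataFrame = field(default=None, repr=False)
    _random_terms: tuple = ("bear", "bear_year")

    @property
    def name(self) -> str:
        return self.spec.name

    def coef(self, term: str) -> float:
        row = self.coefficients.loc[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["estimate"].iloc[0])


class _Design:
    """Maps covariate values to the fitted model's coefficient vector."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        self.fixed = [("(Intercept)", None, None)]  # (name, column, dummy level)
        self.reference: dict[str, str] = {}
        for term in spec.linear_terms:
            if term in CATEGORICAL_TERMS:
                levels = sorted(data[term].astype(str).unique())
                ref = FATE_REFERENCE if FATE_REFERENCE in levels else levels[0]
                for lev in levels:
                    if lev != ref:
                        self.fixed.append((f"{term}[{lev}]", term, lev))
                self.reference[term] = ref
            else:
                self.fixed.append((term, term, None))
        # smooth bases; by-level smooths share one variance component per term
        self.smooth_bases: dict[str, list[SmoothBasis]] = {}
        self.smooth_fixed_names: dict[str, list[str]] = {}
        for s in spec.smooth_terms:
            bases = []
            if s.by is None:
                bases.append(SmoothBasis(cov=s.cov, k=s.k).fit(data[s.cov].to_numpy()))
            else:
                for lev in sorted(data[s.by].astype(str).unique()):
                    mask = data[s.by].astype(str) == lev
                    b = SmoothBasis(cov=s.cov, k=s.k, by=s.by, by_level=lev)
                    b.fit(data.loc[mask, s.cov].to_numpy())
                    bases.append(b)
            self.smooth_bases[s.label()] = bases
        self.means = {
            c: float(data[c].mean())
            for c in data.columns
            if c not in CATEGORICAL_TERMS and pd.api.types.is_numeric_dtype(data[c])
        }
        self.observed_range = {
            c: (float(data[c].min()), float(data[c].max())) for c in self.means
        }

    def fixed_matrix(self, data: pd.DataFrame) -> np.ndarray:
        cols = []
        for name, col, lev in self.fixed:
            if col is None:
                cols.append(np.ones(len(data)))
            elif lev is not None:
                cols.append((data[col].astype(str) == lev).to_numpy(float))
            else:
                cols.append(data[col].to_numpy(float))
        return np.column_stack(cols)

    def smooth_matrices(self, data: pd.DataFrame):
        """Per smooth term: (null-space columns, range-space columns)."""
        out = {}
        for label, bases in self.smooth_bases.items():
            nulls, ranges = [], []
            for b in bases:
                xn, xr = b.transform(data[b.cov].to_numpy())
                if b.by is not None:
                    m = (data[b.by].astype(str) == str(b.by_level)).to_numpy(float)[:, None]
                    xn, xr = xn * m, xr * m
                nulls.append(xn)
                ranges.append(xr)
            out[label] = (np.hstack(nulls), np.hstack(ranges))
        return out

    def row(self, values: dict) -> np.ndarray:
        """One full design row (fixed + smooth columns, theta order)."""
        df = pd.DataFrame([values])
        parts = [self.fixed_matrix(df)[0]]
        sm = self.smooth_matrices(df)
        for label in self.smooth_bases:
            parts.append(sm[label][0][0])
        for label in self.smooth_bases:
            parts.append(sm[label][1][0])
        return np.concatenate(parts)


def _time_sort(data: pd.DataFrame) -> pd.DataFrame:
    order = ["bear_id", "bear_year"]
    for c in ("timestamp", "date"):
        if c in data.columns:
            order.append(c)
            break
    return data.sort_values(order, kind="mergesort").reset_index(drop=True)


def fit_model(
    spec: ModelSpec,
    data: pd.DataFrame,
    maxiter: int = 200,
    random_terms: tuple[str, ...] = ("bear", "bear_year"),
) -> FitResult:
    """Fit one candidate model by maximum likelihood.

    ``random_terms`` selects which nested intercepts enter when
    ``spec.random`` is set; the repeatability likelihood-ratio test refits
    with the bear-level intercept removed.
    """
    needed = spec.columns() + ["bear_id", "bear_year"]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks columns {missing}")
    df = data.dropna(subset=needed)
    df = _time_sort(df)
    n = len(df)
    if n == 0:
        raise ValueError("no rows left after dropping missing values")

    design = _Design(spec, df)
    x = design.fixed_matrix(df)
    smooth_mats = design.smooth_matrices(df)

    fixed_names = [f[0] for f in design.fixed]
    smooth_null_cols: dict[str, list[int]] = {}
    for label in design.smooth_bases:
        xn, _ = smooth_mats[label]
        idx = list(range(x.shape[1], x.shape[1] + xn.shape[1]))
        smooth_null_cols[label] = idx
        fixed_names += [f"{label}.null{j}" for j in range(xn.shape[1])]
        x = np.hstack([x, xn])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(f"rank-deficient fixed-effect design for {spec.name}")

    blocks: list[RandomBlock] = []
    if spec.random:
        columns = {"bear": "bear_id", "bear_year": "bear_year"}
        for name in random_terms:
            col = columns[name]
            codes = pd.factorize(df[col])[0]
            z = sparse.csr_matrix(
                (np.ones(n), (np.arange(n), codes)), shape=(n, codes.max() + 1)
            )
            blocks.append(RandomBlock(name, z))
    for label in design.smooth_bases:
        _, xr = smooth_mats[label]
        blocks.append(RandomBlock(label, sparse.csr_matrix(xr)))

    groups = pd.factorize(df["bear_year"])[0]
    fit = fit_mixed(
        df[spec.response].to_numpy(float), x, blocks,
        groups=groups, ar1=spec.ar1, maxiter=maxiter,
    )

    p = x.shape[1]
    n_plain_fixed = len(design.fixed)
    se = fit.se()

    # linear coefficients with Wald 95% CIs
    rows = []
    for j in range(n_plain_fixed):
        est, s = fit.beta[j], se[j]
        zval = est / s if s > 0 else np.inf
        rows.append(
            dict(term=fixed_names[j], estimate=est, se=s,
                 lo=est - 1.96 * s, hi=est + 1.96 * s,
                 p_value=2 * stats.norm.sf(abs(zval)))
        )
    coefficients = pd.DataFrame(rows)

    # smooth edf and Wald-type p-values on the penalized coefficients
    srows = []
    edf_by_smooth = {}
    theta = np.concatenate([fit.beta, fit.b])
    for label in design.smooth_bases:
        sl = fit.block_slices[label]
        cols = list(smooth_null_cols[label]) + list(range(sl.start, sl.stop))
        edf = float(fit.edf[cols].sum())
        edf_by_smooth[label] = edf
        cvec = theta[cols]
        vsub = fit.cov[np.ix_(cols, cols)]
        try:
            tstat = float(cvec @ np.linalg.pinv(vsub, rcond=1e-10) @ cvec)
        except np.linalg.LinAlgError:
            tstat = np.nan
        dof = max(1, int(round(edf)))
        srows.append(dict(term=label, edf=edf, p_value=stats.chi2.sf(tstat, dof)))
    smooths = pd.DataFrame(srows, columns=["term", "edf", "p_value"])

    s2_bear = fit.variances.get("bear", 0.0)
    s2_bearyear = fit.variances.get("bear_year", 0.0)
    s2_resid = fit.sigma2

    n_var_params = len([b for b in blocks if b.name in ("bear", "bear_year")])
    k = n_plain_fixed + sum(edf_by_smooth.values()) + n_var_params + (1 if spec.ar1 else 0) + 1

    # fixed-effect (incl. smooth) predictions for marginal R^2
    pred_cols = np.concatenate(
        [np.arange(p)]
        + [np.arange(fit.block_slices[l].start, fit.block_slices[l].stop)
           for l in design.smooth_bases]
    ).astype(int) if design.smooth_bases else np.arange(p)
    xfull = np.hstack([x] + [smooth_mats[l][1] for l in design.smooth_bases]) \
        if design.smooth_bases else x
    yhat_fixed = xfull @ theta[pred_cols]
    var_f = float(np.var(yhat_fixed))
    total = var_f + s2_bear + s2_bearyear + s2_resid
    if total <= 0:
        raise ValueError("zero total variance; marginal R^2 undefined")
    r2 = var_f / total

    return FitResult(
        spec=spec,
        coefficients=coefficients,
        smooths=smooths,
        s2_bear=float(s2_bear),
        s2_bearyear=float(s2_bearyear),
        s2_resid=float(s2_resid),
        ar1_phi=fit.phi,
        loglik=fit.loglik,
        k=float(k),
        n=n,
        aicc=aicc(fit.loglik, k, n),
        marginal_r2=float(r2),
        converged=fit.converged,
        _theta=theta,
        _cov=fit.cov,
        _design=design,
        _pred_cols=pred_cols,
        _data=df,
        _random_terms=tuple(random_terms),
    )


def aicc(fit, k: float | None = None, n: int | None = None) -> float:
    """Small-sample Akaike information criterion.

    Accepts either a fitted result or ``(loglik, k, n)`` directly.
    """
    if isinstance(fit, FitResult):
        loglik, k, n = fit.loglik, fit.k, fit.n
    else:
        loglik = float(fit)
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass
class Ranking:
    table: pd.DataFrame
    best: FitResult


def rank_models(fits: list[FitResult]) -> Ranking:
    """Ascending-AICc table; ties (delta < 2) resolved toward fewest
    effective parameters."""
    ok = [f for f in fits if f.converged]
    for f in fits:
        if not f.converged:
            warnings.warn(f"model {f.name} did not converge; excluded from ranking")
    if not ok:
        raise ValueError("no converged candidate models")
    tab = pd.DataFrame(
        dict(
            model=[f.name for f in ok],
            k=[f.k for f in ok],
            loglik=[f.loglik for f in ok],
            aicc=[f.aicc for f in ok],
        )
    ).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].iloc[0]
    close = tab[tab["delta_aicc"] < 2.0]
    best_name = close.loc[close["k"].idxmin(), "model"]
    best = next(f for f in ok if f.name == best_name)
    tab["selected"] = tab["model"] == best_name
    return Ranking(table=tab, best=best)


def marginal_r2(fit: FitResult) -> float:
    """Variance explained by fixed effects (incl. smooths) over total."""
    return fit.marginal_r2


def predict_curve(
    fit: FitResult,
    covariate: str,
    grid,
    holding: dict | None = None,
    backtransform: bool = False,
) -> pd.DataFrame:
    """Fixed-effect prediction with pointwise 95% CIs along ``grid``.

    Other covariates are held at ``holding`` (defaults: training means,
    reference fate). ``backtransform`` exponentiates log-scale responses.
    """
    design = fit._design
    holding = dict(holding or {})
    base = {}
    for name, col, lev in design.fixed:
        if col is not None and col not in base:
            base[col] = design.reference.get(col, design.means.get(col, 0.0))
    for bases in design.smooth_bases.values():
        for b in bases:
            base.setdefault(b.cov, design.means.get(b.cov, 0.0))
            if b.by is not None:
                base.setdefault(b.by, design.reference.get(b.by))
    base.update(holding)

    lo_hi = design.observed_range.get(covariate)
    grid = np.asarray(grid, dtype=float)
    if lo_hi and (grid.min() < lo_hi[0] or grid.max() > lo_hi[1]):
        warnings.warn(f"grid extends beyond observed range of {covariate}; extrapolating")

    out = []
    for g in grid:
        values = dict(base)
        values[covariate] = g
        row = fit._design.row(values)
        pred = float(row @ fit._theta[fit._pred_cols])
        var = float(row @ fit._cov[np.ix_(fit._pred_cols, fit._pred_cols)] @ row)
        sd = np.sqrt(max(var, 0.0))
        out.append((g, pred, pred - 1.96 * sd, pred + 1.96 * sd))
    df = pd.DataFrame(out, columns=[covariate, "fit", "lo", "hi"])
    if backtransform:
        for c in ("fit", "lo", "hi"):
            df[c] = np.exp(df[c])
    return df


def build_candidate_set(trait: str, sex: str | None = None) -> list[ModelSpec]:
    """Hierarchical candidate ladder for one trait.

    Rungs: (1) intercept-only; (2) control covariates; (3) controls + hunting
    season fate (with by-fate smooths for movement); (4) controls + remaining
    lifespan (fit on hunting-killed bears only). All rungs share the nested
    random intercepts and AR1 residuals.
    """
    tag = f"{sex}_" if sex else ""
    if trait == "movement":
        controls = (SmoothSpec("hour"), SmoothSpec("julian_date"), SmoothSpec("age", k=6))
        return [
            ModelSpec(f"{tag}movement_null", "log_rate"),
            ModelSpec(f"{tag}movement_controls", "log_rate", smooth_terms=controls),
            ModelSpec(
                f"{tag}movement_fate", "log_rate",
                linear_terms=("fate",),
                smooth_terms=(
                    SmoothSpec("hour", by="fate", k=6),
                    SmoothSpec("julian_date", by="fate", k=6),
                    SmoothSpec("age", k=6),
                ),
            ),
            ModelSpec(
                f"{tag}movement_lifespan", "log_rate",
                linear_terms=("remaining_lifespan",),
                smooth_terms=controls, dataset="hunting_killed",
            ),
        ]
    if trait == "activity":
        controls = (SmoothSpec("julian_date"), SmoothSpec("age", k=6))
        return [
            ModelSpec(f"{tag}activity_null", "activity_index"),
            ModelSpec(f"{tag}activity_controls", "activity_index", smooth_terms=controls),
            ModelSpec(f"{tag}activity_fate", "activity_index",
                      linear_terms=("fate",), smooth_terms=controls),
            ModelSpec(f"{tag}activity_lifespan", "activity_index",
                      linear_terms=("remaining_lifespan",), smooth_terms=controls,
                      dataset="hunting_killed"),
        ]
    if trait == "distance":
        controls = ("age", "julian_date", "road_density")
        return [
            ModelSpec(f"{tag}distance_null", "log_dist"),
            ModelSpec(f"{tag}distance_controls", "log_dist", linear_terms=controls),
            ModelSpec(f"{tag}distance_fate", "log_dist", linear_terms=controls + ("fate",)),
            ModelSpec(f"{tag}distance_lifespan", "log_dist",
                      linear_terms=controls + ("remaining_lifespan",),
                      dataset="hunting_killed"),
        ]
    raise ValueError(f"unknown trait {trait!r}; expected movement/activity/distance")
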