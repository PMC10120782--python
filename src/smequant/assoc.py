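"""Association engine: distribution tests, adjusted linear models, trend
and effect-modification tests, and multiple imputation with Rubin pooling.

The analysis mirrors a standard epidemiological workflow for a continuous
tissue phenotype:

* Kruskal-Wallis tests compare outcome distributions across categories.
* Ordinary least squares estimates per-category effects with dummy coding
  against a stated reference; *partially adjusted* models add age, study
  site and tissue area; *mutually adjusted* models additionally include
  the other exposures.
* Trend tests replace category dummies with consecutive integer scores.
* Effect modification is tested by a joint Wald chi-square on exposure x
  modifier product terms, with stratum-specific effects from linear
  combinations of the coefficients.
* Missing tumor-marker values are handled by chained-equation multiple
  imputation (logistic/multinomial draws on bootstrapped fits) and the
  per-imputation estimates combined by Rubin's rules with Barnard-Rubin
  small-sample degrees of freedom.

All p-values are two-sided; the conventional significance level is 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .synthcohort import CATEGORY_ORDERS, TUMOR_VARIABLES, derive_subtype

ALPHA = 0.05

# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Ties-corrected Kruskal-Wallis H and chi-square p across groups.

    Rows with missing value or group are dropped; requires at least two
    non-empty groups.  When every observation is tied the statistic is 0
    (p = 1) rather than the 0/0 the ties correction would produce.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    keep = ~pd.isna(values) & ~pd.isna(groups)
    values, groups = values[keep], groups[keep]
    samples = [values[groups == g] for g in pd.unique(groups)]
    samples = [s for s in samples if s.size > 0]
    if len(samples) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 non-empty groups")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    res = stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Model specification and design matrices
# ---------------------------------------------------------------------------

DEFAULT_MUTUAL_EXPOSURES = ("menarche_cat", "parity_status", "body_size", "fhbc")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one adjusted linear model.

    ``adjustment`` is 'partial' (exposure + age + site + tissue area) or
    'mutual' (additionally the other exposures in ``mutual_exposures``).
    Age enters as its 4-level category by default; set
    ``age_continuous=True`` for years.  ``trend_scores`` overrides the
    default consecutive integer scores used by the trend test.
    """

    outcome: str = "tascd_percent"
    exposure: str = "parity_status"
    reference: str | None = None  # default: first level in category order
    adjustment: str = "partial"
    mutual_exposures: tuple[str, ...] = DEFAULT_MUTUAL_EXPOSURES
    age_continuous: bool = False
    trend_scores: dict[str, float] | None = None
    modifier: str | None = None

    def __post_init__(self):
        if self.adjustment not in ("partial", "mutual"):
            raise ValueError("adjustment must be 'partial' or 'mutual'")
        if self.exposure not in CATEGORY_ORDERS:
            raise ValueError(f"unknown exposure {self.exposure!r}")
        ref = self.reference
        if ref is not None and ref not in CATEGORY_ORDERS[self.exposure]:
            raise ValueError(f"reference {ref!r} is not a level of {self.exposure!r}")

    @property
    def reference_level(self) -> str:
        return self.reference or CATEGORY_ORDERS[self.exposure][0]

    def adjustment_variables(self) -> list[str]:
        out = ["site", "tissue_area_mm2", "age_years" if self.age_continuous else "age_group"]
        if self.adjustment == "mutual":
            out += [v for v in self.mutual_exposures if v != self.exposure]
        return out


def _levels_present(df: pd.DataFrame, var: str) -> list[str]:
    present = set(df[var].dropna().astype(str))
    return [l for l in CATEGORY_ORDERS[var] if l in present]


def _dummies(df: pd.DataFrame, var: str, reference: str) -> pd.DataFrame:
    levels = _levels_present(df, var)
    cols = {}
    if len(levels) > 1:  # a single observed level is the de facto reference
        for lvl in levels:
            if lvl == reference or (reference not in levels and lvl == levels[0]):
                continue
            cols[f"{var}[{lvl}]"] = (df[var].astype(str) == lvl).astype(float)
    return pd.DataFrame(cols, index=df.index)


def build_design(df: pd.DataFrame, spec: ModelSpec, include_exposure: bool = True):
    """Complete-case design matrix (with intercept) and outcome vector."""
    used = [spec.outcome, spec.exposure] + [
        v for v in spec.adjustment_variables() if v in df.columns or v in CATEGORY_ORDERS
    ]
    data = df.dropna(subset=[c for c in used if c in df.columns])
    y = data[spec.outcome].astype(float)
    parts = [pd.Series(1.0, index=data.index, name="Intercept")]
    if include_exposure:
        parts.append(_dummies(data, spec.exposure, spec.reference_level))
    for var in spec.adjustment_variables():
        if var in CATEGORY_ORDERS:
            parts.append(_dummies(data, var, CATEGORY_ORDERS[var][0]))
        else:
            parts.append(data[var].astype(float))
    X = pd.concat(parts, axis=1)
    _check_full_rank(X)
    return X, y, data


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        _, r = np.linalg.qr(mat)
        aliased = [X.columns[i] for i in range(mat.shape[1]) if abs(r[i, i]) < 1e-8]
        raise ValueError(f"collinear design; aliased terms: {aliased}")


# ---------------------------------------------------------------------------
# Single-dataset fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermResult:
    term: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class LinearFitResult:
    terms: dict[str, TermResult]
    exposure_terms: tuple[str, ...]
    df_resid: float
    n: int
    model: object = None  # statsmodels results, kept for Wald tests


def fit_linear(cohort: pd.DataFrame, spec: ModelSpec) -> LinearFitResult:
    """OLS fit of one adjusted model on the complete cases.

    Returns per-term estimates (beta, SE, 95% CI, two-sided p) with the
    exposure's non-reference levels flagged.  A rank-deficient design
    raises with the aliased term names.
    """
    X, y, data = build_design(cohort, spec)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=ALPHA)
    terms = {
        name: TermResult(
            term=name,
            beta=float(res.params[name]),
            se=float(res.bse[name]),
            ci_low=float(ci.loc[name, 0]),
            ci_high=float(ci.loc[name, 1]),
            p_value=float(res.pvalues[name]),
        )
        for name in X.columns
    }
    exposure_terms = tuple(c for c in X.columns if c.startswith(f"{spec.exposure}["))
    return LinearFitResult(
        terms=terms,
        exposure_terms=exposure_terms,
        df_resid=float(res.df_resid),
        n=int(res.nobs),
        model=res,
    )


@dataclass(frozen=True)
class TrendResult:
    slope: float
    se: float
    p_trend: float
    scores: dict[str, float]
    n: int


def trend_test(cohort: pd.DataFrame, spec: ModelSpec) -> TrendResult:
    """Ordinal trend test: integer scores replace the category dummies.

    Levels are scored 0, 1, 2, ... in category order (``spec.trend_scores``
    overrides); 'n/a' levels (structurally inapplicable, e.g. nulliparous
    women in a breastfeeding exposure) are excluded.  Requires an ordinal
    exposure with at least 3 represented levels.
    """
    levels = [l for l in _levels_present(cohort, spec.exposure) if l != "n/a"]
    if len(levels) < 3:
        raise ValueError(
            f"trend test needs an ordinal exposure with >= 3 levels; "
            f"{spec.exposure!r} has {len(levels)}"
        )
    scores = spec.trend_scores or {l: float(i) for i, l in enumerate(levels)}
    data = cohort[cohort[spec.exposure].astype(str).isin(scores)]
    X, y, data = build_design(data, spec, include_exposure=False)
    X = X.copy()
    X.insert(1, "__score__", data[spec.exposure].astype(str).map(scores).astype(float))
    res = sm.OLS(y, X).fit()
    return TrendResult(
        slope=float(res.params["__score__"]),
        se=float(res.bse["__score__"]),
        p_trend=float(res.pvalues["__score__"]),
        scores=scores,
        n=int(res.nobs),
    )


@dataclass
class StratumEffect:
    modifier_level: str
    term: str
    beta: float
    se: float


@dataclass
class HeterogeneityResult:
    p_heterogeneity: float
    stratum_effects: list[StratumEffect]
    n: int


def heterogeneity_test(cohort: pd.DataFrame, spec: ModelSpec) -> HeterogeneityResult:
    """Multiplicative effect-modification test.

    Fits the full model with exposure x modifier product terms and reports
    the joint Wald chi-square p over all products, plus stratum-specific
    exposure effects reconstructed by linear combination.  Raises when the
    spec has no modifier, the modifier has < 2 levels, or any exposure x
    modifier cell is empty.
    """
    if spec.modifier is None:
        raise ValueError("spec.modifier must be set for a heterogeneity test")
    mod = spec.modifier
    used = [spec.outcome, spec.exposure, mod] + [
        v for v in spec.adjustment_variables() if v in cohort.columns
    ]
    data = cohort.dropna(subset=[c for c in used if c in cohort.columns])
    mod_levels = _levels_present(data, mod)
    if len(mod_levels) < 2:
        raise ValueError(f"modifier {mod!r} has fewer than 2 levels")
    exp_levels = _levels_present(data, spec.exposure)
    cells = pd.crosstab(data[spec.exposure], data[mod])
    empty = [
        (e, m_)
        for e in exp_levels
        for m_ in mod_levels
        if e not in cells.index or m_ not in cells.columns or cells.loc[e, m_] == 0
    ]
    if empty:
        raise ValueError(f"empty exposure x modifier cells: {empty}")

    spec_wo_mod = replace(spec, modifier=None)
    X, y, data = build_design(data, spec_wo_mod)
    mod_dum = _dummies(data, mod, mod_levels[0])
    X = pd.concat([X, mod_dum], axis=1)
    product_terms = []
    for e in exp_levels[1:]:
        for m_ in mod_levels[1:]:
            name = f"{spec.exposure}[{e}]:{mod}[{m_}]"
            X[name] = X[f"{spec.exposure}[{e}]"] * mod_dum[f"{mod}[{m_}]"]
            product_terms.append(name)
    _check_full_rank(X)
    res = sm.OLS(y, X).fit()

    r_matrix = np.zeros((len(product_terms), X.shape[1]))
    for i, name in enumerate(product_terms):
        r_matrix[i, X.columns.get_loc(name)] = 1.0
    wald = res.wald_test(r_matrix, use_f=False, scalar=True)
    p_het = float(wald.pvalue)

    cov = res.cov_params()
    strata: list[StratumEffect] = []
    for m_ in mod_levels:
        for e in exp_levels[1:]:
            base = f"{spec.exposure}[{e}]"
            beta = res.params[base]
            var = cov.loc[base, base]
            if m_ != mod_levels[0]:
                prod = f"{base}:{mod}[{m_}]"
                beta = beta + res.params[prod]
                var = var + cov.loc[prod, prod] + 2 * cov.loc[base, prod]
            strata.append(
                StratumEffect(modifier_level=m_, term=base, beta=float(beta), se=float(np.sqrt(var)))
            )
    return HeterogeneityResult(p_heterogeneity=p_het, stratum_effects=strata, n=int(res.nobs))


# ---------------------------------------------------------------------------
# Multiple imputation by chained equations
# ---------------------------------------------------------------------------

_MICE_NUMERIC_PREDICTORS = ("tascd_percent", "tsr_percent", "tissue_area_mm2")
_MICE_CATEGORICAL_PREDICTORS = (
    "site",
    "age_group",
    "parity_status",
    "body_size",
    "fhbc",
    "menarche_cat",
)


def _encode_predictors(df: pd.DataFrame, exclude: str, variables) -> np.ndarray:
    parts = [df[c].astype(float).to_numpy()[:, None] for c in _MICE_NUMERIC_PREDICTORS if c in df]
    for var in _MICE_CATEGORICAL_PREDICTORS + tuple(v for v in variables if v != exclude):
        for lvl in CATEGORY_ORDERS[var][1:]:
            parts.append((df[var].astype(str).to_numpy() == lvl).astype(float)[:, None])
    X = np.hstack(parts)
    # standardise numeric block for solver stability
    mu, sd = X.mean(axis=0), X.std(axis=0)
    return (X - mu) / np.where(sd > 0, sd, 1.0)


def mice_impute(
    cohort: pd.DataFrame,
    m: int = 5,
    n_iter: int = 5,
    seed: int = 0,
    variables: tuple[str, ...] | None = None,
) -> list[pd.DataFrame]:
    """Chained-equation multiple imputation of categorical tumor variables.

    Each incomplete variable is imputed from a logistic (binary) or
    multinomial (>= 3 levels) model fitted on a bootstrap of the observed
    rows, drawing imputed categories from the predicted probabilities --
    an approximately proper imputation that preserves between-imputation
    variance.  ``m`` independent streams of ``n_iter`` sweeps each;
    observed values are never altered; reproducible per seed.
    """
    incomplete = [
        c for c in cohort.columns if c != "subtype" and cohort[c].isna().any()
    ]
    bad = [c for c in incomplete if c not in TUMOR_VARIABLES]
    if bad:
        raise ValueError(f"missingness outside designated tumor variables: {bad}")
    if variables is None:
        variables = tuple(incomplete)
    for var in variables:
        if cohort[var].isna().all():
            raise ValueError(f"variable {var!r} is 100% missing; cannot impute")
    if not variables:
        return [cohort.copy() for _ in range(m)]

    # ascending missingness: best-observed variables imputed first
    variables = tuple(sorted(variables, key=lambda v: cohort[v].isna().sum()))
    children = np.random.SeedSequence(seed).spawn(m)
    completed = []
    for k in range(m):
        rng = np.random.default_rng(children[k])
        df = cohort.copy()
        obs_mask = {v: cohort[v].notna().to_numpy() for v in variables}
        for var in variables:  # initial fill: draw from observed marginal
            obs = df.loc[obs_mask[var], var].astype(str).to_numpy()
            n_miss = int((~obs_mask[var]).sum())
            if n_miss:
                df.loc[~obs_mask[var], var] = rng.choice(obs, size=n_miss)
        for _ in range(n_iter):
            for var in variables:
                miss = ~obs_mask[var]
                if not miss.any():
                    continue
                X = _encode_predictors(df, var, variables)
                y = df[var].astype(str).to_numpy()
                obs_idx = np.flatnonzero(obs_mask[var])
                boot = rng.choice(obs_idx, size=obs_idx.size, replace=True)
                classes = np.unique(y[boot])
                if classes.size < 2:
                    df.loc[miss, var] = classes[0]
                    continue
                clf = LogisticRegression(max_iter=300, C=10.0)
                clf.fit(X[boot], y[boot])
                proba = clf.predict_proba(X[miss])
                cum = proba.cumsum(axis=1)
                u = rng.uniform(size=proba.shape[0])
                picks = (u[:, None] > cum).sum(axis=1)
                df.loc[miss, var] = clf.classes_[picks]
        if {"er", "pr", "her2"} <= set(df.columns):
            df["subtype"] = [
                derive_subtype(e, p, h) for e, p, h in zip(df["er"], df["pr"], df["her2"])
            ]
        completed.append(df)
    return completed


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PooledRegressionResult:
    term: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    m: int
    within_var: float  # W = mean(SE^2)
    between_var: float  # B = sample variance of betas
    total_var: float  # T = W + (1 + 1/m) B
    df: float
    p_trend: float | None = None


def rubin_pool(
    betas, ses, term: str = "", df_complete: float | None = None
) -> PooledRegressionResult:
    """Pool per-imputation estimates of one coefficient by Rubin's rules.

    pooled beta = mean(betas); W = mean(se^2); B = sample variance of the
    betas; T = W + (1 + 1/m) B.  Degrees of freedom follow Barnard-Rubin
    when the complete-data df is supplied, else the classical large-sample
    formula; with B = 0 (identical imputations) the result collapses to
    the complete-data fit.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape or betas.size < 1:
        raise ValueError("betas and ses must be aligned, non-empty vectors")
    m = betas.size
    qbar = float(betas.mean())
    W = float(np.mean(ses**2))
    B = float(betas.var(ddof=1)) if m > 1 else 0.0
    T = W + (1.0 + 1.0 / m) * B

    if B == 0.0 or m == 1:
        df = df_complete if df_complete is not None else np.inf
    else:
        lam = (1.0 + 1.0 / m) * B / T
        df_old = (m - 1) / lam**2
        if df_complete is not None:  # Barnard-Rubin adjustment
            nu_com = df_complete
            nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / nu_obs)
        else:
            df = df_old
    se = np.sqrt(T)
    tdist = stats.t(df) if np.isfinite(df) else stats.norm()
    tcrit = float(tdist.ppf(1 - ALPHA / 2))
    p = float(2.0 * tdist.sf(abs(qbar) / se)) if se > 0 else (0.0 if qbar != 0 else 1.0)
    return PooledRegressionResult(
        term=term,
        beta=qbar,
        se=float(se),
        ci_low=qbar - tcrit * float(se),
        ci_high=qbar + tcrit * float(se),
        p_value=p,
        m=m,
        within_var=W,
        between_var=B,
        total_var=T,
        df=float(df),
    )


def pool_fits(fits: list[LinearFitResult]) -> dict[str, PooledRegressionResult]:
    """Rubin-pool aligned per-term results from m imputed-data fits."""
    if not fits:
        raise ValueError("no fits to pool")
    term_sets = [tuple(f.terms) for f in fits]
    if len(set(term_sets)) != 1:
        raise ValueError(f"mismatched term sets across imputations: {sorted(set(term_sets))}")
    df_com = min(f.df_resid for f in fits)
    return {
        t: rubin_pool(
            [f.terms[t].beta for f in fits],
            [f.terms[t].se for f in fits],
            term=t,
            df_complete=df_com,
        )
        for t in fits[0].terms
    }


def pooled_fit(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    m: int = 5,
    n_iter: int = 5,
    seed: int = 0,
) -> dict[str, PooledRegressionResult]:
    """MICE(m) + OLS + Rubin pooling of one adjusted model."""
    fits = [fit_linear(imp, spec) for imp in mice_impute(cohort, m=m, n_iter=n_iter, seed=seed)]
    return pool_fits(fits)


def pooled_trend(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    m: int = 5,
    n_iter: int = 5,
    seed: int = 0,
) -> PooledRegressionResult:
    """MICE + Rubin pooling of the ordinal trend coefficient."""
    trends = [
        trend_test(imp, spec) for imp in mice_impute(cohort, m=m, n_iter=n_iter, seed=seed)
    ]
    res = rubin_pool([t.slope for t in trends], [t.se for t in trends], term="__score__")
    return res


# ---------------------------------------------------------------------------
# Report shaping
# ---------------------------------------------------------------------------


def _round_half_up(x: float, ndigits: int = 2) -> str:
    q = Decimal(1).scaleb(-ndigits)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_beta_ci(beta: float, ci_low: float, ci_high: float) -> str:
    """Render "beta (low, high)" to 2 decimals with half-up rounding."""
    return f"{_round_half_up(beta)} ({_round_half_up(ci_low)}, {_round_half_up(ci_high)})"


REFERENCE_CELL = "1.00 (reference)"


def association_table(
    blocks: list[tuple[str, dict[str, PooledRegressionResult] | dict[str, TermResult], float | None]],
) -> pd.DataFrame:
    """Regression report: per-exposure blocks of "beta (95% CI)" rows.

    ``blocks`` is a list of (exposure, per-term results, p_trend or None).
    The reference category row is rendered "1.00 (reference)"; empty
    blocks are omitted with a warning.
    """
    rows = []
    for exposure, results, p_trend in blocks:
        terms = [t for t in results if t.startswith(f"{exposure}[")]
        if not terms:
            warnings.warn(f"no estimable terms for exposure {exposure!r}; block omitted")
            continue
        ref = CATEGORY_ORDERS.get(exposure, [None])[0]
        rows.append(
            {"exposure": exposure, "level": ref, "beta_ci": REFERENCE_CELL, "p_trend": ""}
        )
        for i, t in enumerate(terms):
            r = results[t]
            rows.append(
                {
                    "exposure": exposure,
                    "level": t[t.index("[") + 1 : -1],
                    "beta_ci": format_beta_ci(r.beta, r.ci_low, r.ci_high),
                    "p_trend": (
                        _round_half_up(p_trend, 3)
                        if (p_trend is not None and i == len(terms) - 1)
                        else ""
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["exposure", "level", "beta_ci", "p_trend"])


def distribution_table(
    cohort: pd.DataFrame, outcome: str, characteristics: list[str]
) -> pd.DataFrame:
    """Outcome distribution by category: mean (SD), median (range), KW p."""
    rows = []
    for var in characteristics:
        values = cohort[outcome]
        groups = cohort[var]
        keep = groups.notna() & values.notna() & (groups.astype(str) != "n/a")
        try:
            _, p = kruskal_wallis(values[keep], groups[keep])
        except ValueError:
            p = np.nan
        levels = _levels_present(cohort[keep.to_numpy()], var)
        for i, lvl in enumerate(levels):
            v = values[keep & (groups.astype(str) == lvl)]
            rows.append(
                {
                    "characteristic": var,
                    "level": lvl,
                    "mean_sd": f"{_round_half_up(v.mean(), 1)} ({_round_half_up(v.std(ddof=1), 1)})",
                    "median_range": (
                        f"{_round_half_up(v.median(), 1)} "
                        f"({_round_half_up(v.min(), 1)}-{_round_half_up(v.max(), 1)})"
                    ),
                    "p_value": _round_half_up(p, 4) if i == len(levels) - 1 else "",
                }
            )
    return pd.DataFrame(rows, columns=["characteristic", "level", "mean_sd", "median_range", "p_value"])
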