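"""Synthetic breast-cancer cohort generator.

Produces patient-level tables with the covariate structure of a West
African hospital-based breast-cancer case series: reproductive history
(menarche, parity, number of children, age at first birth, breastfeeding),
body-size phenotype, family history, tumor markers (ER/PR/HER2, grade,
size) with missing-at-random gaps, per-slide tissue area, and the two
stromal-microenvironment outcomes (TSR %, Ta-SCD %).

Category marginals default to a published cohort frequency table shipped
with the package (``data/reference_cohort_margins.csv``).  Risk-factor
effects on the outcomes are injected additively through an
:class:`EffectSpec`, giving known truth for parameter-recovery tests of
the association engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

CATEGORY_ORDERS: dict[str, list[str]] = {
    "site": ["A", "B", "C"],
    "age_group": ["<35", "35-44", "45-54", ">=55"],
    "menarche_cat": ["<15", "15", "16", ">=17"],
    "parity_status": ["nulliparous", "parous"],
    "n_children": ["0", "1", "2", "3", "4", ">=5"],
    "afb_cat": ["<19", "19-21", "22-25", ">=26", "n/a"],
    "breastfeeding_cat": ["<13", "13-18", ">=19", "n/a"],
    "body_size": ["slight", "moderate", "heavy"],
    "fhbc": ["no", "yes"],
    "er": ["neg", "pos"],
    "pr": ["neg", "pos"],
    "her2": ["neg", "pos"],
    "grade": ["1", "2", "3"],
    "size_cat": ["<2", "2-5", ">5"],
    "subtype": ["luminal A-like", "luminal B-like", "HER2-enriched", "TNBC"],
}

#: variables eligible for injected missingness (tumor pathology data)
TUMOR_VARIABLES = ("er", "pr", "her2", "grade", "size_cat")

# joint (er, pr, her2) distribution chosen to match published marker and
# subtype marginals: ER+ 53%, PR+ 52%, HER2+ 26%, subtypes ~30/34/8/28%
_MARKER_JOINT = {
    ("pos", "pos", "neg"): 0.300,
    ("pos", "pos", "pos"): 0.110,
    ("pos", "neg", "pos"): 0.030,
    ("neg", "pos", "pos"): 0.040,
    ("pos", "neg", "neg"): 0.090,
    ("neg", "pos", "neg"): 0.070,
    ("neg", "neg", "pos"): 0.084,
    ("neg", "neg", "neg"): 0.276,
}

_AGE_RANGES = {"<35": (17, 34), "35-44": (35, 44), "45-54": (45, 54), ">=55": (55, 84)}


def load_reference_margins() -> pd.DataFrame:
    """Published cohort category counts (variable, level, count)."""
    with resources.files("smequant.data").joinpath("reference_cohort_margins.csv").open() as fh:
        return pd.read_csv(fh)


def reference_marginal(variable: str, margins: pd.DataFrame | None = None) -> dict[str, float]:
    """Observed category proportions of one variable from the reference table."""
    margins = load_reference_margins() if margins is None else margins
    sub = margins[margins["variable"] == variable]
    if sub.empty:
        raise KeyError(f"no reference margins for {variable!r}")
    total = sub["count"].sum()
    return dict(zip(sub["level"].astype(str), sub["count"] / total))


def derive_subtype(er, pr, her2):
    """Intrinsic-like subtype from the three-marker rule.

    luminal A-like = ER+/PR+/HER2-; HER2-enriched = ER-/PR-/HER2+; TNBC =
    ER-/PR-/HER2-; everything else (any hormone-receptor positivity with
    HER2+, or single-receptor-positive HER2-) = luminal B-like.  Missing
    any marker -> missing subtype.
    """
    markers = (er, pr, her2)
    if any(m is None or (isinstance(m, float) and np.isnan(m)) or m == "missing" for m in markers):
        return np.nan
    for m in markers:
        if m not in ("neg", "pos"):
            raise ValueError(f"marker values must be neg/pos, got {m!r}")
    if (er, pr, her2) == ("pos", "pos", "neg"):
        return "luminal A-like"
    if er == "neg" and pr == "neg":
        return "HER2-enriched" if her2 == "pos" else "TNBC"
    return "luminal B-like"


@dataclass
class EffectSpec:
    """Truth for recovery tests: additive effects on the outcome means.

    ``tascd_effects`` / ``tsr_effects`` map variable -> {level: beta}
    (levels absent from a map contribute 0, so the first/reference level is
    the natural baseline).  ``interactions`` lists (var_a, var_b, {(level_a,
    level_b): beta}).  ``missingness`` maps tumor variables to marginal
    missingness rates, realised missing-at-random: the per-record
    probability is modulated by observed site and age group but calibrated
    so the marginal rate is preserved.
    """

    tascd_intercept: float = 28.5
    tascd_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    tascd_residual_sd: float = 7.0
    tsr_intercept: float = 76.0
    tsr_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    tsr_residual_sd: float = 14.0
    interactions: list[tuple[str, str, dict[tuple[str, str], float]]] = field(default_factory=list)
    missingness: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.tascd_residual_sd <= 0 or self.tsr_residual_sd <= 0:
            raise ValueError("residual SDs must be positive")
        for effects in (self.tascd_effects, self.tsr_effects):
            for var, levels in effects.items():
                if var not in CATEGORY_ORDERS:
                    raise ValueError(f"effect on unknown variable {var!r}")
                for lvl in levels:
                    if lvl not in CATEGORY_ORDERS[var]:
                        raise ValueError(f"effect on unknown level {lvl!r} of {var!r}")
        for var, rate in self.missingness.items():
            if var not in TUMOR_VARIABLES:
                raise ValueError(f"missingness only supported on tumor variables, got {var!r}")
            if not (0 <= rate < 1):
                raise ValueError("missingness rates must lie in [0, 1)")
        for var_a, var_b, cells in self.interactions:
            for (la, lb) in cells:
                if la not in CATEGORY_ORDERS[var_a] or lb not in CATEGORY_ORDERS[var_b]:
                    raise ValueError(f"interaction on unknown cell ({la!r}, {lb!r})")


def default_effects() -> EffectSpec:
    """Effects at the scale of the published mutually-adjusted estimates.

    Parous +2.92, positive family history +2.36, body-size gradient
    (moderate -1.02, heavy -2.42), grade gradient (+3.53, +5.22), late
    menarche -1.78 on Ta-SCD %; null effects on TSR; marker/grade/size
    missingness at the published unknown rates.
    """
    return EffectSpec(
        tascd_effects={
            "parity_status": {"parous": 2.92},
            "fhbc": {"yes": 2.36},
            "body_size": {"moderate": -1.02, "heavy": -2.42},
            "grade": {"2": 3.53, "3": 5.22},
            "menarche_cat": {">=17": -1.78},
        },
        missingness={"er": 0.25, "pr": 0.254, "her2": 0.294, "grade": 0.141, "size_cat": 0.048},
    )


def _draw(rng, levels_probs: dict[str, float], n: int) -> np.ndarray:
    levels = list(levels_probs)
    p = np.array([levels_probs[l] for l in levels], dtype=float)
    p /= p.sum()
    return rng.choice(levels, size=n, p=p)


def _effect_column(df: pd.DataFrame, effects: dict[str, dict[str, float]]) -> np.ndarray:
    out = np.zeros(len(df))
    for var, levels in effects.items():
        for lvl, beta in levels.items():
            out += beta * (df[var].to_numpy() == lvl)
    return out


def _mar_mask(rng, df: pd.DataFrame, rate: float) -> np.ndarray:
    """MAR missingness indicator: depends on observed site and age group,
    calibrated so the marginal rate equals ``rate``."""
    if rate == 0:
        return np.zeros(len(df), dtype=bool)
    w = np.exp(
        0.45 * (df["site"].to_numpy() == "C")
        + 0.30 * (df["age_group"].to_numpy() == ">=55")
        - 0.20 * (df["age_group"].to_numpy() == "<35")
    )
    p = np.clip(rate * w / w.mean(), 0, 0.999)
    return rng.uniform(size=len(df)) < p


def generate_cohort(
    n: int,
    effects: EffectSpec | None = None,
    seed: int = 0,
    margins: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate a patient-level cohort table.

    Covariates are drawn from the reference category marginals (parity
    consistency enforced: nulliparous women have zero children and ``n/a``
    age-at-first-birth and breastfeeding).  Outcomes are linear in the
    injected effects with Gaussian residuals, Ta-SCD clipped to (5, 95)
    and TSR to (5, 99.9).  Deterministic per seed.
    """
    if n < 50:
        raise ValueError("need n >= 50 for a meaningful cohort")
    effects = default_effects() if effects is None else effects
    effects.validate()
    rng = np.random.default_rng(seed)
    margins = load_reference_margins() if margins is None else margins

    df = pd.DataFrame({"patient_id": [f"P{i:05d}" for i in range(n)]})
    df["site"] = _draw(rng, {"A": 0.40, "B": 0.35, "C": 0.25}, n)
    df["age_group"] = _draw(rng, reference_marginal("age_group", margins), n)
    lo = np.array([_AGE_RANGES[g][0] for g in df["age_group"]])
    hi = np.array([_AGE_RANGES[g][1] for g in df["age_group"]])
    df["age_years"] = rng.integers(lo, hi + 1)

    df["menarche_cat"] = _draw(rng, reference_marginal("menarche_cat", margins), n)
    df["parity_status"] = _draw(rng, reference_marginal("parity_status", margins), n)
    parous = df["parity_status"].to_numpy() == "parous"
    df["n_children"] = "0"
    df.loc[parous, "n_children"] = _draw(rng, reference_marginal("n_children", margins), int(parous.sum()))
    df["afb_cat"] = "n/a"
    df.loc[parous, "afb_cat"] = _draw(rng, reference_marginal("afb_cat", margins), int(parous.sum()))
    df["breastfeeding_cat"] = "n/a"
    df.loc[parous, "breastfeeding_cat"] = _draw(
        rng, reference_marginal("breastfeeding_cat", margins), int(parous.sum())
    )
    df["body_size"] = _draw(rng, reference_marginal("body_size", margins), n)
    df["fhbc"] = _draw(rng, reference_marginal("fhbc", margins), n)

    combos = list(_MARKER_JOINT)
    idx = rng.choice(len(combos), size=n, p=np.array(list(_MARKER_JOINT.values())))
    df["er"] = [combos[i][0] for i in idx]
    df["pr"] = [combos[i][1] for i in idx]
    df["her2"] = [combos[i][2] for i in idx]
    df["grade"] = _draw(rng, reference_marginal("grade", margins), n)
    df["size_cat"] = _draw(rng, reference_marginal("size_cat", margins), n)

    df["tissue_area_mm2"] = rng.gamma(shape=4.0, scale=7.5, size=n)

    def outcome(intercept, eff, sd, clip):
        y = intercept + _effect_column(df, eff) + rng.normal(0, sd, n)
        for var_a, var_b, cells in effects.interactions:
            for (la, lb), beta in cells.items():
                y += beta * ((df[var_a].to_numpy() == la) & (df[var_b].to_numpy() == lb))
        return np.clip(y, *clip)

    df["tascd_percent"] = outcome(
        effects.tascd_intercept, effects.tascd_effects, effects.tascd_residual_sd, (5.0, 95.0)
    )
    # interactions are specified on Ta-SCD only; TSR stays additive
    df["tsr_percent"] = np.clip(
        effects.tsr_intercept
        + _effect_column(df, effects.tsr_effects)
        + rng.normal(0, effects.tsr_residual_sd, n),
        5.0,
        99.9,
    )

    for var, rate in effects.missingness.items():
        df.loc[_mar_mask(rng, df, rate), var] = np.nan

    df["subtype"] = [derive_subtype(e, p, h) for e, p, h in zip(df["er"], df["pr"], df["her2"])]
    return df
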