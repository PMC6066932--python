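"""Cross-cutting statistical analyses.

Codon-level cost-efficiency trade-off gradients, per-family trade-off
profiles, selection-vs-expression associations and evolutionary-rate
(Ka/Ks) associations with nested-model comparison. All regressions are
ordinary least squares; quoted p-values are the regression F-test p, and
nested models are compared by ANOVA F-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.anova import anova_lm

from .code import GeneticCode
from .costs import CostTable, codon_cost, relative_cost
from .tai import TAITable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def simple_ols(x, y) -> RegressionResult:
    """OLS of y on x with intercept; p is the model F-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        p=float(model.f_pvalue),
        n=int(x.size),
    )


def _tradeoff_points(
    tai: TAITable, table: CostTable, code: GeneticCode, use_relative: bool = True
):
    xs, ys = [], []
    for fam in code.families.values():
        if len(fam) < 2:  # singleton families carry no trade-off information
            continue
        for c in sorted(fam):
            if use_relative:
                xs.append(relative_cost(c, table, code))
                ys.append(tai.rel[c])
            else:
                xs.append(codon_cost(c, table))
                ys.append(tai.w[c])
    return np.array(xs), np.array(ys)


def tradeoff_gradient(
    tai: TAITable,
    table: CostTable,
    code: GeneticCode,
    use_relative: bool = True,
) -> RegressionResult:
    """OLS of per-codon relative efficiency on relative biosynthetic cost
    across sense codons of multi-codon families (the species' codon
    cost-efficiency trade-off)."""
    xs, ys = _tradeoff_points(tai, table, code, use_relative)
    return simple_ols(xs, ys)


def cost_metric_correlation(
    tableA: CostTable, tableB: CostTable, code: GeneticCode
) -> RegressionResult:
    """OLS across the 61 sense codons of codon cost under B on cost under A."""
    xs = [codon_cost(c, tableA) for c in code.sense_codons]
    ys = [codon_cost(c, tableB) for c in code.sense_codons]
    return simple_ols(xs, ys)


def family_profile(
    tai: TAITable, table: CostTable, code: GeneticCode, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-family codon cost/efficiency profile with trade-off classification.

    Families where all costs are equal (or the slope is not significant at
    ``alpha``) are classified "none"; otherwise "positive"/"negative" by the
    sign of the fitted slope. Singleton families (M, W) are excluded.
    """
    rows = []
    for aa, fam in sorted(code.families.items()):
        if len(fam) < 2:
            continue
        codons = sorted(fam)
        costs = np.array([relative_cost(c, table, code) for c in codons])
        effs = np.array([tai.rel[c] for c in codons])
        if np.allclose(costs, costs[0]):
            cls, slope, p = "none", 0.0, float("nan")
        elif len(codons) == 2:
            slope = float((effs[1] - effs[0]) / (costs[1] - costs[0]))
            p = 0.0 if effs[0] != effs[1] else float("nan")
            cls = "none" if effs[0] == effs[1] else ("positive" if slope > 0 else "negative")
        else:
            res = simple_ols(costs, effs)
            slope, p = res.slope, res.p
            if np.isnan(p) or p >= alpha:
                cls = "none"
            else:
                cls = "positive" if slope > 0 else "negative"
        for c, co, ef in zip(codons, costs, effs):
            rows.append(
                dict(aa=aa, codon=c, rel_cost=co, rel_eff=ef, slope=slope,
                     p=p, classification=cls)
            )
    return pd.DataFrame(rows)


def selection_expression_association(
    gene_fits: pd.DataFrame, abundance: pd.DataFrame
) -> dict:
    """Associate per-gene S_c and S_t with relative mRNA abundance.

    ``gene_fits`` needs columns (gene, Sc, St); ``abundance`` (gene, value).
    Both the linear-abundance and log-abundance fits are reported because
    expression spans orders of magnitude.
    """
    fits = gene_fits.dropna(subset=["Sc", "St"])
    merged = fits.merge(abundance, on="gene", how="inner")
    dropped = len(fits) - len(merged)
    if dropped:
        logger.info("%d gene(s) without abundance were dropped", dropped)
    if len(merged) < 10:
        raise ValueError(
            f"only {len(merged)} genes shared between fits and abundance (need >= 10)"
        )
    out = {"n": len(merged), "dropped": dropped}
    for coef in ("Sc", "St"):
        out[coef] = {
            "linear": simple_ols(merged["value"], merged[coef]),
            "log": simple_ols(np.log(merged["value"]), merged[coef]),
        }
    return out


def rate_association(
    rates: pd.DataFrame,
    min_genes: int = 1000,
    ks_saturation: float = 1.0,
) -> dict:
    """Evolutionary-rate association with cost-efficiency optimality.

    ``rates`` columns: gene, Ka, Ks, optimality, optionally cost_opt and
    eff_opt covariates and a ``pair`` column grouping ortholog sets by
    species pair. Species pairs with mean Ks > ``ks_saturation`` (rate
    saturation) or fewer than ``min_genes`` genes are excluded; the filters
    commute. Remaining genes are pooled for OLS of Ks and Ka on joint
    optimality, and — when separate cost/efficiency optimality covariates
    are present — the joint two-covariate model is compared to each
    single-covariate model by ANOVA F-test.
    """
    df = rates.copy()
    if "pair" not in df.columns:
        df["pair"] = "pair_0"
    kept, excluded = [], []
    for pair, sub in df.groupby("pair"):
        if sub["Ks"].mean() > ks_saturation:
            excluded.append((pair, "ks_saturation"))
        elif len(sub) < min_genes:
            excluded.append((pair, "too_few_genes"))
        else:
            kept.append(sub)
    if not kept:
        return {"n_pairs": 0, "excluded": excluded, "message": "no pairs pass filters"}
    pooled = pd.concat(kept, ignore_index=True)
    out = {
        "n_pairs": len(kept),
        "excluded": excluded,
        "Ks": simple_ols(pooled["optimality"], pooled["Ks"]),
        "Ka": simple_ols(pooled["optimality"], pooled["Ka"]),
    }
    if {"cost_opt", "eff_opt"} <= set(pooled.columns):
        out["nested"] = {}
        X_joint = sm.add_constant(pooled[["cost_opt", "eff_opt"]])
        for rate in ("Ks", "Ka"):
            y = pooled[rate]
            joint = sm.OLS(y, X_joint).fit()
            report = {"joint_r2": float(joint.rsquared)}
            for single in ("cost_opt", "eff_opt"):
                reduced = sm.OLS(y, sm.add_constant(pooled[[single]])).fit()
                table = anova_lm(reduced, joint)
                report[f"vs_{single}_only"] = {
                    "F": float(table["F"].iloc[1]),
                    "p": float(table["Pr(>F)"].iloc[1]),
                    "single_r2": float(reduced.rsquared),
                }
            out["nested"][rate] = report
    return out
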