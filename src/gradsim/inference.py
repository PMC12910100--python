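"""Statistical analysis of the simulation output.

Four linear mixed-effect models probe how replication drives prediction
accuracy (fixed effects left of the bar, random intercepts right of it;
response shape is always an additional random intercept):

1. accuracy ~ replicates                | total, extremes, knowledge
2. accuracy ~ replicates * extremes     | total, knowledge
3. accuracy ~ replicates * knowledge    | total, extremes
4. accuracy ~ replicates * total        | knowledge, extremes

Models are fit by REML; crossed random intercepts are encoded through a
single grouping with variance components.  Explained variance is summarized
by marginal / conditional R-squared (variance of the fixed-effect
predictor over the total of fixed, random-intercept and residual
variances), the relative contribution of interacting predictors by
variation partitioning on marginal R-squared of nested models, and the
per-case direction of the replication effect by the sign and Wald
significance of the replicate slope in per-case sub-models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .metrics import METRIC_NAMES

__all__ = [
    "MODEL_SPECS",
    "FitSummary",
    "VariationPartition",
    "EffectClassification",
    "fit_lmm",
    "r2_nakagawa",
    "variation_partition",
    "replication_knowledge_partition",
    "classify_replication_effects",
    "compare_models",
    "model_sensitivity_table",
]

logger = logging.getLogger("gradsim")

#: interaction partner of the replicate count and random-intercept factors
#: per model id (partner None = replication-only model)
MODEL_SPECS: Dict[int, Tuple[Optional[str], Tuple[str, ...]]] = {
    1: (None, ("n_total", "extremes", "knowledge")),
    2: ("extremes", ("n_total", "knowledge")),
    3: ("knowledge", ("n_total", "extremes")),
    4: ("n_total", ("knowledge", "extremes")),
}


@dataclass
class FitSummary:
    """Fixed effects, variance components and explained variance of one fit."""

    metric: str
    formula: str
    params: pd.Series
    pvalues: pd.Series
    vcomp: Dict[str, float]
    scale: float
    var_fixed: float
    marginal_r2: float
    conditional_r2: float
    n: int
    converged: bool = True
    singular: bool = False


@dataclass
class VariationPartition:
    """Unique and shared marginal-R2 fractions of two predictors."""

    unique_a: float
    unique_b: float
    shared: float
    total: float  # marginal R2 of the joint model
    r2_a: float
    r2_b: float
    joint_fit: Optional["FitSummary"] = None

    @property
    def identity_residual(self) -> float:
        return self.unique_a + self.unique_b + self.shared - self.total


@dataclass
class EffectClassification:
    """Per-case slope sign/significance of replication plus aggregate shares."""

    table: pd.DataFrame  # one row per case: factors, slope, pvalue, category
    alpha: float
    excluded: int = 0

    def percentages(self) -> Dict[str, float]:
        n = len(self.table)
        if n == 0:
            return {"negative": float("nan"), "positive": float("nan"), "nonsignificant": float("nan")}
        counts = self.table["category"].value_counts()
        return {
            c: 100.0 * counts.get(c, 0) / n
            for c in ("negative", "positive", "nonsignificant")
        }


def _clean(results: pd.DataFrame, metric: str) -> pd.DataFrame:
    if metric not in METRIC_NAMES:
        raise ValueError(f"metric must be one of {METRIC_NAMES}, got {metric!r}")
    df = results
    if "failed" in df.columns:
        df = df[~df["failed"].astype(bool)]
    return df.dropna(subset=[metric])


def _fit_mixed(formula: str, data: pd.DataFrame, random_factors: Sequence[str], huber: bool = False):
    """REML mixed fit with crossed random intercepts; OLS fallback if none vary.

    Returns ``(result, kind, singular)`` where kind is "mixedlm" or "ols".
    ``huber=True`` enables one round of Huber down-weighting of residuals
    (an optional robustness variant, not used by the standard analysis).
    """
    import statsmodels.formula.api as smf

    vcf = {f: f"0 + C({f})" for f in random_factors if data[f].nunique() > 1}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if not vcf:
            res = smf.ols(formula, data=data).fit()
            return res, "ols", False
        model = MixedLM.from_formula(
            formula, data, groups=np.ones(len(data)), vc_formula=vcf, re_formula="0"
        )
        res = model.fit(reml=True, method="lbfgs", maxiter=500)
        if huber:
            resid = np.asarray(res.resid)
            s = np.median(np.abs(resid)) / 0.6745 or 1.0
            w = np.clip(1.345 * s / np.maximum(np.abs(resid), 1e-12), None, 1.0)
            res = MixedLM.from_formula(
                formula,
                data.assign(_w=np.sqrt(w)),
                groups=np.ones(len(data)),
                vc_formula=vcf,
                re_formula="0",
            ).fit(reml=True, method="lbfgs", maxiter=500)
        singular = bool(np.any(np.asarray(res.vcomp) < 1e-10))
    return res, "mixedlm", singular


def _summarize(res, kind: str, metric: str, formula: str, singular: bool) -> FitSummary:
    if kind == "ols":
        var_f = float(np.var(res.fittedvalues, ddof=0))
        scale = float(res.mse_resid)
        vcomp: Dict[str, float] = {}
    else:
        fe = res.fe_params
        var_f = float(np.var(res.model.exog @ np.asarray(fe), ddof=0))
        scale = float(res.scale)
        names = list(res.model.exog_vc.names) if res.model.exog_vc is not None else []
        vcomp = {n: max(float(v), 0.0) for n, v in zip(names, np.asarray(res.vcomp))}
    var_r = sum(vcomp.values())
    denom = var_f + var_r + scale
    if denom > 0:
        marg = var_f / denom
        cond = (var_f + var_r) / denom
    else:
        # a response with no variance at all has nothing to explain
        marg = cond = 0.0
    return FitSummary(
        metric=metric,
        formula=formula,
        params=pd.Series(res.params),
        pvalues=pd.Series(res.pvalues),
        vcomp=vcomp,
        scale=scale,
        var_fixed=var_f,
        marginal_r2=marg,
        conditional_r2=cond,
        n=int(res.nobs),
        converged=bool(getattr(res, "converged", True)),
        singular=singular,
    )


def fit_lmm(
    results: pd.DataFrame,
    model_id: int,
    metric: str,
    include_shape_random: bool = True,
    huber: bool = False,
) -> FitSummary:
    """Fit one of the four accuracy models to a results table.

    The replicate count enters as a numeric fixed effect.  Random factors
    with a single level in the data (e.g. shape inside a per-shape sub-fit)
    drop out automatically.
    """
    if model_id not in MODEL_SPECS:
        raise ValueError(f"model_id must be in {sorted(MODEL_SPECS)}")
    partner, randoms = MODEL_SPECS[model_id]
    if include_shape_random:
        randoms = randoms + ("shape",)
    df = _clean(results, metric)
    fixed = "n_replicates"
    # an interaction partner that does not vary in the data would make the
    # fixed design singular; it then contributes nothing and is dropped
    if partner is not None and df[partner].nunique() > 1:
        fixed = f"n_replicates * {_term(partner, df)}"
    formula = f"{metric} ~ {fixed}"
    res, kind, singular = _fit_mixed(formula, df, randoms, huber=huber)
    return _summarize(res, kind, metric, formula, singular)


def r2_nakagawa(fit: FitSummary) -> Tuple[float, float]:
    """Marginal and conditional R-squared of a fitted mixed model.

    marginal = var(fixed) / (var(fixed) + sum(random intercept variances)
    + residual variance); conditional adds the random-intercept variances
    to the numerator.
    """
    return fit.marginal_r2, fit.conditional_r2


def _term(name: str, data: pd.DataFrame) -> str:
    return name if pd.api.types.is_numeric_dtype(data[name]) else f"C({name})"


def variation_partition(
    results: pd.DataFrame,
    metric: str,
    predictor_a: str = "n_replicates",
    predictor_b: str = "knowledge",
    random_factors: Sequence[str] = ("n_total", "extremes", "shape"),
    interaction: bool = True,
) -> VariationPartition:
    """Legendre-style partition of marginal R2 between two predictors.

    Fits the joint model (with interaction by default, mirroring the
    interacting fixed effects of the accuracy models) and the two
    single-predictor models, all with the same random-intercept structure:
    unique_A = R2(joint) - R2(B), unique_B = R2(joint) - R2(A),
    shared = R2(A) + R2(B) - R2(joint).  Negative shared fractions
    (suppression) are reported as-is.
    """
    df = _clean(results, metric)
    ta, tb = _term(predictor_a, df), _term(predictor_b, df)
    op = "*" if interaction else "+"
    joint_formula = f"{metric} ~ {ta} {op} {tb}"
    randoms = tuple(f for f in random_factors if f in df.columns)
    r2 = {}
    joint_fit = None
    for label, formula in (
        ("joint", joint_formula),
        ("a", f"{metric} ~ {ta}"),
        ("b", f"{metric} ~ {tb}"),
    ):
        res, kind, singular = _fit_mixed(formula, df, randoms)
        summary = _summarize(res, kind, metric, formula, singular)
        if label == "joint":
            joint_fit = summary
        r2[label] = summary.marginal_r2
    unique_a = r2["joint"] - r2["b"]
    unique_b = r2["joint"] - r2["a"]
    shared = r2["a"] + r2["b"] - r2["joint"]
    if shared < 0:
        logger.debug("negative shared fraction (%.4g): suppression", shared)
    return VariationPartition(
        unique_a=unique_a,
        unique_b=unique_b,
        shared=shared,
        total=r2["joint"],
        r2_a=r2["a"],
        r2_b=r2["b"],
        joint_fit=joint_fit,
    )


def replication_knowledge_partition(
    results: pd.DataFrame,
    metric: str,
    noise_level: Optional[float] = None,
    by: Sequence[str] = ("shape", "strategy"),
    aggregate: bool = True,
) -> pd.DataFrame:
    """Per shape-by-strategy Model-3 sub-fits with the replicates/knowledge
    variation partition.

    With ``aggregate=True`` (default) the models are fit to the
    Monte-Carlo mean accuracy per cell, so the explained-variance shares
    describe the systematic design-level variation rather than
    repetition scatter.  Returns one row per sub-case with the joint
    (Model 3) marginal and conditional R2 and the unique/shared
    fractions, all on the 0-1 scale.
    """
    from .experiment import aggregate_cells

    df = _clean(results, metric)
    if noise_level is not None:
        df = df[np.isclose(df["noise"], noise_level)]
    if aggregate:
        df = aggregate_cells(df)
    rows = []
    for key, sub in df.groupby(list(by), sort=True, observed=True):
        part = variation_partition(
            sub, metric, "n_replicates", "knowledge", random_factors=("n_total", "extremes")
        )
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update(
            marginal_r2=part.joint_fit.marginal_r2,
            conditional_r2=part.joint_fit.conditional_r2,
            unique_replicates=part.unique_a,
            unique_knowledge=part.unique_b,
            shared=part.shared,
            joint_r2=part.total,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def classify_replication_effects(
    results: pd.DataFrame,
    metric: str,
    noise_level: Optional[float] = None,
    alpha: float = 0.05,
    case_factors: Sequence[str] = ("shape", "strategy", "knowledge", "extremes"),
) -> EffectClassification:
    """Per-case sign and significance of the replication effect.

    For every case (default: shape x strategy x knowledge x extremes) the
    accuracy metric is regressed on the numeric replicate count with a
    random intercept for total sample size; the slope is classified as
    negative/positive when its Wald p-value is below ``alpha``, otherwise
    nonsignificant.  Cases with fewer than two replicate levels are
    excluded and counted.
    """
    df = _clean(results, metric)
    if noise_level is not None:
        df = df[np.isclose(df["noise"], noise_level)]
    df = df.sort_values(list(case_factors) + ["n_total", "n_replicates", "rep"], kind="mergesort")
    rows = []
    excluded = 0
    for key, sub in df.groupby(list(case_factors), sort=True, observed=True):
        if sub["n_replicates"].nunique() < 2:
            excluded += 1
            continue
        y = sub[metric].to_numpy(float)
        x = np.column_stack([np.ones(len(sub)), sub["n_replicates"].to_numpy(float)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if sub["n_total"].nunique() > 1:
                res = MixedLM(y, x, groups=sub["n_total"].to_numpy()).fit(
                    reml=True, method="lbfgs", maxiter=500
                )
            else:
                import statsmodels.api as sm

                res = sm.OLS(y, x).fit()
        slope = float(res.params[1])
        pval = float(res.pvalues[1])
        # a metric that is (numerically) constant within a case - e.g.
        # multiple R2 for the known linear shape, which is identically 1 by
        # affine invariance - has no replication effect, whatever a
        # zero-variance regression reports
        if np.var(y) <= 1e-16 or np.isnan(pval) or pval >= alpha:
            cat = "nonsignificant"
        else:
            cat = "negative" if slope < 0 else "positive"
        row = dict(zip(case_factors, key if isinstance(key, tuple) else (key,)))
        row.update(slope=slope, pvalue=pval, category=cat)
        rows.append(row)
    table = pd.DataFrame(rows)
    return EffectClassification(table=table, alpha=alpha, excluded=excluded)


@dataclass
class ModelComparison:
    """ANOVA + Tukey HSD compact letter display across groups."""

    letters: Dict[str, str]
    anova_p: float
    means: Dict[str, float]
    tukey: Optional[pd.DataFrame] = None


def compare_models(
    groups: Mapping[str, Iterable[float]], alpha: float = 0.05
) -> ModelComparison:
    """One-way ANOVA with post hoc Tukey HSD, summarized as letters.

    Groups sharing a letter are not significantly different at ``alpha``.
    Letters are assigned to maximal cliques of the nonsignificance graph,
    ordered by descending group mean, so the output does not depend on the
    input ordering of the groups.
    """
    names = sorted(groups, key=lambda g: (-float(np.mean(list(groups[g]))), str(g)))
    arrays = {g: np.asarray(list(groups[g]), float) for g in names}
    if len(names) < 2:
        raise ValueError("compare_models needs at least two groups")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anova_p = float(stats.f_oneway(*[arrays[g] for g in names]).pvalue)
        values = np.concatenate([arrays[g] for g in names])
        labels = np.concatenate([[str(g)] * arrays[g].size for g in names])
        try:
            tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
            tukey_df = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
            sig = {}
            for (g1, g2), rej in zip(
                [(r[0], r[1]) for r in tk.summary().data[1:]], tk.reject
            ):
                sig[frozenset((str(g1), str(g2)))] = bool(rej)
        except Exception:  # zero-variance degenerate groups: nothing distinguishable
            tukey_df = None
            sig = {}

    graph = nx.Graph()
    graph.add_nodes_from(str(g) for g in names)
    for i, g1 in enumerate(names):
        for g2 in names[i + 1 :]:
            if not sig.get(frozenset((str(g1), str(g2))), False):
                graph.add_edge(str(g1), str(g2))
    cliques = list(nx.find_cliques(graph))
    order = {str(g): i for i, g in enumerate(names)}
    cliques.sort(key=lambda c: min(order[m] for m in c))
    letters: Dict[str, List[str]] = {str(g): [] for g in names}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for member in clique:
            letters[member].append(letter)
    return ModelComparison(
        letters={g: "".join(sorted(ls)) for g, ls in letters.items()},
        anova_p=anova_p,
        means={str(g): float(arrays[g].mean()) for g in names},
        tukey=tukey_df,
    )


def model_sensitivity_table(
    results: pd.DataFrame,
    metrics: Sequence[str] = METRIC_NAMES,
    model_ids: Sequence[int] = (1, 2, 3, 4),
    noise_levels: Optional[Sequence[float]] = None,
    by: Sequence[str] = ("shape", "strategy"),
    aggregate: bool = True,
) -> pd.DataFrame:
    """Marginal/conditional R2 of each accuracy model per sub-case.

    Fits on per-cell mean accuracies by default (see
    ``replication_knowledge_partition``).  One row per (noise, metric,
    model, sub-case); aggregating the marginal column over sub-cases
    reproduces the mean-plus-SD sensitivity summary.
    """
    from .experiment import aggregate_cells

    if noise_levels is None:
        noise_levels = sorted(results["noise"].unique())
    if aggregate:
        results = aggregate_cells(results[~results["failed"].astype(bool)])
    rows = []
    for noise in noise_levels:
        df = results[np.isclose(results["noise"], noise)]
        for metric in metrics:
            clean = _clean(df, metric)
            for key, sub in clean.groupby(list(by), sort=True, observed=True):
                for mid in model_ids:
                    fit = fit_lmm(sub, mid, metric, include_shape_random=False)
                    row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
                    row.update(
                        noise=noise,
                        metric=metric,
                        model_id=mid,
                        marginal_r2=fit.marginal_r2,
                        conditional_r2=fit.conditional_r2,
                        singular=fit.singular,
                    )
                    rows.append(row)
    return pd.DataFrame(rows)
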