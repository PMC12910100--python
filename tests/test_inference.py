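"""Mixed-model analysis: recovery, R2 decomposition, partitioning, classification."""

import numpy as np
import pandas as pd
import pytest

from gradsim.inference import (
    classify_replication_effects,
    compare_models,
    fit_lmm,
    r2_nakagawa,
    variation_partition,
)


def _synthetic_table(
    rng,
    beta=-0.005,
    group_sd=0.1,
    resid_sd=0.05,
    n_rep_levels=(1, 2, 4, 8, 16),
    totals=(6, 12, 24, 48, 96),
    reps=40,
    knowledge_effect=0.0,
):
    """Balanced accuracy table with a known replicate slope and group offsets."""
    rows = []
    offsets = {t: rng.normal(0.0, group_sd) for t in totals}
    for total in totals:
        for r in n_rep_levels:
            for know in ("known", "unknown"):
                for ext in ("with", "without"):
                    mu = 0.5 + beta * r + offsets[total]
                    if know == "unknown":
                        mu += knowledge_effect
                    y = mu + rng.normal(0.0, resid_sd, size=reps)
                    for i, val in enumerate(y):
                        rows.append(
                            dict(
                                shape="linear",
                                strategy="systematic",
                                n_total=total,
                                n_locations=max(total // r, 3),
                                n_replicates=r,
                                noise=0.2,
                                knowledge=know,
                                extremes=ext,
                                rep=i,
                                r2_multiple=val,
                                chalcraft_ps=val,
                                neg_rmse=val,
                                failed=False,
                            )
                        )
    return pd.DataFrame(rows)


def test_lmm_recovers_known_replicate_slope(rng):
    beta = -0.005
    df = _synthetic_table(rng, beta=beta)
    fit = fit_lmm(df, model_id=1, metric="r2_multiple")
    est = fit.params["n_replicates"]
    # recover the Wald standard error from the reported z-based p-value
    from scipy import stats

    z = np.abs(stats.norm.ppf(fit.pvalues["n_replicates"] / 2))
    se = abs(est) / z if z > 0 else np.inf
    assert abs(est - beta) < 3 * se


def test_constant_response_has_zero_slope_and_zero_marginal_r2(rng):
    df = _synthetic_table(rng, beta=0.0, group_sd=0.0, resid_sd=0.0)
    df["r2_multiple"] = 0.5
    fit = fit_lmm(df, model_id=1, metric="r2_multiple")
    assert fit.params["n_replicates"] == pytest.approx(0.0, abs=1e-8)
    assert fit.marginal_r2 == pytest.approx(0.0, abs=1e-8)


def test_zero_random_variance_collapses_conditional_to_marginal(rng):
    df = _synthetic_table(rng, beta=-0.01, group_sd=0.0, resid_sd=0.05)
    fit = fit_lmm(df, model_id=1, metric="r2_multiple")
    marg, cond = r2_nakagawa(fit)
    assert cond - marg < 0.01
    assert marg <= cond + 1e-12


def test_marginal_r2_matches_ols_without_random_effects(rng):
    """With all random factors constant the fit degenerates to OLS."""
    n = 2000
    x = rng.uniform(1, 32, size=n)
    y = 0.8 - 0.01 * x + rng.normal(0, 0.05, size=n)
    df = pd.DataFrame(
        dict(
            shape="linear",
            strategy="systematic",
            n_total=48,
            n_locations=12,
            n_replicates=x,
            noise=0.2,
            knowledge="unknown",
            extremes="with",
            rep=np.arange(n),
            r2_multiple=y,
            chalcraft_ps=y,
            neg_rmse=y,
            failed=False,
        )
    )
    fit = fit_lmm(df, model_id=1, metric="r2_multiple")
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ols_r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
    assert fit.marginal_r2 == pytest.approx(ols_r2, abs=0.01)


def test_pure_noise_response_has_negligible_marginal_r2(rng):
    df = _synthetic_table(rng, beta=0.0, group_sd=0.0, resid_sd=1.0)
    fit = fit_lmm(df, model_id=1, metric="r2_multiple")
    assert fit.marginal_r2 < 0.01


def test_variation_partition_algebraic_identity(rng):
    df = _synthetic_table(rng, beta=-0.01, knowledge_effect=-0.1)
    part = variation_partition(df, "r2_multiple")
    assert abs(part.identity_residual) < 1e-10


def test_orthogonal_predictors_share_almost_nothing(rng):
    """Balanced independent factors: the shared fraction vanishes."""
    n = 10_000
    reps_x = rng.choice([1, 2, 4, 8, 16], size=n)
    know = rng.choice(["known", "unknown"], size=n)
    y = 0.5 - 0.02 * reps_x - 0.1 * (know == "unknown") + rng.normal(0, 0.1, size=n)
    df = pd.DataFrame(
        dict(
            shape="linear",
            strategy="systematic",
            n_total=48,
            n_locations=12,
            n_replicates=reps_x,
            noise=0.2,
            knowledge=know,
            extremes="with",
            rep=np.arange(n),
            r2_multiple=y,
            chalcraft_ps=y,
            neg_rmse=y,
            failed=False,
        )
    )
    part = variation_partition(df, "r2_multiple")
    assert abs(part.shared) < 0.02
    assert part.unique_a > 0.05 and part.unique_b > 0.05


def test_noise_predictor_contributes_no_unique_variation(rng):
    df = _synthetic_table(rng, beta=-0.02, knowledge_effect=0.0, resid_sd=0.05)
    part = variation_partition(df, "r2_multiple")  # knowledge has no effect here
    assert part.unique_b == pytest.approx(0.0, abs=0.01)
    assert part.unique_a > 0.1


def test_classification_detects_constructed_negative_effects(rng):
    df = _synthetic_table(rng, beta=-0.05, group_sd=0.02, resid_sd=0.02)
    cls = classify_replication_effects(df, "r2_multiple")
    assert len(cls.table) == 4  # knowledge x extremes for one shape x strategy
    assert (cls.table["category"] == "negative").all()
    pct = cls.percentages()
    assert pct["negative"] == 100.0
    assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)


def test_null_cases_flag_at_about_the_alpha_rate():
    """Flat replicate effects should be called significant at ~ alpha."""
    rng = np.random.default_rng(77)
    frames = []
    for case in range(200):
        sub = _synthetic_table(
            rng, beta=0.0, group_sd=0.0, resid_sd=1.0, reps=5, totals=(6, 24, 96)
        )
        sub["shape"] = f"case{case}"  # distinct case key
        frames.append(sub)
    df = pd.concat(frames, ignore_index=True)
    cls = classify_replication_effects(
        df, "r2_multiple", case_factors=("shape", "knowledge", "extremes")
    )
    sig_rate = 1.0 - cls.percentages()["nonsignificant"] / 100.0
    assert 0.005 < sig_rate < 0.12  # binomial band around alpha = 0.05


def test_classification_invariant_to_row_order(rng):
    df = _synthetic_table(rng, beta=-0.01)
    shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = classify_replication_effects(df, "r2_multiple").table
    b = classify_replication_effects(shuffled, "r2_multiple").table
    pd.testing.assert_frame_equal(a, b)


def test_cases_with_single_replicate_level_are_excluded(rng):
    df = _synthetic_table(rng, n_rep_levels=(1,))
    cls = classify_replication_effects(df, "r2_multiple")
    assert len(cls.table) == 0
    assert cls.excluded == 4


def test_compare_models_identical_groups_share_a_letter(rng):
    vals = rng.normal(0.5, 0.1, size=30)
    cmp_res = compare_models({"m1": vals, "m2": vals.copy(), "m3": vals.copy()})
    assert len(set(cmp_res.letters.values())) == 1


def test_compare_models_separated_groups_get_distinct_letters(rng):
    a = rng.normal(0.0, 0.01, size=30)
    b = rng.normal(1.0, 0.01, size=30)
    cmp_res = compare_models({"lo": a, "hi": b})
    assert cmp_res.letters["lo"] != cmp_res.letters["hi"]
    assert cmp_res.anova_p < 1e-6


def test_compare_models_letters_invariant_to_input_order(rng):
    groups = {
        "a": rng.normal(0.0, 0.05, 40),
        "b": rng.normal(0.5, 0.05, 40),
        "c": rng.normal(0.52, 0.05, 40),
    }
    fwd = compare_models(dict(groups))
    rev = compare_models(dict(reversed(list(groups.items()))))
    assert fwd.letters == rev.letters
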