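"""Model-fitting correctness: nesting limit, oracle cross-checks, crude ORs."""

import shutil
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from landepi.association_models import (
    ModelSpec,
    _fit_aghq,
    _irls_logistic,
    crude_or,
    fit_mixed_logistic,
    or_table,
)


def _synthetic_table(n, seed, p_case=None, regions=("A", "B", "C")):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "status": np.where(
                rng.random(n) < (0.15 if p_case is None else p_case), "case", "control"
            ),
            "gci": rng.uniform(0, 100, n),
            "env": rng.choice(["rural", "industrial", "intersection", "urban", "ring"], n),
            "ses_q": rng.choice(["Q1", "Q2", "Q3", "Q4"], n),
            "sex": rng.choice(["M", "F"], n),
            "birth_year": rng.integers(1996, 2012, n),
            "region": rng.choice(list(regions), n),
        }
    )
    return df


def test_single_region_fixed_sigma_matches_plain_logistic():
    """With sigma pinned at 0 the mixed likelihood is the ordinary one."""
    df = _synthetic_table(1_500, seed=1, regions=("A",))
    fit = fit_mixed_logistic(df, ModelSpec(), fix_sigma=0.0)
    X = pd.DataFrame(
        {
            "const": 1.0,
            "gci10": df["gci"] / 10,
            **{
                f"env_{lv}": (df["env"] == lv).astype(float)
                for lv in ("industrial", "intersection", "urban", "ring")
            },
            **{f"ses_q_{q}": (df["ses_q"] == q).astype(float) for q in ("Q2", "Q3", "Q4")},
            "sex_male": (df["sex"] == "M").astype(float),
            "birth_year_c": df["birth_year"] - df["birth_year"].mean(),
        }
    )
    y = (df["status"] == "case").astype(float)
    sm_fit = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-12)
    mine = np.array([t.estimate for t in fit.terms.values()])
    np.testing.assert_allclose(mine, sm_fit.params.to_numpy(), atol=1e-6)


def test_null_exposure_ci_covers_one():
    """Case status independent of every covariate: GCI CI covers 1."""
    df = _synthetic_table(3_000, seed=2)
    fit = fit_mixed_logistic(df, ModelSpec())
    t = fit.terms["gci10"]
    assert t.ci_low <= 1.0 <= t.ci_high


def test_aghq_matches_lme4_glmer():
    """Independent oracle: lme4's adaptive-quadrature GLMM on shared data."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript is required for the lme4 cross-check")
    rng = np.random.default_rng(42)
    G, n = 8, 1_200
    g = rng.integers(0, G, n)
    u = rng.normal(0, 0.8, G)
    x1 = rng.normal(size=n)
    x2 = rng.binomial(1, 0.4, n)
    eta = -0.5 + 0.6 * x1 - 0.4 * x2 + u[g]
    y = (rng.random(n) < expit(eta)).astype(float)
    X = np.column_stack([np.ones(n), x1, x2])
    beta0, _, _, _ = _irls_logistic(y, X)
    beta, sigma, _, _, ok = _fit_aghq(y, X, g, 15, beta0)
    assert ok
    with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
        pd.DataFrame({"y": y.astype(int), "x1": x1, "x2": x2, "g": g}).to_csv(
            fh.name, index=False
        )
        path = fh.name
    rcode = (
        f'd <- read.csv("{path}"); suppressMessages(library(lme4)); '
        "m <- glmer(y ~ x1 + x2 + (1|g), data=d, family=binomial, nAGQ=15); "
        'cat(fixef(m), sqrt(unlist(VarCorr(m))), sep="\\n")'
    )
    out = subprocess.run(
        ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    ref = np.array([float(v) for v in out.stdout.split()])
    np.testing.assert_allclose(np.append(beta, sigma), ref, atol=5e-4)


def test_random_intercept_recovered_on_clustered_data():
    """A real region effect yields a non-boundary variance estimate."""
    rng = np.random.default_rng(7)
    n, G = 4_000, 6
    g = rng.integers(0, G, n)
    u = rng.normal(0, 0.7, G)
    df = _synthetic_table(n, seed=7, regions=[f"R{i}" for i in range(G)])
    df["region"] = [f"R{i}" for i in g]
    eta = -1.5 + u[g]
    df["status"] = np.where(rng.random(n) < expit(eta), "case", "control")
    fit = fit_mixed_logistic(df, ModelSpec())
    assert fit.method == "aghq"
    assert 0.2 < fit.sigma_region < 1.6


def test_boundary_variance_falls_back_to_fixed_regions():
    df = _synthetic_table(2_000, seed=3)  # no region effect in truth
    fit = fit_mixed_logistic(df, ModelSpec())
    assert fit.method in ("region_fixed", "aghq")
    if fit.method == "region_fixed":
        assert fit.sigma_region == 0.0
        assert any(k.startswith("region_") for k in fit.terms)


def test_reference_levels_omitted():
    df = _synthetic_table(2_000, seed=4)
    fit = fit_mixed_logistic(df, ModelSpec())
    assert "env_rural" not in fit.terms
    assert "ses_q_Q1" not in fit.terms


def test_missing_covariates_dropped_and_counted():
    df = _synthetic_table(1_000, seed=5)
    df.loc[df.index[:37], "gci"] = np.nan
    fit = fit_mixed_logistic(df, ModelSpec())
    assert fit.n_dropped == 37
    assert fit.n_cases + fit.n_controls == 963


def test_adjusted_matches_crude_without_confounding():
    """Independent covariates: the adjusted env OR tracks the crude OR."""
    rng = np.random.default_rng(11)
    n = 6_000
    df = _synthetic_table(n, seed=11)
    df["env"] = rng.choice(["rural", "industrial"], n)
    eta = -1.6 + np.log(2.0) * (df["env"] == "industrial")
    df["status"] = np.where(rng.random(n) < expit(eta), "case", "control")
    fit = fit_mixed_logistic(df, ModelSpec())
    is_case = df["status"] == "case"
    exposed = df["env"] == "industrial"
    crude, _ = crude_or(
        (is_case & exposed).sum(),
        (is_case & ~exposed).sum(),
        (~is_case & exposed).sum(),
        (~is_case & ~exposed).sum(),
    )
    assert np.log(fit.terms["env_industrial"].or_) == pytest.approx(
        np.log(crude), abs=0.12
    )


def test_crude_or_symmetry():
    or_, (lo, hi) = crude_or(10, 10, 10, 10)
    assert or_ == 1.0
    assert lo < 1.0 < hi


def test_crude_or_on_published_count_margins():
    """Cross-products of the published 2x2 margins."""
    from landepi.published import TOTAL_CNS_COUNTS

    a, b, c, d = TOTAL_CNS_COUNTS["ses_q4_vs_q1"]
    or_, _ = crude_or(a, b, c, d)
    assert or_ == pytest.approx(229 / 152, rel=1e-12)
    assert round(or_, 4) == 1.5066
    a, b, c, d = TOTAL_CNS_COUNTS["industrial_vs_rural"]
    or_, _ = crude_or(a, b, c, d)
    assert round(or_, 4) == 0.7839


def test_crude_or_zero_cell_handling():
    with pytest.raises(ValueError):
        crude_or(0, 5, 5, 5)
    or_, (lo, hi) = crude_or(0, 5, 5, 5, haldane=True)
    assert 0 < lo < or_ < hi


@given(
    a=st.integers(1, 500), b=st.integers(1, 500),
    c=st.integers(1, 500), d=st.integers(1, 500),
)
@settings(max_examples=100, derandomize=True)
def test_crude_or_exposure_swap_inverts(a, b, c, d):
    or1, _ = crude_or(a, b, c, d)
    or2, _ = crude_or(b, a, d, c)
    assert or1 * or2 == pytest.approx(1.0, rel=1e-9)


def test_or_table_layout_and_percentages():
    df = _synthetic_table(2_500, seed=6)
    fit = fit_mixed_logistic(df, ModelSpec())
    tbl = or_table({"total": fit})
    env_rows = tbl[tbl["term"].str.startswith("env_")]
    assert env_rows["pct_controls"].sum() == pytest.approx(100.0, abs=1e-6)
    assert env_rows["pct_cases"].sum() == pytest.approx(100.0, abs=1e-6)
    # reference row carries OR 1 with no interval
    rural = tbl[tbl["term"] == "env_rural"].iloc[0]
    assert rural["or"] == 1.0 and np.isnan(rural["ci_low"])
    # null-generated data: every estimated OR near 1
    est = tbl[tbl["term"].isin(["gci10", "sex_male"])]["or"]
    assert ((est > 0.6) & (est < 1.6)).all()


def test_gci_positive_count_zero_on_cropless_data():
    df = _synthetic_table(800, seed=8)
    df["gci"] = 0.0
    fit = fit_mixed_logistic(df, ModelSpec())
    assert fit.gci_positive == (0, 0)
    tbl = or_table({"t": fit})
    row = tbl[tbl["term"] == "gci10"].iloc[0]
    assert row["n_cases"] == 0 and row["n_controls"] == 0
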