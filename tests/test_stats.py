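import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from twigwood import (
    correlate_pair,
    correlation_matrix,
    normality_screen,
    shapiro_normal,
    study_cohort_table,
    summarize_traits,
)
from twigwood.stats import significance_band
from twigwood.traits import species_means


# --- normality gate -------------------------------------------------------


def test_shapiro_accepts_normal_samples_at_nominal_rate():
    hits = 0
    for seed in range(200):
        x = np.random.default_rng(seed).standard_normal(69)
        hits += shapiro_normal(x).is_normal
    assert 0.90 <= hits / 200 <= 0.99


def test_shapiro_rejects_exponential_samples():
    rejections = 0
    for seed in range(200):
        x = np.random.default_rng(seed).exponential(size=69)
        rejections += not shapiro_normal(x).is_normal
    assert rejections / 200 > 0.95


def test_shapiro_degenerate_inputs():
    with pytest.raises(ValueError):
        shapiro_normal([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        shapiro_normal([1.0, 2.0])


def test_log_transform_screen_normalizes_lognormal_trait():
    rng = np.random.default_rng(8)
    df = pd.DataFrame({"species": range(69), "N": np.exp(rng.standard_normal(69))})
    raw = normality_screen(df, traits=["N"])
    logged = normality_screen(df, traits=["N"], log10_traits=("N",))
    assert not raw["N"].is_normal
    assert logged["N"].is_normal


# --- pairwise correlation -------------------------------------------------


def test_exact_linear_relation_gives_pearson_one():
    x = np.arange(10.0)
    res = correlate_pair(x, 2 * x + 1, True, True)
    assert res.method == "pearson"
    assert res.coefficient == pytest.approx(1.0)


def test_spearman_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    x, y = rng.normal(size=30), rng.normal(size=30)
    a = correlate_pair(x, y, False, True)
    b = correlate_pair(x, np.exp(y), False, True)
    assert a.method == b.method == "spearman"
    assert a.coefficient == pytest.approx(b.coefficient)


def test_gate_selects_spearman_when_either_not_normal():
    x = np.arange(12.0)
    assert correlate_pair(x, x**2, True, False).method == "spearman"
    assert correlate_pair(x, x + 1, True, True).method == "pearson"


def test_pairwise_deletion_and_validation():
    x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
    y = np.array([2.0, 4.0, 6.0, 8.0, np.nan])
    res = correlate_pair(x, y, True, True)
    assert res.n == 3
    with pytest.raises(ValueError, match="length"):
        correlate_pair([1, 2, 3], [1, 2], True, True)
    with pytest.raises(ValueError, match="variance"):
        correlate_pair([1, 1, 1], [1, 2, 3], True, True)


def test_no_multiple_testing_correction_is_applied():
    # reported p values are the raw two-sided test p values
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=25), rng.normal(size=25)
    res = correlate_pair(x, y, True, True)
    assert res.p == pytest.approx(sps.pearsonr(x, y)[1])


def test_significance_bands_match_convention():
    assert significance_band(0.2) == "ns"
    assert significance_band(0.03) == "*"
    assert significance_band(0.005) == "**"
    assert significance_band(0.0005) == "***"


# --- matrix ---------------------------------------------------------------


@pytest.fixture(scope="module")
def cohort_means():
    return species_means(study_cohort_table(rng_seed=42))


def test_matrix_symmetry_and_unit_diagonal(cohort_means):
    corr = correlation_matrix(cohort_means)
    for mat in (corr.pearson, corr.spearman, corr.headline):
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)


def test_headline_entries_come_from_a_base_matrix(cohort_means):
    corr = correlation_matrix(cohort_means)
    for i, x in enumerate(corr.traits):
        for y in corr.traits[i + 1:]:
            h = corr.headline.loc[x, y]
            assert h in (corr.pearson.loc[x, y], corr.spearman.loc[x, y])
            both_normal = corr.normality[x] and corr.normality[y]
            want = corr.pearson.loc[x, y] if both_normal else corr.spearman.loc[x, y]
            assert h == want


def test_fibre_parenchyma_tradeoff_recovered_at_study_size(cohort_means):
    corr = correlation_matrix(cohort_means)
    r = corr.headline.loc["TFF", "TPF"]
    # 95% sampling interval of r = -0.86 at n = 69 is about +/- 0.065
    assert r == pytest.approx(-0.86, abs=0.10)


def test_zero_variance_trait_dropped_with_warning(cohort_means):
    df = cohort_means.copy()
    df["WD"] = 0.5
    with pytest.warns(UserWarning, match="WD"):
        corr = correlation_matrix(df)
    assert "WD" not in corr.traits


def test_site_restriction(cohort_means):
    corr = correlation_matrix(cohort_means, site="rainforest")
    assert corr.n.to_numpy().max() <= 41


def test_matrix_requires_enough_species(cohort_means):
    with pytest.raises(ValueError, match="3 species"):
        correlation_matrix(cohort_means.head(2))


# --- summaries ------------------------------------------------------------


def test_summary_of_constant_trait():
    df = pd.DataFrame({"species": list("abc"), "WD": [0.5, 0.5, 0.5]})
    row = summarize_traits(df, traits=["WD"]).iloc[0]
    assert row["low"] == row["high"] == row["average"] == 0.5
    assert row["nfold"] == 1.0


def test_summary_zero_rule_uses_lowest_nonzero():
    df = pd.DataFrame({"species": list("abcd"), "CF": [0.0, 0.002, 0.01, 0.15]})
    row = summarize_traits(df, traits=["CF"]).iloc[0]
    assert row["low"] == pytest.approx(0.002)
    assert row["nfold"] == pytest.approx(75.0)
    assert row["average"] == pytest.approx(np.mean([0.002, 0.01, 0.15]))
    assert row["n_present"] == 3


def test_summary_empty_table_raises():
    with pytest.raises(ValueError):
        summarize_traits(pd.DataFrame())
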