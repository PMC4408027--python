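import numpy as np
import pandas as pd
import pytest

from twigwood import RangeMarginal, TraitTableSpec, generate_trait_table, study_cohort_table
from twigwood.copula import (
    GaussianCopula,
    NotPositiveSemidefiniteError,
    nearest_correlation,
    validate_correlation,
)
from twigwood.reference import BASE_FRACTIONS, COMPOSITES


# --- copula engine --------------------------------------------------------


def test_non_psd_matrix_raises_with_suggestion():
    bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
    with pytest.raises(NotPositiveSemidefiniteError) as err:
        validate_correlation(bad)
    fix = err.value.suggestion
    assert np.linalg.eigvalsh(fix).min() >= -1e-10
    assert np.allclose(np.diag(fix), 1.0)


def test_nearest_correlation_is_identity_on_valid_input():
    good = np.array([[1.0, 0.5], [0.5, 1.0]])
    assert np.allclose(nearest_correlation(good), good, atol=1e-8)


def test_marginal_bounds_validated():
    with pytest.raises(ValueError, match="low"):
        RangeMarginal(0.5, 0.5)
    with pytest.raises(ValueError, match="mean"):
        RangeMarginal(0.0, 1.0, mean=1.5)


def test_copula_respects_marginal_bounds():
    cop = GaussianCopula(
        ["x", "y"],
        np.array([[1.0, -0.7], [-0.7, 1.0]]),
        {"x": RangeMarginal(2.0, 5.0), "y": RangeMarginal(-1.0, 1.0)},
    )
    vals = cop.sample(500, np.random.default_rng(0))
    assert vals["x"].min() >= 2.0 and vals["x"].max() <= 5.0
    assert vals["y"].min() >= -1.0 and vals["y"].max() <= 1.0


def test_copula_recovers_negative_latent_correlation():
    cop = GaussianCopula(
        ["x", "y"],
        np.array([[1.0, -0.86], [-0.86, 1.0]]),
        {"x": RangeMarginal(0.1, 0.7, 0.35), "y": RangeMarginal(0.2, 0.8, 0.45)},
    )
    vals = cop.sample(5000, np.random.default_rng(1))
    r = np.corrcoef(vals["x"], vals["y"])[0, 1]
    assert r == pytest.approx(-0.86, abs=0.03)


# --- generic trait tables -------------------------------------------------


def _generic_spec(**kw):
    marginals = {
        "t1": RangeMarginal(0.0, 1.0),
        "t2": RangeMarginal(0.1, 0.9),
        "t3": RangeMarginal(10.0, 50.0),
        "t4": RangeMarginal(1.0, 2.0),
    }
    return TraitTableSpec(marginals=marginals, **kw)


def test_identity_latent_gives_near_zero_correlations():
    """Null simulation: with an identity latent matrix the generated traits
    are uncorrelated — pairwise r averages to ~0 over repeated cohorts and
    no single draw strays beyond loose null bounds."""
    traits = None
    sums: dict[tuple[str, str], list[float]] = {}
    for seed in range(30):
        spec = _generic_spec(
            n_species=200, n_replicates=1, replicate_cv=0.0, rng_seed=seed
        )
        df = generate_trait_table(spec)
        traits = traits or list(spec.marginals)
        for i, a in enumerate(traits):
            for b in traits[i + 1:]:
                sums.setdefault((a, b), []).append(
                    np.corrcoef(df[a], df[b])[0, 1]
                )
    for pair, rs in sums.items():
        assert abs(np.mean(rs)) < 0.05, pair      # ~3.9 sigma of the mean
        assert max(np.abs(rs)) < 0.33, pair       # ~4.7 sigma single-draw


def test_generated_traits_stay_inside_marginal_ranges():
    spec = _generic_spec(n_species=50, n_replicates=1, replicate_cv=0.0)
    df = generate_trait_table(spec)
    assert df["t3"].between(10.0, 50.0).all()
    assert df["t2"].between(0.1, 0.9).all()


def test_trait_table_is_deterministic_given_seed():
    a = generate_trait_table(_generic_spec(rng_seed=9))
    b = generate_trait_table(_generic_spec(rng_seed=9))
    pd.testing.assert_frame_equal(a, b)


def test_spec_validation():
    with pytest.raises(ValueError, match="replicate_cv"):
        _generic_spec(replicate_cv=1.5)
    with pytest.raises(ValueError, match="site"):
        _generic_spec(n_species=5, site_labels=("a",))


def test_closure_renormalizes_rows():
    spec = TraitTableSpec(
        marginals={"a": RangeMarginal(0.1, 0.5), "b": RangeMarginal(0.2, 0.9)},
        closure=("a", "b"),
        n_species=20,
        n_replicates=2,
    )
    df = generate_trait_table(spec)
    assert np.allclose(df["a"] + df["b"], 1.0)


# --- study cohort ---------------------------------------------------------


@pytest.fixture(scope="module")
def cohort():
    return study_cohort_table(rng_seed=123)


def test_cohort_base_fractions_close_to_one(cohort):
    sums = cohort[list(BASE_FRACTIONS)].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_cohort_composites_and_vessel_identities(cohort):
    for comp, (a, b) in COMPOSITES.items():
        assert np.allclose(cohort[comp], cohort[a] + cohort[b], atol=1e-9)
    assert np.allclose(cohort["N"] * cohort["A"], cohort["VLF"], atol=1e-12)
    assert np.allclose(cohort["S"] * cohort["N"], cohort["A"], atol=1e-12)


def test_cohort_design_counts(cohort):
    species = cohort.drop_duplicates("species")
    assert len(species) == 69
    assert species["site"].value_counts().to_dict() == {
        "rainforest": 41, "temperate": 17, "woodland": 11,
    }
    assert (species["CF"] > 0).sum() == 26
    assert (species["MCF"] > 0).sum() == 3
    muc = species.loc[species["MCF"] > 0, "site"]
    assert (muc == "rainforest").all()


def test_cohort_fractions_are_valid(cohort):
    for col in BASE_FRACTIONS:
        assert cohort[col].between(0, 1).all()


def test_cohort_composite_correlation_at_large_n():
    df = study_cohort_table(n_species=1000, species_level=True, rng_seed=3)
    r = np.corrcoef(df["TPF"], df["TFF"])[0, 1]
    assert r == pytest.approx(-0.86, abs=0.05)


def test_cohort_deterministic_given_seed():
    a = study_cohort_table(rng_seed=11)
    b = study_cohort_table(rng_seed=11)
    pd.testing.assert_frame_equal(a, b)
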