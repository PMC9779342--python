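import numpy as np
import pandas as pd
import pytest

from riskshare.design import validate_design
from riskshare.synthetic import (
    CategoryBlock,
    Member,
    SyntheticModel,
    generate_cohort,
    model_from_dict,
    model_to_dict,
    salia_template,
    true_contributions,
)


def test_reproducible_and_seed_sensitive(recovery_model):
    t1, _ = generate_cohort(recovery_model, 7)
    t2, _ = generate_cohort(recovery_model, 7)
    pd.testing.assert_frame_equal(t1, t2)
    t3, _ = generate_cohort(recovery_model, 8)
    assert not t1.equals(t3)


def test_null_model_outcome_uncorrelated():
    model = SyntheticModel(
        n_participants=10_000,
        categories=[CategoryBlock("c", [Member(f"x{j}") for j in range(4)], rho=0.3)],
        noise_sd=1.0,
    )
    table, design = generate_cohort(model, 1)
    for col in ["x0", "x1", "x2", "x3"]:
        r = np.corrcoef(table[col], table[design.outcome])[0, 1]
        assert abs(r) < 4 / np.sqrt(10_000)


def test_block_correlation_preserved():
    model = SyntheticModel(
        n_participants=10_000,
        categories=[CategoryBlock("c", [Member(f"x{j}") for j in range(5)], rho=0.9)],
    )
    table, _ = generate_cohort(model, 2)
    C = np.corrcoef(table[[f"x{j}" for j in range(5)]].to_numpy().T)
    off = C[np.triu_indices(5, 1)]
    assert np.all(off > 0.85) and np.all(off < 0.95)


def test_generated_design_validates_and_types_match():
    model = salia_template(n_snps=5, n_participants=200)
    table, design = generate_cohort(model, 3)
    validate_design(design, table)
    assert design.outcome == "fev1_z"
    assert design.single_groups == {"ses": ["ses_medium", "ses_high"]}
    assert set(table["current_smoking"].unique()) <= {0.0, 1.0}
    assert set(table["snp_001"].unique()) <= {0.0, 1.0, 2.0}
    # outcome is a z-score
    assert table["fev1_z"].mean() == pytest.approx(0.0, abs=1e-12)
    assert table["fev1_z"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_template_marginals_match_descriptives():
    """Generated means/SDs/prevalences stay within 3 standard errors of the
    template's target values (BMI 27.29 (4.34), smoking prevalence 0.024,
    NO2 37.21 (11.16), correlated with NOx)."""
    model = salia_template(n_snps=5, n_participants=547)
    table, _ = generate_cohort(model, 11)
    n = len(table)
    assert abs(table["bmi_followup"].mean() - 27.29) < 3 * 4.34 / np.sqrt(n)
    assert abs(table["bmi_followup"].std(ddof=1) - 4.34) < 3 * 4.34 / np.sqrt(n)
    se_prev = np.sqrt(0.024 * 0.976 / n)
    assert abs(table["current_smoking"].mean() - 0.024) < 3 * se_prev
    assert abs(table["no2"].mean() - 37.21) < 3 * 11.16 / np.sqrt(n)
    assert np.corrcoef(table["no2"], table["nox"])[0, 1] > 0.5


def test_degenerate_inputs_rejected(recovery_model):
    with pytest.raises(ValueError):
        generate_cohort(
            SyntheticModel(n_participants=1,
                           categories=recovery_model.categories), 0
        )
    bad_corr = np.array([[1.0, 2.0], [2.0, 1.0]])
    with pytest.raises(ValueError, match="positive definite"):
        SyntheticModel(
            n_participants=10,
            singles=[Member("a"), Member("b")],
            single_corr=bad_corr,
        ).latent_correlation()
    with pytest.raises(ValueError):
        CategoryBlock("c", [Member("x")], rho=1.0)


# -- analytic ground truth --------------------------------------------------


def test_zero_effects_zero_shares(null_model):
    shares, r2 = true_contributions(null_model)
    assert r2 == pytest.approx(0.0, abs=1e-12)
    assert all(v == pytest.approx(0.0, abs=1e-12) for v in shares.values())


def test_orthogonal_equal_effects_split_evenly():
    """Two independent single-member categories with equal effects and
    noise tuned for R^2 = 0.5 take shares 0.25 each."""
    b = 0.5
    model = SyntheticModel(
        n_participants=100,
        categories=[CategoryBlock("a", [Member("x1", effect=b)]),
                    CategoryBlock("b", [Member("x2", effect=b)])],
        noise_sd=np.sqrt(2 * b**2),  # signal var = noise var
    )
    shares, r2 = true_contributions(model)
    assert r2 == pytest.approx(0.5, abs=1e-12)
    assert shares["a"] == pytest.approx(0.25, abs=1e-12)
    assert shares["b"] == pytest.approx(0.25, abs=1e-12)


def test_single_informative_category_takes_all(recovery_model):
    model = SyntheticModel(
        n_participants=100,
        categories=[
            CategoryBlock("signal", [Member("s1", effect=0.4),
                                     Member("s2", effect=0.4)], rho=0.5),
            CategoryBlock("nothing", [Member("n1"), Member("n2")], rho=0.3),
        ],
        noise_sd=0.8,
    )
    shares, r2 = true_contributions(model)
    assert shares["signal"] == pytest.approx(r2, abs=1e-12)
    assert shares["nothing"] == pytest.approx(0.0, abs=1e-12)


def test_block_model_shares_hit_targets(recovery_model):
    shares, r2 = true_contributions(recovery_model)
    np.testing.assert_allclose(
        [shares["cat1"], shares["cat2"], shares["cat3"]], [0.12, 0.06, 0.01],
        atol=1e-12,
    )
    assert r2 == pytest.approx(0.19, abs=1e-12)


def test_truth_equivariant_under_category_relabeling(recovery_model):
    base, _ = true_contributions(recovery_model)
    perm = SyntheticModel(
        n_participants=recovery_model.n_participants,
        categories=recovery_model.categories[::-1],
        noise_sd=recovery_model.noise_sd,
    )
    flipped, _ = true_contributions(perm)
    for k in base:
        assert flipped[k] == pytest.approx(base[k], abs=1e-12)


def test_model_dict_round_trip():
    model = salia_template(n_snps=3, n_participants=50)
    rebuilt = model_from_dict(model_to_dict(model))
    t1, _ = generate_cohort(model, 5)
    t2, _ = generate_cohort(rebuilt, 5)
    pd.testing.assert_frame_equal(t1, t2)
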