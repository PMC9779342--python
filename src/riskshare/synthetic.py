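"""Synthetic cohorts with known category contributions.

Cohorts are drawn from a Gaussian copula: all dependence lives on a
latent multivariate-normal scale, where each risk-factor category is an
equicorrelated block (within-block correlation ``rho``), blocks are
mutually independent, and single predictors carry their own optional
correlation matrix.  Marginals are obtained by transforming the latent
normals — affinely for continuous variables, by quantile thresholding for
binary prevalences, and through the Binomial(2, allele frequency)
quantile function for SNP allele counts.  Realized correlations of
discretized variables are therefore attenuated relative to the latent
``rho``.

The outcome is linear on the latent scale,

    y = sum_j effect_j * z_j + eps,   eps ~ N(0, noise_sd²),

then standardized to a z-score.  Keeping the effects on the latent scale
makes the implied joint covariance of predictors and outcome available in
closed form, so the population explained-variance decomposition — the
recovery target for the whole pipeline — is analytic
(:func:`true_contributions`).  For continuous predictors the latent and
realized variables coincide up to an affine map, so the analytic shares
are exactly what an infinite-data run of the pipeline estimates; for
binary/SNP members they are the latent-scale ideal that realized data
approach from below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import StudyDesign, VariableSpec
from .importance import lmg_from_moments


@dataclass
class Member:
    """One synthetic variable: marginal parameters and its latent effect
    on the outcome."""

    name: str
    var_type: str = "continuous"
    mean: float = 0.0
    sd: float = 1.0
    prevalence: float = 0.5
    allele_freq: float = 0.3
    effect: float = 0.0

    def __post_init__(self) -> None:
        if self.var_type not in ("continuous", "binary", "snp"):
            raise ValueError(f"unknown var_type {self.var_type!r}")
        if self.var_type == "continuous" and self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")
        if self.var_type == "binary" and not 0 < self.prevalence < 1:
            raise ValueError(f"{self.name}: prevalence must be in (0,1)")
        if self.var_type == "snp" and not 0 < self.allele_freq < 1:
            raise ValueError(f"{self.name}: allele_freq must be in (0,1)")


@dataclass
class CategoryBlock:
    """An equicorrelated block of category members."""

    name: str
    members: list[Member]
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"category {self.name!r}: rho must be in [0, 1)")
        if len(self.members) < 1:
            raise ValueError(f"category {self.name!r} needs at least one member")


@dataclass
class SyntheticModel:
    """Generative specification of a cohort.

    ``single_corr`` is an optional latent correlation matrix among the
    single predictors (identity if omitted); categories are mutually
    independent blocks.  ``single_groups`` is forwarded to the generated
    :class:`~riskshare.design.StudyDesign`.
    """

    n_participants: int
    singles: list[Member] = field(default_factory=list)
    categories: list[CategoryBlock] = field(default_factory=list)
    single_corr: np.ndarray | None = None
    noise_sd: float = 1.0
    outcome: str = "y"
    single_groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.single_corr is not None:
            self.single_corr = np.asarray(self.single_corr, float)
            k = len(self.singles)
            if self.single_corr.shape != (k, k):
                raise ValueError("single_corr shape does not match singles")

    # ------------------------------------------------------------------
    @property
    def all_members(self) -> list[Member]:
        return self.singles + [m for c in self.categories for m in c.members]

    @property
    def effects(self) -> np.ndarray:
        return np.array([m.effect for m in self.all_members])

    def latent_correlation(self) -> np.ndarray:
        """Block-diagonal latent correlation matrix (positive definite)."""
        blocks = []
        k = len(self.singles)
        if k:
            blocks.append(self.single_corr if self.single_corr is not None else np.eye(k))
        for c in self.categories:
            m = len(c.members)
            blocks.append(np.full((m, m), c.rho) + (1 - c.rho) * np.eye(m))
        if not blocks:
            raise ValueError("model has no predictors")
        R = _block_diag(blocks)
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError as e:
            raise ValueError("implied latent covariance is not positive definite") from e
        return R

    def to_design(self) -> StudyDesign:
        variables = [VariableSpec(self.outcome, "outcome")]
        variables += [VariableSpec(m.name, "single", var_type=m.var_type)
                      for m in self.singles]
        for c in self.categories:
            variables += [
                VariableSpec(m.name, "member", var_type=m.var_type, category=c.name)
                for m in c.members
            ]
        return StudyDesign(variables=variables, single_groups=dict(self.single_groups))


def _block_diag(blocks: list[np.ndarray]) -> np.ndarray:
    p = sum(b.shape[0] for b in blocks)
    out = np.zeros((p, p))
    i = 0
    for b in blocks:
        m = b.shape[0]
        out[i : i + m, i : i + m] = b
        i += m
    return out


def _transform(z: np.ndarray, member: Member) -> np.ndarray:
    if member.var_type == "continuous":
        return member.mean + member.sd * z
    if member.var_type == "binary":
        return (z > stats.norm.ppf(1.0 - member.prevalence)).astype(float)
    u = stats.norm.cdf(z)
    return stats.binom.ppf(u, 2, member.allele_freq)


def generate_cohort(
    model: SyntheticModel, seed: int
) -> tuple[pd.DataFrame, StudyDesign]:
    """Draw a cohort table; identical (model, seed) gives identical output.

    The outcome column is the latent linear predictor plus Gaussian noise,
    standardized to a sample z-score (mean 0, SD 1 with ddof=1).
    """
    if model.n_participants < 2:
        raise ValueError("need at least 2 participants")
    R = model.latent_correlation()
    L = np.linalg.cholesky(R)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((model.n_participants, R.shape[0])) @ L.T
    members = model.all_members
    data = {m.name: _transform(Z[:, j], m) for j, m in enumerate(members)}
    y = Z @ model.effects + model.noise_sd * rng.standard_normal(model.n_participants)
    y = (y - y.mean()) / y.std(ddof=1)
    table = pd.DataFrame({model.outcome: y, **data})
    return table, model.to_design()


def true_contributions(model: SyntheticModel) -> tuple[dict[str, float], float]:
    """Population LMG shares per regressor unit, and the population R².

    Each category is represented by its best-linear-combination score
    (the population regression of the outcome on that category's latent
    block alone, uniform if the category carries no signal — mirroring
    the pipeline's uniform fallback), each ungrouped single predictor by
    itself, and each single group by its block.  Shares are computed by
    the same Shapley algebra as the empirical decomposition, applied to
    the implied covariance matrix, and sum to the population R² of the
    score-based model.
    """
    R = model.latent_correlation()
    beta = model.effects
    c = R @ beta  # cov(latents, y)
    var_y = float(beta @ R @ beta) + model.noise_sd**2
    if var_y <= 0:
        raise ValueError("degenerate outcome: zero variance")

    k = len(model.singles)
    # linear maps latent -> unit variables
    maps: list[np.ndarray] = []  # each (p,) weight vector
    unit_names: list[str] = []
    unit_groups: list[list[int]] = []
    col_group = {s: g for g, cols in model.single_groups.items() for s in cols}
    grouped: dict[str, list[int]] = {}
    for j, s in enumerate(model.singles):
        e = np.zeros(R.shape[0])
        e[j] = 1.0
        maps.append(e)
        g = col_group.get(s.name)
        if g is None:
            unit_names.append(s.name)
            unit_groups.append([len(maps) - 1])
        else:
            grouped.setdefault(g, []).append(len(maps) - 1)
    for g, idx in grouped.items():
        unit_names.append(g)
        unit_groups.append(idx)
    offset = k
    for cat in model.categories:
        m = len(cat.members)
        block = slice(offset, offset + m)
        Rk = R[block, block]
        ck = c[block]
        if np.allclose(ck, 0.0):
            w = np.full(m, 1.0 / m)
        else:
            w = np.linalg.solve(Rk, ck)
        e = np.zeros(R.shape[0])
        e[block] = w
        maps.append(e)
        unit_names.append(cat.name)
        unit_groups.append([len(maps) - 1])
        offset += m
    W = np.column_stack(maps)
    cov_units = W.T @ R @ W
    cov_uy = W.T @ c
    groups = [np.array(g) for g in unit_groups]
    shares, r2 = lmg_from_moments(cov_units, cov_uy, var_y, groups)
    return dict(zip(unit_names, map(float, shares))), r2


# ---------------------------------------------------------------------------
# packaged template


def salia_template(n_snps: int = 15, n_participants: int = 510) -> SyntheticModel:
    """A lung-function-flavoured cohort template.

    Marginal means, SDs and prevalences mirror published descriptive
    statistics of the SALIA cohort of elderly German women (ages ~73,
    n = 510 with lung-function data): singles age, height and two SES
    dummies; categories genetic (SNP allele counts), obesity, smoking and
    air pollution.  The real genetic score uses 278 SNPs; the template
    defaults to 15 independent-ish loci since no attempt is made to model
    real LD structure.  Latent effect sizes are chosen so the outcome
    variance decomposes roughly as observed for lung function (genetics
    largest, then obesity and smoking, air pollution small), with total
    explained variance near 20%.
    """
    snps = [
        Member(f"snp_{i:03d}", "snp", allele_freq=0.15 + 0.02 * (i % 10),
               effect=0.055)
        for i in range(1, n_snps + 1)
    ]
    singles = [
        Member("age", mean=73.52, sd=2.99, effect=-0.02),
        Member("height", mean=162.83, sd=5.76, effect=0.05),
        Member("ses_medium", "binary", prevalence=0.488, effect=0.03),
        Member("ses_high", "binary", prevalence=0.337, effect=0.06),
    ]
    # the two SES dummies are mutually exclusive levels: negative latent corr
    single_corr = np.eye(4)
    single_corr[2, 3] = single_corr[3, 2] = -0.6
    model = SyntheticModel(
        n_participants=n_participants,
        singles=singles,
        single_corr=single_corr,
        categories=[
            CategoryBlock("genetic", snps, rho=0.1),
            CategoryBlock(
                "obesity",
                [
                    Member("bmi_mean_early", mean=26.66, sd=3.66, effect=-0.09),
                    Member("bmi_followup", mean=27.29, sd=4.34, effect=-0.09),
                    Member("low_physical_activity", "binary", prevalence=0.602,
                           effect=-0.09),
                ],
                rho=0.6,
            ),
            CategoryBlock(
                "smoking",
                [
                    Member("current_smoking", "binary", prevalence=0.024, effect=-0.05),
                    Member("former_smoking", "binary", prevalence=0.167, effect=-0.05),
                    Member("ets_work", "binary", prevalence=0.424, effect=-0.05),
                    Member("ets_home", "binary", prevalence=0.339, effect=-0.05),
                    Member("packyears", mean=3.83, sd=12.74, effect=-0.05),
                ],
                rho=0.4,
            ),
            CategoryBlock(
                "air_pollution",
                [
                    Member("urban_residence", "binary", prevalence=0.512, effect=-0.009),
                    Member("no2", mean=37.21, sd=11.16, effect=-0.009),
                    Member("nox", mean=69.17, sd=31.93, effect=-0.009),
                    Member("pm10", mean=48.98, sd=7.38, effect=-0.009),
                    Member("pm25", mean=32.56, sd=4.78, effect=-0.009),
                    Member("pm_coarse", mean=17.42, sd=3.91, effect=-0.009),
                    Member("pm25_absorbance", mean=2.71, sd=0.92, effect=-0.009),
                    Member("traffic_load_major", mean=839.51, sd=2200.63, effect=-0.009),
                    Member("inv_distance_major", mean=0.01, sd=0.02, effect=-0.009),
                ],
                rho=0.7,
            ),
        ],
        noise_sd=0.95,
        outcome="fev1_z",
        single_groups={"ses": ["ses_medium", "ses_high"]},
    )
    return model


# ---------------------------------------------------------------------------
# plain-text (YAML) serialization of models


def model_from_dict(d: dict) -> SyntheticModel:
    def member(spec: dict) -> Member:
        spec = dict(spec)
        spec["var_type"] = spec.pop("type", spec.pop("var_type", "continuous"))
        return Member(**spec)

    singles = [member(s) for s in d.get("singles", [])]
    cats = [
        CategoryBlock(
            name=c["name"],
            rho=float(c.get("rho", 0.0)),
            members=[member(m) for m in c["members"]],
        )
        for c in d.get("categories", [])
    ]
    sc = d.get("single_corr")
    return SyntheticModel(
        n_participants=int(d["n_participants"]),
        singles=singles,
        categories=cats,
        single_corr=np.asarray(sc, float) if sc is not None else None,
        noise_sd=float(d.get("noise_sd", 1.0)),
        outcome=str(d.get("outcome", "y")),
        single_groups={k: list(v) for k, v in (d.get("single_groups") or {}).items()},
    )


def model_to_dict(model: SyntheticModel) -> dict:
    def member(m: Member) -> dict:
        out: dict = {"name": m.name, "type": m.var_type, "effect": m.effect}
        if m.var_type == "continuous":
            out.update(mean=m.mean, sd=m.sd)
        elif m.var_type == "binary":
            out.update(prevalence=m.prevalence)
        else:
            out.update(allele_freq=m.allele_freq)
        return out

    d: dict = {
        "n_participants": model.n_participants,
        "outcome": model.outcome,
        "noise_sd": model.noise_sd,
        "singles": [member(m) for m in model.singles],
        "categories": [
            {"name": c.name, "rho": c.rho, "members": [member(m) for m in c.members]}
            for c in model.categories
        ],
    }
    if model.single_corr is not None:
        d["single_corr"] = model.single_corr.tolist()
    if model.single_groups:
        d["single_groups"] = {k: list(v) for k, v in model.single_groups.items()}
    return d
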