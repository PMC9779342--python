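"""Declarative description of a risk-score analysis.

A study design assigns every analysis column one of three roles:

``outcome``
    The single continuous response (typically a z-score).
``single``
    A covariate entering the final linear model directly, unregularized in
    the weight-learning step.  Dummy codings of one categorical variable
    (e.g. two socio-economic-status dummies) can be declared as a
    *single group* so that the importance decomposition treats them as one
    regressor unit.
``member``
    A predictor belonging to a named risk-factor category (air pollution,
    smoking, ...).  All members of one category are combined into a single
    weighted risk score.

Variables are ``continuous``, ``binary`` (0/1) or ``snp`` (minor-allele
count 0/1/2).  Everything except SNPs is standardized before model fitting;
SNPs stay on their allele-count scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ROLES = ("outcome", "single", "member")
VAR_TYPES = ("continuous", "binary", "snp")


class DesignError(ValueError):
    """Raised when a study design is internally inconsistent or does not
    match the cohort table it is applied to."""


@dataclass(frozen=True)
class VariableSpec:
    """One analysis column and its role.

    ``standardize`` defaults to True for every variable type except
    ``snp``; an explicit value overrides the default.
    """

    name: str
    role: str
    var_type: str = "continuous"
    category: str | None = None
    standardize: bool | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DesignError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.var_type not in VAR_TYPES:
            raise DesignError(
                f"unknown var_type {self.var_type!r} for variable {self.name!r}"
            )
        if (self.category is not None) != (self.role == "member"):
            raise DesignError(
                f"variable {self.name!r}: category must be given exactly for role='member'"
            )
        if self.standardize is None:
            object.__setattr__(self, "standardize", self.var_type != "snp")

    @property
    def is_standardized(self) -> bool:
        return bool(self.standardize)


@dataclass
class StudyDesign:
    """A full variable inventory: one outcome, single predictors and
    ordered risk-factor categories.

    ``single_groups`` maps a group name to the single predictors that form
    one regressor unit in the importance decomposition.
    """

    variables: list[VariableSpec]
    single_groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check_invariants()

    # -- derived views ---------------------------------------------------
    @property
    def outcome(self) -> str:
        return next(v.name for v in self.variables if v.role == "outcome")

    @property
    def singles(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "single"]

    @property
    def categories(self) -> dict[str, list[str]]:
        """Ordered mapping category name -> member column names."""
        cats: dict[str, list[str]] = {}
        for v in self.variables:
            if v.role == "member":
                cats.setdefault(v.category, []).append(v.name)
        return cats

    @property
    def member_counts(self) -> dict[str, int]:
        return {k: len(m) for k, m in self.categories.items()}

    @property
    def analysis_columns(self) -> list[str]:
        return [v.name for v in self.variables]

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    # -- validation ------------------------------------------------------
    def _check_invariants(self) -> None:
        names = [v.name for v in self.variables]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise DesignError(f"duplicate variable names: {sorted(dup)}")
        n_out = sum(v.role == "outcome" for v in self.variables)
        if n_out != 1:
            raise DesignError(f"exactly one outcome required, got {n_out}")
        for k, members in self.categories.items():
            if len(members) < 1:
                raise DesignError(f"category {k!r} has no members")
        singles = set(self.singles)
        seen: dict[str, str] = {}
        for group, cols in self.single_groups.items():
            for c in cols:
                if c not in singles:
                    raise DesignError(
                        f"single_group {group!r} references {c!r}, which is not a single predictor"
                    )
                if c in seen:
                    raise DesignError(
                        f"single predictor {c!r} appears in groups {seen[c]!r} and {group!r}"
                    )
                seen[c] = group


def validate_design(design: StudyDesign, table: pd.DataFrame) -> StudyDesign:
    """Check a design against a cohort table and return it.

    Confirms that every declared variable has a column, that roles
    partition the analysis columns (guaranteed by construction) and that
    SNP columns only hold allele counts 0, 1 or 2.  Validation is
    idempotent: it never alters the design.
    """
    design._check_invariants()
    missing = [c for c in design.analysis_columns if c not in table.columns]
    if missing:
        raise DesignError(f"cohort table is missing columns: {missing}")
    for v in design.variables:
        col = table[v.name]
        if not pd.api.types.is_numeric_dtype(col):
            raise DesignError(f"column {v.name!r} is not numeric")
        if v.var_type == "snp":
            vals = col.dropna()
            bad = ~vals.isin([0, 1, 2])
            if bad.any():
                raise DesignError(
                    f"snp column {v.name!r} contains values outside {{0,1,2}}: "
                    f"{sorted(vals[bad].unique())[:5]}"
                )
        if v.var_type == "binary":
            vals = col.dropna()
            bad = ~vals.isin([0, 1])
            if bad.any():
                raise DesignError(
                    f"binary column {v.name!r} contains values outside {{0,1}}"
                )
    return design


def complete_cases(table: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Drop rows with any missing analysis variable (complete-case rule)."""
    cols = design.analysis_columns
    keep = table[cols].notna().all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("complete-case analysis: dropped %d of %d rows", n_drop, len(table))
    return table.loc[keep].reset_index(drop=True)


@dataclass
class AnalysisConfig:
    """Tuning knobs of the full pipeline.

    Parameters
    ----------
    n_bootstrap
        Number of bootstrap replicates *B*; replicate 0 is always the
        original data set.
    train_fraction
        Share of each replicate assigned to the training sample
        (weight learning); the rest forms the test sample.
    cv_folds, cv_repeats
        Folds of the cross-validation that picks the ridge penalty, and
        how many fold re-randomizations are averaged.
    n_lambda, lambda_min_ratio
        Geometry of the descending penalty grid.
    ci_level
        Level of the percentile bootstrap confidence intervals.
    standardize_on
        ``"train"`` (default): standardization statistics are estimated on
        each replicate's training sample and frozen for its test sample.
        ``"full"``: one-time standardization on the original table before
        any resampling.
    iqr_on
        Reference sample for the risk-score interquartile range:
        ``"test"`` (default) or ``"replicate"`` (train + test).
    """

    n_bootstrap: int = 200
    train_fraction: float = 0.6
    cv_folds: int = 10
    cv_repeats: int = 20
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    ci_level: float = 0.95
    seed: int = 0
    standardize_on: str = "train"
    iqr_on: str = "test"
    n_jobs: int = 1
    save_weights: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be strictly between 0 and 1")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.cv_folds < 2 or self.cv_repeats < 1:
            raise ValueError("cv_folds >= 2 and cv_repeats >= 1 required")
        if self.standardize_on not in ("train", "full"):
            raise ValueError("standardize_on must be 'train' or 'full'")
        if self.iqr_on not in ("test", "replicate"):
            raise ValueError("iqr_on must be 'test' or 'replicate'")


# ---------------------------------------------------------------------------
# plain-text (YAML) serialization


def design_from_dict(d: dict) -> StudyDesign:
    """Build a design from the documented config mapping.

    Schema::

        outcome: fev1_z
        singles:
          age: continuous
          ses_med: {type: binary, group: ses}
        categories:
          air_pollution:
            members:
              no2: continuous
              residence: binary
          genetic:
            var_type: snp            # default type for all members
            members: [rs1, rs2]
    """
    variables = [VariableSpec(str(d["outcome"]), "outcome")]
    groups: dict[str, list[str]] = {}
    for name, spec in (d.get("singles") or {}).items():
        if isinstance(spec, str):
            spec = {"type": spec}
        spec = spec or {}
        variables.append(
            VariableSpec(
                str(name),
                "single",
                var_type=spec.get("type", "continuous"),
                standardize=spec.get("standardize"),
            )
        )
        if "group" in spec:
            groups.setdefault(str(spec["group"]), []).append(str(name))
    for cat, cspec in (d.get("categories") or {}).items():
        default_type = (cspec or {}).get("var_type", "continuous")
        members = (cspec or {}).get("members", [])
        if isinstance(members, list):
            members = {m: default_type for m in members}
        for name, mtype in members.items():
            if isinstance(mtype, dict):
                mtype = mtype.get("type", default_type)
            variables.append(
                VariableSpec(str(name), "member", var_type=mtype or default_type,
                             category=str(cat))
            )
    return StudyDesign(variables=variables, single_groups=groups)


def design_to_dict(design: StudyDesign) -> dict:
    singles: dict[str, dict] = {}
    col_group = {c: g for g, cols in design.single_groups.items() for c in cols}
    for v in design.variables:
        if v.role == "single":
            entry: dict = {"type": v.var_type}
            if v.name in col_group:
                entry["group"] = col_group[v.name]
            singles[v.name] = entry
    categories = {}
    for cat, members in design.categories.items():
        categories[cat] = {
            "members": {m: design.variable(m).var_type for m in members}
        }
    return {"outcome": design.outcome, "singles": singles, "categories": categories}


def load_design(path) -> StudyDesign:
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))


def save_design(design: StudyDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)
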