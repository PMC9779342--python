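"""Cohort/result I/O and the run manifest.

CSV dialect is fixed: comma-separated, UTF-8, "." decimal, header row
required; the strings "" and "NA" are missing values.  Contributions are
written as percentages of outcome variance (the scale on which they are
reported); coefficients stay on the model scale.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .design import DesignError, StudyDesign, complete_cases, validate_design
from .pipeline import BootstrapResult, BootstrapSummary

logger = logging.getLogger(__name__)

NA_TOKENS = ["", "NA"]


def read_cohort_csv(path, design: StudyDesign) -> pd.DataFrame:
    """Read and validate a cohort table; complete-case rows only."""
    path = Path(path)
    table = pd.read_csv(path, na_values=NA_TOKENS, keep_default_na=False,
                        float_precision="round_trip")
    if table.shape[0] == 0:
        raise DesignError(f"{path}: empty cohort file")
    missing = [c for c in design.analysis_columns if c not in table.columns]
    if missing:
        raise DesignError(f"{path}: missing columns {missing}")
    for col in design.analysis_columns:
        try:
            table[col] = pd.to_numeric(table[col])
        except (ValueError, TypeError) as e:
            raise DesignError(f"{path}: non-numeric value in column {col!r}") from e
    n_raw = len(table)
    table = complete_cases(table, design)
    logger.info("read %d rows (%d complete cases) from %s", n_raw, len(table), path)
    validate_design(design, table)
    return table


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    out_dir,
    result: BootstrapResult,
    summary: BootstrapSummary,
    input_digests: dict[str, str] | None = None,
    wall_clock: float | None = None,
) -> None:
    """Write contributions.csv, coefficients.csv, optionally weights.csv,
    and manifest.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    contrib = summary.contributions.copy() * 100.0
    contrib.insert(0, "predictor", contrib.index)
    overall = pd.DataFrame(
        [{"predictor": "Overall",
          "median": summary.r_squared["median"] * 100.0,
          "lower": summary.r_squared["lower"] * 100.0,
          "upper": summary.r_squared["upper"] * 100.0}]
    )
    contrib = pd.concat([overall, contrib], ignore_index=True)
    contrib.to_csv(out / "contributions.csv", index=False, float_format="%.10g")

    coefs = summary.coefficients.copy()
    coefs.insert(0, "predictor", coefs.index)
    coefs.to_csv(out / "coefficients.csv", index=False, float_format="%.10g")

    if result.config.save_weights:
        rows = []
        for b, per_rep in enumerate(result.weights):
            for cw in per_rep:
                for member, w in zip(cw.members, cw.weights):
                    rows.append(
                        {"replicate": b, "category": cw.category, "member": member,
                         "weight": w, "fallback": cw.fallback or ""}
                    )
        pd.DataFrame(rows).to_csv(out / "weights.csv", index=False,
                                  float_format="%.10g")

    manifest = {
        "package": "riskshare",
        "version": __version__,
        "config": asdict(result.config),
        "seed": result.config.seed,
        "input_digests": input_digests or {},
        "n_replicates": len(result.replicates),
        "n_flagged": result.n_flagged,
        "flag_counts": summary.flag_counts,
        "ci_level": summary.ci_level,
        "wall_clock_seconds": wall_clock,
        "p_value_definition": (
            "sign-crossing interpretation of the percentile bootstrap: "
            "2*min(frac(coef>=0), frac(coef<=0)), floored at 2/B_effective"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
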