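"""Cross-cohort validation of co-modulation patterns.

The regression betas learned in a discovery cohort predict, for every patient
of an independent cohort, the covariability of each gene pair from that
patient's modulator z-scores alone ("estimated" profile). The "real" profile
is computed within the validation cohort from the pair genes' expression. A
patient validates when the two profiles — compared across the pair subset —
are significantly positively correlated, and a one-sample z-test asks whether
the validated fraction of patients exceeds the chance rate.

Modulator z-scores are always recomputed within the validation cohort (the
platforms and scales differ between cohorts); the discovery betas are applied
unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .covariability import covariability_profile, zscore_rows
from .expression_io import ExpressionMatrix
from .modulation import proportion_ci
from .regression import CoModulationPattern

__all__ = ["ValidationReport", "estimate_profile", "validate_cohort"]


@dataclass
class ValidationReport:
    """Per-patient and overall outcome of a cohort validation run.

    ``per_patient`` has one row per validation-cohort patient with the
    Pearson r between estimated and real profiles (across pairs), its
    two-sided p-value and the validated flag (r > 0 and p < patient_alpha).
    The z-test is one-sided: does the validated proportion exceed
    ``null_proportion``?
    """

    per_patient: pd.DataFrame
    n_validated: int
    n_patients: int
    proportion: float
    ci_low: float
    ci_high: float
    z_statistic: float
    z_pvalue: float
    patient_alpha: float
    null_proportion: float

    def summary(self) -> dict:
        return {
            "n_validated": self.n_validated,
            "n_patients": self.n_patients,
            "proportion": self.proportion,
            "percentage": round(100.0 * self.proportion, 2),
            "ci_95": [self.ci_low, self.ci_high],
            "z_statistic": self.z_statistic,
            "z_pvalue": self.z_pvalue,
            "patient_alpha": self.patient_alpha,
            "null_proportion": self.null_proportion,
        }

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.per_patient.to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def estimate_profile(
    patterns: Sequence[CoModulationPattern],
    validation_expr: ExpressionMatrix,
    include_intercept: bool = True,
) -> np.ndarray:
    """Predicted covariability (pairs x patients) from discovery betas.

    Entry (p, k) is ``intercept_p + sum_m beta_pm * z_mk`` where z_mk is the
    z-score of modulator m in validation patient k. All patterns must share
    one modulator panel, and every modulator must be present in the
    validation matrix.
    """
    if not patterns:
        return np.empty((0, validation_expr.n_samples))
    modulator_ids = patterns[0].modulator_ids
    for pat in patterns:
        if pat.modulator_ids != modulator_ids:
            raise ValueError("patterns have inconsistent modulator ids")
    z = zscore_rows(validation_expr, modulator_ids)  # M x K
    betas = np.array([pat.betas for pat in patterns])  # n x M
    est = betas @ z
    if include_intercept:
        est += np.array([pat.intercept for pat in patterns])[:, None]
    return est


def validate_cohort(
    patterns: Sequence[CoModulationPattern],
    validation_expr: ExpressionMatrix,
    pair_subset: Sequence[tuple[str, str]] | None = None,
    patient_alpha: float = 0.05,
    null_proportion: float = 0.05,
    discovery_alpha: float = 0.05,
    include_intercept: bool = True,
) -> ValidationReport:
    """Validate discovery-cohort co-modulation patterns in another cohort.

    ``pair_subset`` restricts the profile to specific gene pairs (e.g. one
    co-modulation group); by default all pairs with at least one significant
    modulator in the discovery fit (p < ``discovery_alpha``) enter. At least
    3 pairs are required for the per-patient correlation to be defined.
    """
    by_pair = {pat.pair: pat for pat in patterns}
    if pair_subset is None:
        selected = [
            pat for pat in patterns if pat.significant_set(discovery_alpha)
        ]
    else:
        missing = [p for p in pair_subset if tuple(p) not in by_pair]
        if missing:
            raise KeyError(f"pairs absent from patterns: {missing[:5]}")
        selected = [by_pair[tuple(p)] for p in pair_subset]
    if len(selected) < 3:
        raise ValueError(
            f"need at least 3 gene pairs to correlate profiles, got {len(selected)}"
        )

    pairs = [pat.pair for pat in selected]
    est = estimate_profile(selected, validation_expr, include_intercept)
    real = covariability_profile(validation_expr, pairs)

    rows = []
    for k, sample in enumerate(validation_expr.sample_ids):
        r, p = stats.pearsonr(est[:, k], real[:, k])
        rows.append(
            {
                "sample_id": sample,
                "r": float(r),
                "pvalue": float(p),
                "validated": bool(r > 0 and p < patient_alpha),
            }
        )
    per_patient = pd.DataFrame(rows)
    n_patients = len(per_patient)
    n_validated = int(per_patient["validated"].sum())
    p_hat = n_validated / n_patients
    z = (p_hat - null_proportion) / np.sqrt(
        null_proportion * (1.0 - null_proportion) / n_patients
    )
    ci_low, ci_high = proportion_ci(p_hat, n_patients, clip=True)
    return ValidationReport(
        per_patient=per_patient,
        n_validated=n_validated,
        n_patients=n_patients,
        proportion=p_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        z_statistic=float(z),
        z_pvalue=float(stats.norm.sf(z)),
        patient_alpha=patient_alpha,
        null_proportion=null_proportion,
    )
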