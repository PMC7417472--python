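"""Relative traits, distribution diagnostics and pool-level summaries.

Salt-tolerance phenotyping at the bud burst stage records shoot length
(SL, cm), root number (RN, count) and root length (RL, cm) for each line
under a control and a salt treatment; the relative trait
(treatment / control) removes between-line vigour differences, giving RSL,
RRN and RRL. A relative trait is taken forward to bulk selection only when
its distribution looks like a quantitative trait: |skewness| and |excess
kurtosis| both below 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TRAITS",
    "RELATIVE_TRAITS",
    "DistributionDiagnostics",
    "PoolComparison",
    "relative_value",
    "relative_table",
    "diagnose_distribution",
    "compare_pools",
    "read_phenotypes",
]

TRAITS = ("SL", "RN", "RL", "SNK")
RELATIVE_TRAITS = {"SL": "RSL", "RN": "RRN", "RL": "RRL"}


@dataclass
class DistributionDiagnostics:
    """Moment diagnostics of a relative-trait distribution.

    ``qtl_suitable`` is True iff |skewness| < 1 and |excess kurtosis| < 1.
    """

    trait: str
    n: int
    skewness: float
    kurtosis: float  # excess (normal = 0)
    normality_ok: bool
    qtl_suitable: bool
    reason: str = ""


@dataclass
class PoolComparison:
    """Rank-sum comparison of a trait between the two bulks."""

    median_t: float
    median_s: float
    q1_t: float
    q3_t: float
    q1_s: float
    q3_s: float
    p_value: float
    direction: str  # "T>S", "S>T" or "none"
    tested: bool


def relative_value(treatment: float, control: float) -> float:
    """Relative trait = treatment value / control value.

    A treatment value of 0 legitimately yields 0 (growth stopped under
    stress); a control value of 0 leaves the ratio undefined and raises.
    """
    if treatment < 0 or control < 0:
        raise ValueError("phenotype values must be non-negative")
    if control == 0:
        raise ZeroDivisionError("control value is 0; relative trait undefined")
    return treatment / control


def relative_table(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-line relative traits from a long phenotype table.

    Input columns: line_id, trait, control_value, treatment_value. Rows
    with control_value == 0 are excluded (counted in the log) because the
    ratio is undefined; SNK rows pass through unchanged under their own
    label since SNK is already a ratio.
    """
    required = {"line_id", "trait", "control_value", "treatment_value"}
    missing = required - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    bad = (phenotypes["control_value"] < 0) | (phenotypes["treatment_value"] < 0)
    if bad.any():
        raise ValueError("phenotype values must be non-negative")
    rows = []
    dropped = 0
    for _, rec in phenotypes.iterrows():
        trait = rec["trait"]
        if trait not in RELATIVE_TRAITS:
            continue
        if rec["control_value"] == 0:
            dropped += 1
            continue
        rows.append(
            {
                "line_id": rec["line_id"],
                "trait": RELATIVE_TRAITS[trait],
                "value": rec["treatment_value"] / rec["control_value"],
            }
        )
    if dropped:
        logger.warning(
            "excluded %d records with control value 0 (relative trait undefined)",
            dropped,
        )
    out = pd.DataFrame(rows, columns=["line_id", "trait", "value"])
    out.attrs["excluded_zero_control"] = dropped
    return out


def diagnose_distribution(values, trait: str = "") -> DistributionDiagnostics:
    """Bias-corrected sample skewness and excess kurtosis, plus suitability.

    Uses the standard bias-corrected moment estimators; normality is
    additionally probed with the D'Agostino-Pearson omnibus test at
    alpha = 0.05. Constant input leaves the moments undefined and the trait
    flagged unsuitable.
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 8:
        raise ValueError(f"need at least 8 values, got {n}")
    if np.ptp(x) == 0:
        return DistributionDiagnostics(
            trait=trait,
            n=n,
            skewness=float("nan"),
            kurtosis=float("nan"),
            normality_ok=False,
            qtl_suitable=False,
            reason="constant input: moments undefined",
        )
    skew = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normal_p = float(stats.normaltest(x).pvalue)
    suitable = abs(skew) < 1.0 and abs(kurt) < 1.0
    return DistributionDiagnostics(
        trait=trait,
        n=n,
        skewness=skew,
        kurtosis=kurt,
        normality_ok=normal_p > 0.05,
        qtl_suitable=suitable,
        reason="" if suitable else "|skewness| or |kurtosis| >= 1",
    )


def compare_pools(values_t, values_s) -> PoolComparison:
    """Median/quartile summaries plus a two-sided rank-sum test.

    The Wilcoxon-Mann-Whitney test is preferred over a t test because the
    relative traits can be zero-inflated. With fewer than 3 values in either
    pool the test is skipped (summaries are still returned).
    """
    t = np.asarray(values_t, float)
    s = np.asarray(values_s, float)
    if len(t) == 0 or len(s) == 0:
        raise ValueError("both pools must be non-empty")
    q1t, medt, q3t = np.percentile(t, [25, 50, 75])
    q1s, meds, q3s = np.percentile(s, [25, 50, 75])
    tested = len(t) >= 3 and len(s) >= 3
    if tested:
        p = float(stats.mannwhitneyu(t, s, alternative="two-sided").pvalue)
    else:
        warnings.warn(
            "fewer than 3 values in a pool; rank-sum test skipped",
            UserWarning,
            stacklevel=2,
        )
        p = float("nan")
    if medt > meds:
        direction = "T>S"
    elif meds > medt:
        direction = "S>T"
    else:
        direction = "none"
    return PoolComparison(
        median_t=float(medt),
        median_s=float(meds),
        q1_t=float(q1t),
        q3_t=float(q3t),
        q1_s=float(q1s),
        q3_s=float(q3s),
        p_value=p,
        direction=direction,
        tested=tested,
    )


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read the long phenotype TSV (line_id, trait, control, treatment)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"line_id", "trait", "control_value", "treatment_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    unknown = set(df["trait"]) - set(TRAITS)
    if unknown:
        raise ValueError(f"unknown trait labels: {sorted(unknown)}")
    return df
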