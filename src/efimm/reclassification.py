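"""Paired comparison of frailty-index measurement variants.

Changing the data sources (VA-only vs VA+CMS) or the lookback window (1 vs 3
years) changes the measured index for the same patient.  This module
quantifies that measurement effect: the mean intra-individual change with a
paired t-test, the share of patients reclassified to a higher severity
category, the share whose score rises by at least a threshold (0.1 by
default — a large, clinically meaningful change for a frailty index), and
the stability of the Cox association when the exposure is recomputed under
each variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .frailty import FrailtyScore, classify_severity
from .survival import CoxResult, SurvivalRecord, cox_fit, encode_design, records_frame

__all__ = ["VariantComparison", "compare_fi_variants", "association_stability"]


@dataclass
class VariantComparison:
    """Paired A-vs-B summary; deltas are B − A on the same patient set."""

    label_a: str
    label_b: str
    n: int
    mean_delta: float
    ci: tuple[float, float]
    t_statistic: float | None
    p_value: float
    pct_reclassified_up: float
    pct_reclassified_down: float
    pct_same: float
    pct_delta_ge_threshold: float
    delta_threshold: float
    deltas: pd.Series = field(repr=False)
    all_zero: bool = False


def compare_fi_variants(
    scores_a: dict[str, FrailtyScore],
    scores_b: dict[str, FrailtyScore],
    delta_threshold: float = 0.1,
    label_a: str = "A",
    label_b: str = "B",
) -> VariantComparison:
    """Paired comparison of two per-patient score maps.

    Reclassification is counted on the five-level severity scale derived from
    each score.  The t-test is two-sided against a zero mean change; a
    degenerate all-zero-delta comparison reports p = 1 with ``all_zero`` set
    rather than failing.
    """
    ids_a, ids_b = set(scores_a), set(scores_b)
    if ids_a != ids_b:
        raise ValueError(
            f"patient sets differ; only in A: {sorted(ids_a - ids_b)[:10]}, "
            f"only in B: {sorted(ids_b - ids_a)[:10]}"
        )
    ids = sorted(ids_a)
    if not ids:
        raise ValueError("empty patient set")
    a = np.array([scores_a[i].score for i in ids])
    b = np.array([scores_b[i].score for i in ids])
    deltas = b - a
    n = len(ids)

    cat_a = np.array([int(classify_severity(x)) for x in a])
    cat_b = np.array([int(classify_severity(x)) for x in b])
    up = float(np.mean(cat_b > cat_a) * 100)
    down = float(np.mean(cat_b < cat_a) * 100)
    same = float(np.mean(cat_b == cat_a) * 100)

    mean_delta = float(deltas.mean())
    sd = float(deltas.std(ddof=1)) if n > 1 else 0.0
    all_zero = bool(np.all(deltas == 0))
    if n > 1 and sd > 0:
        t_stat, p = stats.ttest_1samp(deltas, 0.0)
        t_stat, p = float(t_stat), float(p)
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        ci = (mean_delta - half, mean_delta + half)
    else:
        # zero-variance (e.g. identical vectors): t undefined
        t_stat, p = None, 1.0
        ci = (mean_delta, mean_delta)

    return VariantComparison(
        label_a=label_a,
        label_b=label_b,
        n=n,
        mean_delta=mean_delta,
        ci=ci,
        t_statistic=t_stat,
        p_value=p,
        pct_reclassified_up=up,
        pct_reclassified_down=down,
        pct_same=same,
        pct_delta_ge_threshold=float(np.mean(deltas >= delta_threshold) * 100),
        delta_threshold=delta_threshold,
        deltas=pd.Series(deltas, index=ids, name="delta"),
        all_zero=all_zero,
    )


def association_stability(
    records_by_variant: dict[str, list[SurvivalRecord]],
    ties: str = "efron",
) -> pd.DataFrame:
    """Refit the category-only Cox model with the exposure recomputed under
    each measurement variant; aligned HR/CI table.

    A variant that collapses everyone into one category is skipped with the
    reason recorded in the table.
    """
    if len(records_by_variant) < 2:
        raise ValueError("need >= 2 variants")
    rows = []
    for variant, records in records_by_variant.items():
        cats = {r.category for r in records}
        if len(cats) < 2:
            rows.append(
                {
                    "variant": variant,
                    "covariate": None,
                    "hr": np.nan,
                    "ci_lower": np.nan,
                    "ci_upper": np.nan,
                    "status": "skipped: single category",
                }
            )
            continue
        frame = records_frame(records)
        design = encode_design(frame, ["category"])
        design["time"] = frame["time"]
        design["event"] = frame["event"]
        fit: CoxResult = cox_fit(
            design,
            [c for c in design.columns if c not in ("time", "event")],
            ties=ties,
        )
        for cov, row in fit.table.iterrows():
            rows.append(
                {
                    "variant": variant,
                    "covariate": cov,
                    "hr": row["hr"],
                    "ci_lower": row["ci_lower"],
                    "ci_upper": row["ci_upper"],
                    "status": "ok",
                }
            )
    return pd.DataFrame(rows)
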