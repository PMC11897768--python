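"""Between-condition statistics and tabular reporting.

Thin, convention-fixing wrappers over scipy.stats: Mann-Whitney U and
Kolmogorov-Smirnov comparisons between unit groups (two-sided throughout),
Pearson correlation for within-unit paired designs, and a report builder
that collects per-condition medians, filter counts and the comparison
table into stable CSV/JSON outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ComparisonResult", "compare_groups", "paired_correlation", "make_report"]


@dataclass(frozen=True)
class ComparisonResult:
    test: str  # mann_whitney_u | ks | pearson
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    medians: tuple[float, ...] | None = None
    r: float | None = None


def compare_groups(
    a: Sequence[float], b: Sequence[float], test: str = "mann_whitney_u"
) -> ComparisonResult:
    """Two-sided two-group comparison (Mann-Whitney U or KS).

    Uses scipy's exact/asymptotic switching by sample size; reports group
    medians alongside the U statistic, or the KS D statistic.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs n >= 3")
    if test == "mann_whitney_u":
        if np.unique(np.concatenate([x, y])).size == 1:
            warnings.warn("degenerate all-tied data; continuity-corrected U-test")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        return ComparisonResult(
            test=test,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n_per_group=(x.size, y.size),
            medians=(float(np.median(x)), float(np.median(y))),
        )
    if test == "ks":
        res = stats.ks_2samp(x, y, alternative="two-sided")
        return ComparisonResult(
            test=test,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n_per_group=(x.size, y.size),
            medians=(float(np.median(x)), float(np.median(y))),
        )
    raise ValueError(f"unknown test {test!r}")


def paired_correlation(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Pearson correlation of one quantity measured twice in the same units
    (e.g. photoreceptor-driven vs optogenetically driven conditions)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("paired vectors must align")
    if xv.size < 10:
        raise ValueError("paired correlation needs n >= 10")
    if xv.std() == 0 or yv.std() == 0:
        warnings.warn("zero variance in a paired vector; r undefined")
        return ComparisonResult(
            test="pearson",
            statistic=float("nan"),
            p_value=float("nan"),
            n_per_group=(xv.size,),
            r=None,
        )
    r, p = stats.pearsonr(xv, yv)
    return ComparisonResult(
        test="pearson",
        statistic=float(r),
        p_value=float(p),
        n_per_group=(xv.size,),
        r=float(r),
    )


# ---------------------------------------------------------------------------
# reporting

_METRIC_COLUMNS = [
    "amplitude",
    "qi",
    "latency_s",
    "bias_index",
    "transience_index",
    "mean_rate",
    "c50",
    "nr_slope",
    "peak_tf",
    "spread",
]


def make_report(
    metrics: pd.DataFrame,
    out_dir: str | Path | None = None,
    condition_col: str = "condition",
) -> dict:
    """Summary tables from a per-unit metrics frame.

    ``metrics`` carries one row per unit with a condition column and any
    subset of the metric columns (missing ones are skipped; an unexpected
    absence of the condition column is a schema error). Produces
    per-condition medians, inclusion counts at each filter, and the
    pairwise comparison table (U-test per metric). Output is
    deterministic: conditions and metrics are ordered, floats fixed to six
    significant digits.
    """
    if condition_col not in metrics.columns:
        raise KeyError(f"missing required column {condition_col!r}")
    conditions = sorted(metrics[condition_col].astype(str).unique())
    present = [c for c in _METRIC_COLUMNS if c in metrics.columns]

    medians: dict[str, dict[str, float | None]] = {}
    counts: dict[str, dict[str, int]] = {}
    for cond in conditions:
        sub = metrics[metrics[condition_col].astype(str) == cond]
        medians[cond] = {}
        counts[cond] = {"n_units": int(len(sub))}
        for col in present:
            vals = pd.to_numeric(sub[col], errors="coerce").dropna()
            counts[cond][f"n_{col}"] = int(len(vals))
            medians[cond][col] = (
                round(float(vals.median()), 6) if len(vals) else None
            )
        for flag in ("is_lr", "nr_included", "hg_included"):
            if flag in sub.columns:
                counts[cond][f"n_{flag}"] = int(sub[flag].fillna(False).astype(bool).sum())

    comparisons = []
    for i in range(len(conditions)):
        for j in range(i + 1, len(conditions)):
            ca, cb = conditions[i], conditions[j]
            for col in present:
                va = pd.to_numeric(
                    metrics.loc[metrics[condition_col].astype(str) == ca, col],
                    errors="coerce",
                ).dropna()
                vb = pd.to_numeric(
                    metrics.loc[metrics[condition_col].astype(str) == cb, col],
                    errors="coerce",
                ).dropna()
                if len(va) < 3 or len(vb) < 3:
                    continue
                res = compare_groups(va, vb, "mann_whitney_u")
                comparisons.append(
                    {
                        "metric": col,
                        "group_a": ca,
                        "group_b": cb,
                        "test": res.test,
                        "statistic": round(res.statistic, 6),
                        "p_value": round(res.p_value, 6),
                        "median_a": round(res.medians[0], 6),
                        "median_b": round(res.medians[1], 6),
                        "n_a": res.n_per_group[0],
                        "n_b": res.n_per_group[1],
                    }
                )

    report = {
        "conditions": conditions,
        "n_total_units": int(len(metrics)),
        "medians": medians,
        "counts": counts,
        "comparisons": comparisons,
        "n_tests_run": len(comparisons),  # no multiplicity correction applied
    }
    if not len(metrics):
        report["note"] = "zero analyzable units"

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        if comparisons:
            pd.DataFrame(comparisons).to_csv(out_dir / "comparisons.csv", index=False)
        pd.DataFrame(medians).to_csv(out_dir / "medians.csv")
    return report
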