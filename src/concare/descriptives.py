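"""Standardized differences and cohort comparison tables.

Group contrasts are reported as standardized differences rather than
p-values: a scale-free effect size for which values below 0.1 are
conventionally read as negligible imbalance.

* continuous: d = |m1 - m2| / sqrt((s1^2 + s2^2) / 2)
* binary:     d = |p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2)
* multi-category: Mahalanobis-type distance on the first L-1 category
  proportions using the averaged multinomial covariance (the
  Yang–Dalton construction), which reduces to the binary formula at
  L = 2.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .outcomes import BIN_LABELS, bin_series

logger = logging.getLogger(__name__)

#: Sentinel returned when the pooled variance is zero but means differ.
INFINITE_DIFFERENCE = float("inf")


def std_diff_continuous(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled = np.sqrt((sd1**2 + sd2**2) / 2.0)
    diff = abs(mean1 - mean2)
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        logger.warning("zero pooled SD with differing means: infinite standardized difference")
        return INFINITE_DIFFERENCE
    return diff / pooled


def std_diff_binary(p1: float, p2: float) -> float:
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    pooled = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    diff = abs(p1 - p2)
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        logger.warning("degenerate proportions with differing values: infinite standardized difference")
        return INFINITE_DIFFERENCE
    return diff / pooled


def std_diff_categorical(props1, props2) -> float:
    """Yang–Dalton multi-category standardized difference.

    ``props1``/``props2`` are proportion vectors of equal length L >= 2,
    each summing to 1 (tolerance 1e-9). Uses the first L-1 categories
    and the averaged multinomial covariance; a pseudo-inverse handles
    the degenerate (structurally empty category) case.
    """
    p1 = np.asarray(props1, dtype=float)
    p2 = np.asarray(props2, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 1 or p1.size < 2:
        raise ValueError("proportion vectors must be 1-D, equal length >= 2")
    for name, p in (("props1", p1), ("props2", p2)):
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1")
        if (p < 0).any():
            raise ValueError(f"{name} has negative entries")
    t = (p1 - p2)[:-1]
    a, b = p1[:-1], p2[:-1]
    cov = (np.diag(a) - np.outer(a, a) + np.diag(b) - np.outer(b, b)) / 2.0
    if np.allclose(t, 0.0):
        return 0.0
    try:
        sol = np.linalg.solve(cov, t)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(cov) @ t
    return float(np.sqrt(t @ sol))


# ---------------------------------------------------------------------------
# comparison tables
# ---------------------------------------------------------------------------

#: (column, kind) pairs rendered by default, mirroring the utilization
#: comparison tables: binned counts with a categorical d, means with a
#: continuous d, and binary outcome rows.
DEFAULT_VARIABLES = [
    ("n_admissions_all", "count"),
    ("n_admissions_copd", "count"),
    ("died_in_hospital", "binary"),
    ("any_readmission_30d", "binary"),
    ("n_ed_all", "count"),
    ("n_ed_copd", "count"),
    ("n_ed_with_admission", "count"),
    ("age_at_index", "continuous"),
]


def build_comparison_table(
    profiles: pd.DataFrame,
    outcomes: pd.DataFrame,
    persons: pd.DataFrame,
    grouping: str = "coci_category",
    variables=None,
) -> pd.DataFrame:
    """Two-group comparison table with standardized differences.

    ``grouping`` is ``coci_category`` (low vs high; not_assessed rows
    are dropped) or ``predominant_group`` (FP vs SP). Count variables
    are additionally summarized as a mean +/- SD row. Percentages are
    reported to 1 decimal; raw counts are always retained.
    """
    variables = variables if variables is not None else DEFAULT_VARIABLES
    data = profiles.merge(outcomes, on="patient_id").merge(
        persons, on="patient_id", how="left"
    )
    if grouping == "coci_category":
        data = data[data["coci_category"].isin(["low", "high"])]
        g1, g2 = "low", "high"
    elif grouping == "predominant_group":
        g1, g2 = "FP", "SP"
    else:
        raise ValueError(f"unknown grouping '{grouping}'")
    group = data[grouping]
    d1 = data[group == g1]
    d2 = data[group == g2]
    for label, frame in ((g1, d1), (g2, d2)):
        if frame.empty:
            raise ValueError(f"comparison group '{label}' is empty")

    rows = []
    for column, kind in variables:
        if column not in data.columns:
            continue
        if kind == "count":
            b1 = bin_series(d1[column]).value_counts().reindex(list(BIN_LABELS), fill_value=0)
            b2 = bin_series(d2[column]).value_counts().reindex(list(BIN_LABELS), fill_value=0)
            p1 = (b1 / b1.sum()).to_numpy()
            p2 = (b2 / b2.sum()).to_numpy()
            d = std_diff_categorical(p1, p2)
            for level in BIN_LABELS:
                rows.append(
                    {
                        "variable": column,
                        "level": level,
                        f"{g1}_count": int(b1[level]),
                        f"{g1}_pct": round(100.0 * b1[level] / b1.sum(), 1),
                        f"{g2}_count": int(b2[level]),
                        f"{g2}_pct": round(100.0 * b2[level] / b2.sum(), 1),
                        "std_diff": d,
                    }
                )
            rows.append(
                {
                    "variable": f"mean_{column}",
                    "level": "mean ± SD",
                    f"{g1}_mean": d1[column].mean(),
                    f"{g1}_sd": d1[column].std(ddof=1),
                    f"{g2}_mean": d2[column].mean(),
                    f"{g2}_sd": d2[column].std(ddof=1),
                    "std_diff": std_diff_continuous(
                        d1[column].mean(), d1[column].std(ddof=1),
                        d2[column].mean(), d2[column].std(ddof=1),
                    ),
                }
            )
        elif kind == "binary":
            p1v = float(d1[column].astype(bool).mean())
            p2v = float(d2[column].astype(bool).mean())
            rows.append(
                {
                    "variable": column,
                    "level": "yes",
                    f"{g1}_count": int(d1[column].astype(bool).sum()),
                    f"{g1}_pct": round(100.0 * p1v, 1),
                    f"{g2}_count": int(d2[column].astype(bool).sum()),
                    f"{g2}_pct": round(100.0 * p2v, 1),
                    "std_diff": std_diff_binary(p1v, p2v),
                }
            )
        elif kind == "continuous":
            rows.append(
                {
                    "variable": column,
                    "level": "mean ± SD",
                    f"{g1}_mean": d1[column].mean(),
                    f"{g1}_sd": d1[column].std(ddof=1),
                    f"{g2}_mean": d2[column].mean(),
                    f"{g2}_sd": d2[column].std(ddof=1),
                    "std_diff": std_diff_continuous(
                        d1[column].mean(), d1[column].std(ddof=1),
                        d2[column].mean(), d2[column].std(ddof=1),
                    ),
                }
            )
        else:
            raise ValueError(f"unknown variable kind '{kind}'")
    table = pd.DataFrame(rows)
    table.attrs["group_sizes"] = {g1: len(d1), g2: len(d2)}
    return table


def render_markdown(table: pd.DataFrame, float_fmt: str = "{:.2f}") -> str:
    """Plain Markdown rendering of a comparison table."""
    show = table.copy()
    for col in show.columns:
        if show[col].dtype.kind == "f":
            integral = show[col].dropna().mod(1).eq(0).all() and not col.endswith("pct")
            fmt = "{:.0f}" if integral and "std" not in col else float_fmt
            show[col] = show[col].map(
                lambda v, fmt=fmt: "" if pd.isna(v) else fmt.format(v)
            )
        else:
            show[col] = show[col].map(lambda v: "" if pd.isna(v) else str(v))
    header = "| " + " | ".join(show.columns) + " |"
    rule = "| " + " | ".join("---" for _ in show.columns) + " |"
    lines = ["| " + " | ".join(row) + " |" for row in show.to_numpy(dtype=object)]
    return "\n".join([header, rule, *lines])
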