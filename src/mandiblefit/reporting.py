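"""Cohort fit-rate summaries.

Aggregates per-test fit results into the study's summary table: one
percentage cell per plate type x size, a pooled "Total" per plate type,
subgroup breakdowns (side, sex, population group) and the pooled overall
fit rate.  Cell and total percentages are rounded half-up to integers; the
overall rate is reported to one decimal.  Every summary is exactly
recomputable from the raw per-test table — there is no hidden state.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortFitSummary",
    "round_half_up",
    "summarize",
    "summary_from_counts",
    "pooled_overall",
    "subgroup_compare",
    "table1_text",
]

_TYPE_ORDER = ["condyle", "body", "angle", "symphysis"]
_SIZE_ORDER = ["L", "M", "S"]
#: table row labels; the angle plate is printed as the "Ramus plate" row
_ROW_LABELS = {
    "condyle": "Condyle plate",
    "body": "Body plate",
    "angle": "Ramus plate",
    "symphysis": "Symphysis plate",
}


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortFitSummary:
    """Aggregated fit percentages.

    ``cells``: DataFrame (type, size, n_tests, n_fit, percent);
    ``type_totals``: type -> pooled integer percent;
    ``overall``: pooled percent over all tests, 1 decimal;
    ``subgroups``: factor -> per-level DataFrame.
    """

    cells: pd.DataFrame
    type_totals: dict
    overall: float
    n_tests: int
    n_fit: int
    subgroups: dict


def _counts_frame(df: pd.DataFrame) -> pd.DataFrame:
    g = (
        df.groupby(["type", "size"], sort=False)
        .agg(n_tests=("fit", "size"), n_fit=("fit", "sum"))
        .reset_index()
    )
    g["n_fit"] = g["n_fit"].astype(int)
    g["percent"] = [
        round_half_up(100.0 * f / n) for f, n in zip(g["n_fit"], g["n_tests"])
    ]
    key = {t: i for i, t in enumerate(_TYPE_ORDER)}
    skey = {s: i for i, s in enumerate(_SIZE_ORDER)}
    g = g.sort_values(
        ["type", "size"],
        key=lambda col: col.map(key if col.name == "type" else skey),
    ).reset_index(drop=True)
    return g


def summarize(results, metadata: pd.DataFrame = None) -> CohortFitSummary:
    """Build the full summary from FitResults or a per-test DataFrame."""
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        from .plate_fit import results_to_frame

        df = results_to_frame(results, metadata)
    if df.empty:
        raise ValueError("no fit results to summarise")
    cells = _counts_frame(df)
    type_totals = {}
    for ptype, sub in cells.groupby("type", sort=False):
        type_totals[ptype] = round_half_up(100.0 * sub["n_fit"].sum() / sub["n_tests"].sum())
    n_tests = int(cells["n_tests"].sum())
    n_fit = int(cells["n_fit"].sum())
    overall = round_half_up(100.0 * n_fit / n_tests, 1)
    subgroups = {}
    for factor in ("side", "sex", "group"):
        if factor in df.columns and df[factor].nunique() >= 2:
            subgroups[factor] = (
                df.groupby(factor)
                .agg(n_tests=("fit", "size"), n_fit=("fit", "sum"))
                .assign(
                    percent=lambda s: [
                        round_half_up(100.0 * f / n)
                        for f, n in zip(s["n_fit"], s["n_tests"])
                    ]
                )
                .reset_index()
            )
    return CohortFitSummary(cells, type_totals, overall, n_tests, n_fit, subgroups)


def summary_from_counts(counts: dict) -> CohortFitSummary:
    """Summary directly from ``{(type, size): (n_fit, n_tests)}`` counts
    (used when only aggregated results are available)."""
    rows = []
    for (ptype, size), (n_fit, n_tests) in counts.items():
        rows += [{"type": ptype, "size": size, "fit": i < n_fit} for i in range(n_tests)]
    return summarize(pd.DataFrame(rows))


def pooled_overall(counts: dict) -> float:
    """Pooled percent over per-cell ``(n_fit, n_tests)`` counts, 1 decimal."""
    n_fit = sum(v[0] for v in counts.values())
    n_tests = sum(v[1] for v in counts.values())
    if n_tests == 0:
        raise ValueError("zero tests")
    return round_half_up(100.0 * n_fit / n_tests, 1)


def subgroup_compare(df: pd.DataFrame, factor: str):
    """Fit percentages per level of ``factor`` plus Fisher's exact p-value
    for a difference between two levels (the study design has two levels
    for every factor: left/right, M/F, European/Asian)."""
    if factor == "side":
        # the side comparison is left vs right; midline symphysis tests
        # have no laterality and are excluded
        df = df[df[factor].isin(["left", "right"])]
    levels = sorted(df[factor].dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    table = []
    rows = []
    for lev in levels:
        sub = df[df[factor] == lev]
        n_fit = int(sub["fit"].sum())
        n = len(sub)
        table.append([n_fit, n - n_fit])
        rows.append(
            {
                factor: lev,
                "n_tests": n,
                "n_fit": n_fit,
                "percent": round_half_up(100.0 * n_fit / n),
            }
        )
    arr = np.array(table)
    if (arr.sum(axis=0) == 0).any():
        # all tests fit (or none did) in every level: no evidence of a
        # difference between levels
        p = 1.0
    elif len(levels) == 2:
        _, p = stats.fisher_exact(arr)
    else:
        _, p, _, _ = stats.chi2_contingency(arr)
    return pd.DataFrame(rows), float(p)


def table1_text(summary: CohortFitSummary) -> str:
    """Human-readable text table (rows: plate types; columns: L, M, S,
    Total) mirroring the study's summary layout."""
    lines = [f"{'':<18}{'Size L':>8}{'Size M':>8}{'Size S':>8}{'Total':>8}"]
    cells = summary.cells.set_index(["type", "size"])["percent"]
    for ptype in _TYPE_ORDER:
        if ptype not in summary.type_totals:
            continue
        vals = []
        for size in _SIZE_ORDER:
            if (ptype, size) in cells.index:
                vals.append(f"{int(cells.loc[(ptype, size)]):>8}")
            else:
                vals.append(f"{'-':>8}")
        lines.append(
            f"{_ROW_LABELS.get(ptype, ptype):<18}"
            + "".join(vals)
            + f"{int(summary.type_totals[ptype]):>8}"
        )
    lines.append(f"\nOverall fit: {summary.overall}% ({summary.n_fit}/{summary.n_tests} tests)")
    return "\n".join(lines)
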