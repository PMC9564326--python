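"""Assembly of binding free energies, percent contributions and
complex-vs-complex statistical comparisons.

The binding free energy is assembled additively,

    dG_binding = dG_MM/GBSA + (-T dS),

with run-to-run SDs propagated in quadrature. Per-group percentages are
group/total x 100 rounded half-away-from-zero to integers; contributions
rounding below 1% are rendered "<1%". Two complexes are compared with a
pooled-variance two-sample t test on their per-run values (or summary
statistics), df = n_A + n_B - 2, two-tailed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AssemblyError, EmptyInputError, ParameterError

__all__ = [
    "BindingReport",
    "ComparisonReport",
    "assemble_binding",
    "percent_contributions",
    "mean_over_runs",
    "compare_complexes",
    "compare_complexes_from_stats",
]


@dataclass
class BindingReport:
    """Assembled binding free energy for one complex (kcal/mol)."""

    label: str
    dg_mmgbsa: float
    dg_mmgbsa_sd: float
    minus_t_ds: float
    minus_t_ds_sd: float
    dg_binding: float
    dg_binding_sd: float
    per_group: Optional[pd.DataFrame] = None


@dataclass
class ComparisonReport:
    label_a: str
    label_b: str
    ddg: float           # dG_A - dG_B
    t_statistic: float
    df: int
    p_value: float


def assemble_binding(
    dg_mmgbsa: float,
    minus_t_ds: float,
    dg_sd: float = 0.0,
    ds_sd: float = 0.0,
    label: str = "",
    per_group: Optional[pd.DataFrame] = None,
) -> BindingReport:
    """dG_binding = dG_MM/GBSA + (-T dS); SDs combined in quadrature."""
    if not (np.isfinite(dg_mmgbsa) and np.isfinite(minus_t_ds)):
        raise AssemblyError("non-finite energy component")
    return BindingReport(
        label=label,
        dg_mmgbsa=float(dg_mmgbsa),
        dg_mmgbsa_sd=float(dg_sd),
        minus_t_ds=float(minus_t_ds),
        minus_t_ds_sd=float(ds_sd),
        dg_binding=float(dg_mmgbsa + minus_t_ds),
        dg_binding_sd=float(math.hypot(dg_sd, ds_sd)),
        per_group=per_group,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def percent_contributions(table: pd.DataFrame, total: Optional[float] = None) -> pd.DataFrame:
    """Add integer percent-of-total columns to a per-group energy table.

    Requires columns ``group`` and ``energy``. ``percent`` holds the signed
    integer; ``percent_label`` renders contributions rounding below 1% as
    "<1%".
    """
    if total is None:
        total = float(table["energy"].sum())
    if total == 0:
        raise ParameterError("zero total energy; percentages undefined")
    out = table.copy()
    pct = 100.0 * out["energy"] / total
    out["percent"] = [_round_half_away(p) for p in pct]
    out["percent_label"] = [
        "<1%" if abs(p) < 1 else f"{p}%" for p in out["percent"]
    ]
    return out


def mean_over_runs(values: Sequence[float]) -> Tuple[float, Optional[float]]:
    """(mean, sample SD) over per-run values; SD is None for n = 1."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise EmptyInputError("no per-run values")
    sd = float(v.std(ddof=1)) if v.size > 1 else None
    return float(v.mean()), sd


def compare_complexes(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "A",
    label_b: str = "B",
    pooled: bool = True,
) -> ComparisonReport:
    """Two-sample t test on per-run values (pooled variance by default,
    Welch optionally)."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise EmptyInputError("need at least 2 replicates per complex")
    if np.allclose(a, b):
        t, df, p = 0.0, a.size + b.size - 2, 1.0
    else:
        res = stats.ttest_ind(a, b, equal_var=pooled)
        t, p = float(res.statistic), float(res.pvalue)
        df = a.size + b.size - 2 if pooled else float(res.df)
    return ComparisonReport(
        label_a=label_a, label_b=label_b,
        ddg=float(a.mean() - b.mean()),
        t_statistic=t, df=df, p_value=p,
    )


def compare_complexes_from_stats(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    label_a: str = "A",
    label_b: str = "B",
    pooled: bool = True,
) -> ComparisonReport:
    """Summary-statistics entry mode for the two-sample t test."""
    if n_a < 2 or n_b < 2:
        raise EmptyInputError("need at least 2 replicates per complex")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=pooled
    )
    df = n_a + n_b - 2 if pooled else None
    return ComparisonReport(
        label_a=label_a, label_b=label_b,
        ddg=float(mean_a - mean_b),
        t_statistic=float(res.statistic),
        df=df if df is not None else float("nan"),
        p_value=float(res.pvalue),
    )
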