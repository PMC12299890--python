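"""Descriptive group statistics: mean, SEM and Student-t confidence intervals.

Group rows in small-animal PK reports carry mean ± SEM with a symmetric
95% CI computed as mean ± t(1-alpha/2, n-1) * SEM — the t-quantile, not the
normal one, matters at n = 3. CI bounds are reported as computed, even when
a bound goes negative for a nonnegative quantity: fidelity to the
underlying interval over cosmetic truncation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nca import NCAResult

logger = logging.getLogger(__name__)

#: report order of the per-subject parameters summarised per group
PARAMETER_ORDER = (
    "cmax_mg_per_L",
    "tmax_h",
    "auclast_mg_h_per_L",
    "vd_L",
    "cl_L_per_h",
    "k_per_h",
    "t_half_h",
    "mrt_h",
)


@dataclass(frozen=True)
class SummaryStats:
    """n, mean, SEM and a symmetric confidence interval for one parameter."""

    n: int
    mean: float
    sem: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95


def summarize(values: Sequence[float], confidence: float = 0.95) -> SummaryStats:
    """Mean, SEM (n-1 denominator) and Student-t CI of a sample.

    A single value yields a mean-only result (SEM and CI are NaN).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty sample")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    mean = float(arr.mean())
    if arr.size == 1:
        logger.warning("sample of size 1: reporting mean only")
        return SummaryStats(1, mean, float("nan"), float("nan"), float("nan"), confidence)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
    t_crit = float(stats.t.ppf(0.5 + confidence / 2.0, arr.size - 1))
    half = t_crit * sem
    return SummaryStats(int(arr.size), mean, sem, mean - half, mean + half, confidence)


def summarize_table(
    results: Sequence[NCAResult],
    grouping: Mapping[str, Sequence[str]],
    confidence: float = 0.95,
) -> pd.DataFrame:
    """One summary row per (group, parameter), in report column order.

    ``grouping`` maps a group label (e.g. "rats 1-3") to the subject ids it
    contains; every group must be nonempty. Incomplete results contribute
    their defined parameters only (NaN cells are dropped per parameter).
    """
    by_id = {r.subject_id: r for r in results}
    rows = []
    for label, ids in grouping.items():
        members = [by_id[i] for i in ids if i in by_id]
        if not members:
            raise ValueError(f"group {label!r} matches no results")
        for param in PARAMETER_ORDER:
            vals = [getattr(r, param) for r in members]
            vals = [v for v in vals if math.isfinite(v)]
            if not vals:
                continue
            s = summarize(vals, confidence)
            rows.append(
                {
                    "group": label,
                    "parameter": param,
                    "n": s.n,
                    "mean": s.mean,
                    "sem": s.sem,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                }
            )
    return pd.DataFrame(rows, columns=["group", "parameter", "n", "mean", "sem", "ci_low", "ci_high"])
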