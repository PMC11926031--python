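"""Method-comparison statistics and the evaluation harness.

Counting methods are compared the way method studies in quantitative
microscopy do it: squared Pearson correlation (R^2) between a method's
counts and the reference counts, two-sided paired t-tests on the absolute
counts, and per-sample overcounting ratios

    ratio = method count / reference count

whose mean +/- SD summarizes systematic bias.  A 0/0 ratio is undefined
and excluded; a k/0 ratio (k > 0, false positives on an empty reference)
is also undefined but flagged separately because it is scientifically
different.  Ground-truth counts from the synthetic generator stand in for
the error-free analog of manual "gold standard" counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ParameterError, UndefinedStatisticError
from .synth import NoisePanelEntry, SyntheticScene

__all__ = [
    "r_squared",
    "paired_t_test",
    "PairedTResult",
    "overcount_ratios",
    "OvercountResult",
    "evaluate_methods",
    "noise_comparison",
]

logger = logging.getLogger(__name__)


def r_squared(x, y) -> float:
    """Squared Pearson correlation between two count vectors.

    Raises :class:`UndefinedStatisticError` (never a silent 0) when either
    vector has zero variance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1D vectors of equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 samples for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for zero-variance input")
    r = sps.pearsonr(x, y).statistic
    return float(r * r)


@dataclass
class PairedTResult:
    """Two-sided paired t-test: statistic, p-value, degrees of freedom."""

    t: float
    p: float
    df: int


def paired_t_test(x, y) -> PairedTResult:
    """Two-sided paired t-test on the differences d = x - y.

    t = mean(d) / (sd(d) / sqrt(n)) with n - 1 degrees of freedom.
    Degenerate inputs signal explicitly: identical vectors (zero mean,
    zero SD of differences) raise :class:`UndefinedStatisticError`; a
    constant nonzero difference yields t = +/-inf with p = 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1D vectors of equal length")
    n = x.size
    if n < 2:
        raise ParameterError("need at least 2 pairs")
    d = x - y
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        if mean == 0.0:
            raise UndefinedStatisticError(
                "paired t undefined: differences identically zero"
            )
        return PairedTResult(t=math.copysign(math.inf, mean), p=0.0, df=n - 1)
    res = sps.ttest_rel(x, y)
    return PairedTResult(t=float(res.statistic), p=float(res.pvalue), df=n - 1)


@dataclass
class OvercountResult:
    """Per-sample overcounting ratios and their summary.

    ``ratios`` carries NaN where the ratio is undefined; 0/0 cases are
    counted in ``n_undefined`` and k/0 (k > 0) in ``n_infinite``; both are
    excluded from ``mean``/``sd`` (sample SD, NaN when fewer than two
    defined ratios).
    """

    ratios: np.ndarray
    mean: float
    sd: float
    n_undefined: int
    n_infinite: int


def overcount_ratios(method, manual) -> OvercountResult:
    """Per-sample [method count] / [reference count] ratios."""
    method = np.asarray(method, dtype=np.float64)
    manual = np.asarray(manual, dtype=np.float64)
    if method.shape != manual.shape or method.ndim != 1:
        raise ParameterError("count vectors must be 1D and of equal length")
    ratios = np.full(method.shape, np.nan)
    defined = manual != 0
    ratios[defined] = method[defined] / manual[defined]
    zero_zero = (~defined) & (method == 0)
    k_zero = (~defined) & (method != 0)
    vals = ratios[defined]
    mean = float(vals.mean()) if vals.size else float("nan")
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else float("nan")
    return OvercountResult(
        ratios=ratios,
        mean=mean,
        sd=sd,
        n_undefined=int(zero_zero.sum()),
        n_infinite=int(k_zero.sum()),
    )


CountingMethod = Callable[[SyntheticScene], int]


def _run_method(fn: CountingMethod, scene: SyntheticScene) -> float:
    try:
        return float(fn(scene))
    except Exception as exc:  # noqa: BLE001 - harness must not crash on one scene
        logger.warning("method failed on scene (seed %s): %s", scene.spec.seed, exc)
        return float("nan")


def evaluate_methods(
    scenes: Sequence[SyntheticScene],
    methods: Mapping[str, CountingMethod],
    group_labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Compare counting methods against ground truth over a scene panel.

    Each method is a callable scene -> colocalized count.  The report has
    one row per method (and per group when ``group_labels`` is given) with
    R^2, the paired-t statistic/p-value, and the overcounting-ratio
    summary.  Failures on single scenes are logged and recorded as
    missing, never raised.  An empty method mapping yields an empty report.
    """
    if not len(scenes):
        raise ParameterError("scene panel must be non-empty")
    if group_labels is not None and len(group_labels) != len(scenes):
        raise ParameterError("one group label per scene required")
    truth = np.array([s.n_coloc_truth for s in scenes], dtype=np.float64)
    labels = np.asarray(group_labels if group_labels is not None else ["all"] * len(scenes))
    rows: List[dict] = []
    for name, fn in methods.items():
        counts = np.array([_run_method(fn, s) for s in scenes])
        for grp in pd.unique(labels):
            sel = (labels == grp) & ~np.isnan(counts)
            t_cnt, m_cnt = truth[sel], counts[sel]
            row = {
                "method": name,
                "group": grp,
                "n": int(sel.sum()),
                "n_failed": int(((labels == grp) & np.isnan(counts)).sum()),
            }
            try:
                row["r2"] = r_squared(t_cnt, m_cnt)
            except (ParameterError, UndefinedStatisticError):
                row["r2"] = float("nan")
            try:
                tt = paired_t_test(m_cnt, t_cnt)
                row["t"], row["p"] = tt.t, tt.p
            except (ParameterError, UndefinedStatisticError):
                row["t"], row["p"] = float("nan"), float("nan")
            oc = overcount_ratios(m_cnt, t_cnt)
            row.update(
                mean_ratio=oc.mean,
                sd_ratio=oc.sd,
                n_undefined=oc.n_undefined,
                n_infinite=oc.n_infinite,
            )
            rows.append(row)
    columns = [
        "method", "group", "n", "n_failed", "r2", "t", "p",
        "mean_ratio", "sd_ratio", "n_undefined", "n_infinite",
    ]
    return pd.DataFrame(rows, columns=columns)


def noise_comparison(
    panel: Sequence[NoisePanelEntry],
    methods: Mapping[str, CountingMethod],
) -> pd.DataFrame:
    """Clean-vs-noisy paired comparison over a degraded-image panel.

    For each method and morphology: mean +/- SD of counts on clean and
    noisy variants, the paired t-test between them, and the mean signed
    deviation (noisy - clean) showing the direction of the noise effect.
    """
    rows: List[dict] = []
    morphologies = sorted({e.morphology for e in panel})
    for name, fn in methods.items():
        for morph in morphologies:
            entries = [e for e in panel if e.morphology == morph]
            clean = np.array([_run_method(fn, e.clean) for e in entries])
            noisy = np.array([_run_method(fn, e.noisy) for e in entries])
            ok = ~np.isnan(clean) & ~np.isnan(noisy)
            clean, noisy = clean[ok], noisy[ok]
            row = {
                "method": name,
                "morphology": morph,
                "n": int(ok.sum()),
                "mean_clean": float(clean.mean()) if clean.size else float("nan"),
                "sd_clean": float(clean.std(ddof=1)) if clean.size >= 2 else float("nan"),
                "mean_noisy": float(noisy.mean()) if noisy.size else float("nan"),
                "sd_noisy": float(noisy.std(ddof=1)) if noisy.size >= 2 else float("nan"),
                "mean_deviation": float((noisy - clean).mean()) if clean.size else float("nan"),
            }
            try:
                tt = paired_t_test(noisy, clean)
                row["t"], row["p"] = tt.t, tt.p
            except (ParameterError, UndefinedStatisticError):
                row["t"], row["p"] = float("nan"), float("nan")
            rows.append(row)
    columns = [
        "method", "morphology", "n", "mean_clean", "sd_clean",
        "mean_noisy", "sd_noisy", "mean_deviation", "t", "p",
    ]
    return pd.DataFrame(rows, columns=columns)
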