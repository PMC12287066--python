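"""AUC-window quantification and normality-gated paired comparisons.

Around each event onset two windows are integrated on the Z-score trace:
"before" (default -0.6 to -0.3 s) and "during" (default 0 to +0.3 s). The
0.3 s window length corresponds to the duration of one sniff. Before/during
pairs are then compared per unit (animal or event) with a paired t-test when
the Shapiro-Wilk test does not reject normality of the differences, and a
paired Wilcoxon signed-rank test otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .events import AlignedEnsemble

__all__ = [
    "AUCWindows",
    "PairedComparison",
    "auc",
    "before_during",
    "before_during_from_ensembles",
    "paired_test",
]

SIDEDNESS = ("two-sided", "greater", "less")


@dataclass
class AUCWindows:
    """Analysis windows in seconds relative to event onset."""

    before: tuple[float, float] = (-0.6, -0.3)
    during: tuple[float, float] = (0.0, 0.3)

    def __post_init__(self) -> None:
        ta, tb = self.before
        tc, td = self.during
        if not (ta < tb <= 0.0 <= tc < td):
            raise ParameterError(
                f"windows must satisfy t_a < t_b <= 0 <= t_c < t_d, got {self.before}, {self.during}"
            )


@dataclass
class PairedComparison:
    """Result of a normality-gated paired comparison.

    ``test_used`` is "paired t" iff ``normality_p >= alpha_normality``;
    ``degenerate`` flags zero-variance differences (all-zero differences are
    reported with p = 1).
    """

    values_before: np.ndarray
    values_during: np.ndarray
    normality_p: float
    test_used: str
    sidedness: str
    statistic: float
    p_value: float
    alpha_normality: float = 0.05
    degenerate: bool = False

    @property
    def n(self) -> int:
        return int(self.values_before.size)


def auc(rel_time: np.ndarray, trace: np.ndarray, window: Sequence[float]) -> float:
    """Trapezoidal integral of a trace over a closed window (z·s).

    Window endpoints falling between samples are linearly interpolated, so the
    integral is exact for piecewise-linear traces and additive over adjacent
    windows regardless of the sample grid.
    """
    rel_time = np.asarray(rel_time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if rel_time.shape != trace.shape:
        raise ParameterError("rel_time and trace must have equal length")
    t0, t1 = float(window[0]), float(window[1])
    if t0 >= t1:
        raise ParameterError(f"window start must be < end, got [{t0}, {t1}]")
    if t0 < rel_time[0] - 1e-12 or t1 > rel_time[-1] + 1e-12:
        raise ParameterError(
            f"window [{t0}, {t1}] outside trace span [{rel_time[0]}, {rel_time[-1]}]"
        )
    inside = (rel_time > t0) & (rel_time < t1)
    ts = np.concatenate(([t0], rel_time[inside], [t1]))
    vs = np.concatenate(
        ([np.interp(t0, rel_time, trace)], trace[inside], [np.interp(t1, rel_time, trace)])
    )
    return float(np.trapezoid(vs, ts))


def before_during(
    units: Mapping[str, tuple[np.ndarray, np.ndarray]],
    windows: AUCWindows | None = None,
) -> tuple[pd.DataFrame, int]:
    """Per-unit before/during AUC table.

    ``units`` maps a unit id (animal or event) to its (rel_time, trace) pair;
    both AUCs are computed on the same trace. Units whose trace does not cover
    both windows are excluded and counted in the second return value.
    """
    windows = windows or AUCWindows()
    rows, excluded = [], 0
    for unit, (rel_time, trace) in units.items():
        rel_time = np.asarray(rel_time, dtype=float)
        if rel_time[0] > windows.before[0] + 1e-12 or rel_time[-1] < windows.during[1] - 1e-12:
            excluded += 1
            continue
        rows.append(
            {
                "unit": unit,
                "auc_before": auc(rel_time, trace, windows.before),
                "auc_during": auc(rel_time, trace, windows.during),
            }
        )
    return pd.DataFrame(rows, columns=["unit", "auc_before", "auc_during"]), excluded


def before_during_from_ensembles(
    ensembles: Mapping[str, AlignedEnsemble],
    windows: AUCWindows | None = None,
    unit: str = "animal",
) -> tuple[pd.DataFrame, int]:
    """Before/during table from aligned ensembles.

    unit="animal": one row per ensemble, AUC on its mean trace.
    unit="event": one row per event, AUC on each row.
    """
    if unit == "animal":
        traces = {uid: (e.rel_time, e.mean) for uid, e in ensembles.items()}
    elif unit == "event":
        traces = {
            f"{uid}/{sid}:{idx}": (e.rel_time, e.matrix[i])
            for uid, e in ensembles.items()
            for i, (sid, idx) in enumerate(e.event_ids)
        }
    else:
        raise ParameterError(f"unit must be 'animal' or 'event', got {unit!r}")
    return before_during(traces, windows)


def paired_test(
    pairs: pd.DataFrame,
    sidedness: str,
    alpha_normality: float = 0.05,
) -> PairedComparison:
    """Normality-gated paired comparison of auc_during vs auc_before.

    ``sidedness`` is the alternative on (during - before): "two-sided",
    "greater" or "less" — it must be stated by the caller, no default is
    applied. Shapiro-Wilk on the paired differences decides between the paired
    t-test (normality not rejected at ``alpha_normality``) and the paired
    Wilcoxon signed-rank test.
    """
    if sidedness not in SIDEDNESS:
        raise ParameterError(f"sidedness must be one of {SIDEDNESS}, got {sidedness!r}")
    before = np.asarray(pairs["auc_before"], dtype=float)
    during = np.asarray(pairs["auc_during"], dtype=float)
    if before.size != during.size:
        raise ParameterError("before/during columns differ in length")
    if before.size < 3:
        raise ParameterError(f"paired test needs >= 3 pairs, got {before.size}")
    diffs = during - before

    if np.ptp(diffs) == 0.0:
        shift = float(diffs[0])
        if shift == 0.0:
            return PairedComparison(before, during, normality_p=1.0, test_used="paired t",
                                    sidedness=sidedness, statistic=0.0, p_value=1.0,
                                    alpha_normality=alpha_normality, degenerate=True)
        # Constant non-zero shift: the paired-t limit (sd -> 0, |t| -> inf).
        stat = np.inf if shift > 0 else -np.inf
        if sidedness == "two-sided":
            p = 0.0
        elif sidedness == "greater":
            p = 0.0 if shift > 0 else 1.0
        else:
            p = 0.0 if shift < 0 else 1.0
        return PairedComparison(before, during, normality_p=1.0, test_used="paired t",
                                sidedness=sidedness, statistic=float(stat), p_value=p,
                                alpha_normality=alpha_normality, degenerate=True)

    normality_p = float(stats.shapiro(diffs).pvalue)
    if normality_p >= alpha_normality:
        res = stats.ttest_rel(during, before, alternative=sidedness)
        test_used = "paired t"
    else:
        res = stats.wilcoxon(during, before, alternative=sidedness)
        test_used = "paired Wilcoxon"
    return PairedComparison(before, during, normality_p=normality_p, test_used=test_used,
                            sidedness=sidedness, statistic=float(res.statistic),
                            p_value=float(res.pvalue), alpha_normality=alpha_normality)
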