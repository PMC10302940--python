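"""Paired experiment-vs-simulation statistics.

Implements the classic paired two-sample comparison in two equivalent routes:
from raw series (t on the per-sample differences) and from summary statistics
(two means, two sample variances, their Pearson correlation and n) via

    t = (m1 - m2) / sqrt((v1 + v2 - 2 r s1 s2) / n),   df = n - 1.

Variances use the sample (n-1) convention throughout — the convention under
which the two routes are algebraically identical.  ``agreement_report``
assembles the full per-axis comparison block (means, variances, Pearson r,
paired t, two-tailed p), per-axis error standard deviations and the mean peak
deviation of the upper-arm length fluctuation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal, stats

from .errors import ConstantSeriesError, InputError
from .synthgen import ArmGeometry, ArmTrajectory

__all__ = [
    "PairedSeries",
    "PairedSummary",
    "TTestResult",
    "pearson",
    "paired_t_from_summary",
    "paired_t_from_series",
    "agreement_report",
    "TABLE_ROW_LABELS",
]

TABLE_ROW_LABELS = (
    "Mean",
    "Variance",
    "Observations",
    "Pearson Correlation",
    "Hypothesized Mean Difference",
    "t Stat",
    "P two-tail",
)


@dataclass(frozen=True)
class PairedSeries:
    """Two aligned real-valued series (e.g. experiment vs simulation), cm."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise InputError("paired series must be equal-length 1-D arrays")
        if len(a) < 2:
            raise InputError("paired series need n >= 2")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class PairedSummary:
    """Summary statistics of a pair: means, sample variances, Pearson r, n."""

    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    r: float
    n: int

    def __post_init__(self) -> None:
        if self.var_a < 0 or self.var_b < 0:
            raise InputError("variances must be >= 0")
        if not -1.0 <= self.r <= 1.0:
            raise InputError(f"Pearson r must lie in [-1, 1], got {self.r}")
        if self.n < 2:
            raise InputError("n must be >= 2")


@dataclass(frozen=True)
class TTestResult:
    """Paired t statistic with df and two-tailed p; infinite=True flags the
    zero-difference-variance, nonzero-mean-difference degeneracy."""

    t: float
    df: int
    p: float
    infinite: bool = False


def pearson(a, b) -> float:
    """Sample Pearson correlation coefficient."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise InputError("pearson needs two equal-length series with n >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConstantSeriesError("correlation undefined for a constant series")
    am, bm = a - a.mean(), b - b.mean()
    return float(np.dot(am, bm) / math.sqrt(np.dot(am, am) * np.dot(bm, bm)))


def paired_t_from_summary(s: PairedSummary) -> TTestResult:
    """Paired t test reconstructed from summary statistics alone.

    The variance of the per-pair differences is recovered from the marginal
    variances and their correlation: var_d = v1 + v2 - 2 r s1 s2.
    """
    var_d = s.var_a + s.var_b - 2.0 * s.r * math.sqrt(s.var_a * s.var_b)
    var_d = max(var_d, 0.0)  # guard round-off for r = +-1
    df = s.n - 1
    mean_d = s.mean_a - s.mean_b
    if var_d == 0.0:
        if mean_d == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(t=math.copysign(math.inf, mean_d), df=df, p=0.0, infinite=True)
    t = mean_d / math.sqrt(var_d / s.n)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p)


def summarize(pair: PairedSeries) -> PairedSummary:
    """Sample summary (n-1 variances) of a paired series."""
    return PairedSummary(
        mean_a=float(pair.a.mean()),
        mean_b=float(pair.b.mean()),
        var_a=float(pair.a.var(ddof=1)),
        var_b=float(pair.b.var(ddof=1)),
        r=pearson(pair.a, pair.b),
        n=pair.n,
    )


def paired_t_from_series(pair: PairedSeries) -> TTestResult:
    """Paired t from raw series; identical to the summary route by construction."""
    d = pair.a - pair.b
    if np.ptp(d) == 0:
        if d[0] == 0.0:
            return TTestResult(t=0.0, df=pair.n - 1, p=1.0)
        return TTestResult(
            t=math.copysign(math.inf, d[0]), df=pair.n - 1, p=0.0, infinite=True
        )
    t = float(d.mean() / (d.std(ddof=1) / math.sqrt(pair.n)))
    p = 2.0 * float(stats.t.sf(abs(t), pair.n - 1))
    return TTestResult(t=t, df=pair.n - 1, p=p)


def _axis_block(exp: np.ndarray, sim: np.ndarray) -> dict:
    """One comparison column pair in the conventional paired-t table layout."""
    n = len(exp)
    block: dict = {
        "Mean": (float(np.mean(exp)), float(np.mean(sim))),
        "Variance": (float(np.var(exp, ddof=1)), float(np.var(sim, ddof=1))),
        "Observations": n,
        "Hypothesized Mean Difference": 0,
    }
    try:
        r = pearson(exp, sim)
        block["Pearson Correlation"] = r
    except ConstantSeriesError:
        block["Pearson Correlation"] = None
    tt = paired_t_from_series(PairedSeries(exp, sim))
    block["t Stat"] = tt.t
    block["P two-tail"] = tt.p
    return block


def agreement_report(
    sim: ArmTrajectory,
    exp: ArmTrajectory,
    geom: Optional[ArmGeometry] = None,
    peak_prominence: float = 0.05,
) -> dict:
    """Full experiment-vs-simulation agreement report on the elbow track.

    Per axis (X, Y of the elbow position): means, sample variances, Pearson r,
    paired t and two-tailed p, plus the standard deviation of the per-sample
    error.  Also reports the mean peak deviation of |l1_effective - l1| in the
    experimental trajectory (peaks = local maxima with the given prominence,
    cm) and the wrist/elbow RMS errors.
    """
    if sim.n != exp.n:
        raise InputError(f"misaligned series: sim has {sim.n} samples, exp has {exp.n}")
    if geom is None:
        geom = exp.geometry

    report: dict = {"axes": {}, "error_sd_cm": {}, "n": sim.n}
    for ax, name in ((0, "X"), (1, "Y")):
        e = exp.p_elbow[:, ax]
        s = sim.p_elbow[:, ax]
        report["axes"][name] = _axis_block(e, s)
        err = e - s
        report["error_sd_cm"][name] = float(np.std(err, ddof=1)) if np.ptp(err) else 0.0

    report["elbow_rmse_cm"] = float(
        np.sqrt(np.mean(np.sum((exp.p_elbow - sim.p_elbow) ** 2, axis=1)))
    )
    report["wrist_rmse_cm"] = float(
        np.sqrt(np.mean(np.sum((exp.p_wrist - sim.p_wrist) ** 2, axis=1)))
    )

    dev = np.abs(exp.l1_effective - geom.l1)
    peaks, props = signal.find_peaks(dev, prominence=peak_prominence)
    report["l1_mean_peak_deviation_cm"] = float(np.mean(dev[peaks])) if len(peaks) else 0.0
    report["l1_n_peaks"] = int(len(peaks))
    return report
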