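"""Robust outlier exclusion for triage distance errors.

Implements a constant-model variant of the ROUT idea (robust fit followed by
FDR-controlled outlier identification): the robust fit of a one-dimensional
sample is its median; residual spread is estimated by the RSDR (robust
standard deviation of the residuals, the 68.27th percentile of the absolute
residuals with an n/(n-1) small-sample correction); each point gets a
two-tailed t p-value from its scaled residual; and the Benjamini–Hochberg
step-up at rate Q flags the outliers.  Q defaults to 1%.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["RoutConfig", "OutlierReport", "rout_constant", "summarize_distances"]

_RSDR_PERCENTILE = 68.27  # one normal standard deviation


@dataclass(frozen=True)
class RoutConfig:
    """Q is the outlier false discovery rate; detection is skipped below min_n."""

    Q: float = 0.01
    min_n: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.Q < 1.0:
            raise ValueError("Q must be in (0, 1)")


@dataclass
class OutlierReport:
    values: np.ndarray
    robust_center: float
    robust_scale: float
    p_values: np.ndarray
    flags: np.ndarray  # True = flagged as outlier
    warnings: list[str] = field(default_factory=list)

    @property
    def retained(self) -> np.ndarray:
        return self.values[~self.flags]

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def summary(self) -> dict:
        mean, sd, n = summarize_distances(self.retained)
        return {
            "n_before": int(len(self.values)),
            "n_after": int(n),
            "n_flagged": self.n_flagged,
            "mean": mean,
            "sd": sd,
            "robust_center": self.robust_center,
            "robust_scale": self.robust_scale,
        }


def rout_constant(values: np.ndarray | list[float], config: RoutConfig = RoutConfig()) -> OutlierReport:
    """Flag outliers in a 1-D sample at false discovery rate ``config.Q``.

    Recipe: median centre; RSDR scale from the 68.27th percentile of absolute
    residuals times n/(n-1); two-tailed p-values from t = |r|/RSDR with n-1
    degrees of freedom; BH step-up at Q.  A zero RSDR flags exactly the
    nonzero residuals (if any).  Below ``min_n`` detection is skipped with a
    recorded warning and no flags.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("rout_constant requires at least 2 values")
    center = float(np.median(x))
    resid = x - center
    scale = float(np.percentile(np.abs(resid), _RSDR_PERCENTILE)) * n / (n - 1)
    p = np.ones(n)
    flags = np.zeros(n, dtype=bool)
    notes: list[str] = []
    if n < config.min_n:
        notes.append(f"n={n} < min_n={config.min_n}: outlier detection skipped")
        warnings.warn(notes[-1], stacklevel=2)
        return OutlierReport(x, center, scale, p, flags, notes)
    if scale == 0.0:
        flags = resid != 0.0
        p = np.where(flags, 0.0, 1.0)
        return OutlierReport(x, center, scale, p, flags, notes)
    t = np.abs(resid) / scale
    p = 2.0 * stats.t.sf(t, df=n - 1)
    flags = multipletests(p, alpha=config.Q, method="fdr_bh")[0]
    return OutlierReport(x, center, scale, p, flags, notes)


def summarize_distances(values: np.ndarray | list[float]) -> tuple[float, float, int]:
    """Arithmetic mean, sample standard deviation (n-1), and n.

    A single value has an undefined (NaN) standard deviation.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 1:
        raise ValueError("summarize_distances requires at least one value")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if len(x) > 1 else float("nan")
    return mean, sd, len(x)
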