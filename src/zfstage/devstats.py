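"""Developmental-rate statistics.

Implements the temperature scaling of zebrafish development,

    H_T = h / (0.055 * T - c),        c = 0.57 degC,

where ``h`` is hours of development at the 28.5 degC reference and ``H_T``
the hours required to reach the same stage at temperature ``T``; plus the
through-origin line fits (``y = m x``), residual summaries and resampled
slope bands used to decide whether two embryo populations develop at
distinguishably different rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "RateModel",
    "OriginLineFit",
    "SlopeBand",
    "ResidualSummary",
    "relative_rate",
    "stage_at_time",
    "fit_through_origin",
    "bootstrap_slope_band",
    "residual_summary",
    "populations_distinguishable",
]


@dataclass(frozen=True)
class RateModel:
    """Linear temperature scaling of developmental rate.

    ``rate(T) = slope_coeff * T - c`` is the number of reference-equivalent
    developmental hours elapsed per wall-clock hour at temperature ``T``.
    At the reference temperature (28.5 degC) the formula evaluates to
    0.9975, not exactly 1; it is used as printed.
    """

    c: float = 0.57                    # degC
    slope_coeff: float = 0.055         # per degC
    reference_temperature: float = 28.5  # degC

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError(f"c must be positive, got {self.c}")

    @property
    def min_temperature(self) -> float:
        """Temperature below which the model gives a nonpositive rate."""
        return self.c / self.slope_coeff


@dataclass(frozen=True)
class OriginLineFit:
    """Least-squares fit of y = m x. ``r_squared`` is None when SS_tot = 0."""

    m: float
    r_squared: Optional[float]
    n: int


@dataclass(frozen=True)
class SlopeBand:
    """[min, max] of through-origin slopes over random subsamples."""

    m_min: float
    m_max: float
    k: int
    n_boot: int

    def __post_init__(self) -> None:
        if self.m_min > self.m_max:
            raise ValueError("m_min must not exceed m_max")


@dataclass(frozen=True)
class ResidualSummary:
    mean: float
    sd: float
    sem: float
    n: int


def relative_rate(temperature_c: float, model: RateModel = RateModel()) -> float:
    """Developmental rate at ``temperature_c`` relative to the 28.5 degC clock.

    Returns ``0.055 * T - c``: the expected through-origin slope of
    reference-equivalent stage against wall-clock hours post fertilisation
    for a population incubated at ``T``.  25.0 degC gives 0.805.

    Raises ``ValueError`` if the rate is not positive (T <= c/0.055).
    """
    rate = model.slope_coeff * temperature_c - model.c
    if rate <= 0:
        raise ValueError(
            f"nonpositive developmental rate {rate:.4g} at {temperature_c} degC; "
            f"model valid only above {model.min_temperature:.3f} degC"
        )
    return rate


def stage_at_time(
    t_hours: float, temperature_c: float, model: RateModel = RateModel()
) -> float:
    """Reference-equivalent stage (hpf at 28.5 degC) after ``t_hours`` at ``T``.

    Inverts the scaling equation: ``h = t * (0.055 * T - c)``. Linear in
    elapsed time and strictly increasing in temperature over the valid range.
    """
    if t_hours < 0:
        raise ValueError(f"elapsed time must be nonnegative, got {t_hours}")
    return t_hours * relative_rate(temperature_c, model)


def fit_through_origin(x: np.ndarray, y: np.ndarray) -> OriginLineFit:
    """Least-squares line through the origin, ``y = m x``.

    m = sum(x*y) / sum(x^2).  R^2 is the conventional
    ``1 - SS_res / sum((y - ybar)^2)``; for through-origin fits it can be
    negative, and it is reported as ``None`` when y is constant (SS_tot = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-D, got {x.shape}, {y.shape}")
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("all x values are zero; slope undefined")
    m = float(np.dot(x, y)) / sxx
    ss_res = float(np.sum((y - m * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = None if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return OriginLineFit(m=m, r_squared=r2, n=n)


def _sample_without_replacement(
    rng: np.random.Generator, n: int, k: int, n_boot: int
) -> np.ndarray:
    """(n_boot, k) index matrix, each row a uniform k-subset of range(n).

    Partial Fisher-Yates shuffles run in parallel across rows (chunked to
    bound memory): k swap rounds on a tiled arange give uniform random
    k-prefixes, i.e. uniform k-subsets, at O(n_boot * (n + k)) cost.
    """
    chunk = max(1, 2_000_000 // n)
    out = np.empty((n_boot, k), dtype=np.intp)
    for start in range(0, n_boot, chunk):
        rows = min(chunk, n_boot - start)
        perm = np.tile(np.arange(n), (rows, 1))
        rr = np.arange(rows)
        for j in range(k):
            r = rng.integers(j, n, size=rows)
            picked = perm[rr, r]
            perm[rr, r] = perm[:, j]
            perm[:, j] = picked
        out[start : start + rows] = perm[:, :k]
    return out


def bootstrap_slope_band(
    x: np.ndarray,
    y: np.ndarray,
    k: int,
    n_boot: int = 10_000,
    seed: int = 0,
    replace: bool = False,
) -> SlopeBand:
    """Range of through-origin slopes over ``n_boot`` random subsamples of size ``k``.

    Each resample is drawn without replacement by default (the resample is a
    subset of the data; set ``replace=True`` for a classical bootstrap) and
    fitted with :func:`fit_through_origin`; the minimum and maximum slopes
    across all resamples form the band.  With k = n and ``replace=False``
    every resample is the full data set and the band collapses to the
    full-data slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if k < 2:
        raise ValueError(f"resample size k must be >= 2, got {k}")
    if not replace and k > n:
        raise ValueError(f"cannot draw {k} points without replacement from {n}")
    rng = np.random.default_rng(seed)
    if replace:
        idx = rng.integers(0, n, size=(n_boot, k))
    else:
        idx = _sample_without_replacement(rng, n, k, n_boot)
    xs = x[idx]
    ys = y[idx]
    slopes = np.einsum("ij,ij->i", xs, ys) / np.einsum("ij,ij->i", xs, xs)
    return SlopeBand(
        m_min=float(slopes.min()), m_max=float(slopes.max()), k=k, n_boot=n_boot
    )


def residual_summary(x: np.ndarray, y: np.ndarray, fit: OriginLineFit) -> ResidualSummary:
    """Summary of residuals r_i = y_i - m x_i about a through-origin fit.

    The mean and sd use divisor n (population sd); the sem uses the sample
    sd (divisor n - 1) divided by sqrt(n).  The two divisor conventions are
    deliberate: they mirror the defaults of the NumPy ``std`` and SciPy
    ``sem`` routines respectively, which differ in ddof.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    r = y - fit.m * x
    sd = float(np.std(r))  # ddof=0
    sem = float(np.std(r, ddof=1) / np.sqrt(n))
    return ResidualSummary(mean=float(r.mean()), sd=sd, sem=sem, n=n)


def populations_distinguishable(a: SlopeBand, b: SlopeBand) -> tuple[bool, float]:
    """Whether two slope bands are disjoint, plus the separation margin.

    Returns ``(True, gap)`` when the intervals do not intersect (gap > 0 is
    the distance between them) and ``(False, -overlap)`` otherwise.  For
    through-origin cones, slope-interval disjointness implies the prediction
    cones are disjoint at every x > 0.
    """
    margin = max(a.m_min, b.m_min) - min(a.m_max, b.m_max)
    return margin > 0, float(margin)
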