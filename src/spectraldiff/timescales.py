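"""Characteristic timescales of stimuli and neural activity.

Two estimators of the characteristic timescale (CT) of a signal:

* ``piecewise_ct`` — for piecewise-constant signals (artificial stimuli),
  the mean duration of the maximal constant runs, excluding the possibly
  truncated first and last runs.
* ``fit_characteristic_timescale`` — for everything else, a constrained fit
  of the log autocorrelation to a continuous two-phase linear decay with a
  fast timescale ``t1`` (the CT used downstream), a slow timescale ``t2``
  and a transition lag ``c``:

      log ac(x) = −a − x/t1                      for x < c
      log ac(x) = −a − c/t1 − (x − c)/t2         for x ≥ c

  with box constraints 0 < t1 ≤ 1.5 s, 0.5 ≤ t2 ≤ 20 s, 0.03 ≤ c ≤ 0.2 s,
  a ≥ 0.

The module also surveys how differentiation depends on the state length S
(``nd_vs_state_length``), classifies the resulting curve's optimum
(``detect_optimal_timescale``) and fits the power-law decay beyond the CT
(``power_law_fit``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .differentiation import DifferentiationConfig, nd_timeseries
from .preprocess import DEFAULT_F, RateMatrix

_BOUNDS_LO = np.array([0.0, 0.03, 1e-4, 0.5])  # a, c, t1, t2
_BOUNDS_HI = np.array([20.0, 0.2, 1.5, 20.0])


@dataclass
class ACTimescaleFit:
    """Parameters of the two-phase log-autocorrelation decay model."""

    a: float
    c: float
    t1: float
    t2: float
    residual: float
    at_boundary: bool = False

    @property
    def ct(self) -> float:
        """Characteristic timescale: the fast decay constant t1."""
        return self.t1


@dataclass
class NDCurve:
    """Normalized differentiation as a function of state length S."""

    s_grid: np.ndarray
    nd_values: np.ndarray
    classification: str | None = None

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.nd_values = np.asarray(self.nd_values, dtype=float)
        if np.any(np.diff(self.s_grid) <= 0):
            raise ValueError("s_grid must be strictly increasing")
        if np.any(self.nd_values < 0):
            raise ValueError("nd_values must be non-negative")


def piecewise_ct(signal: np.ndarray, f: float = DEFAULT_F) -> float:
    """Mean duration (s) of interior maximal constant runs of a signal.

    The first and last runs are excluded because they may be truncated by
    the recording edges. Only run lengths matter, not the values.
    """
    signal = np.asarray(signal)
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    change = np.flatnonzero(signal[1:] != signal[:-1]) + 1
    # run boundaries: [0, change..., n]
    edges = np.concatenate(([0], change, [signal.size]))
    run_lengths = np.diff(edges)
    if run_lengths.size < 3:
        raise ValueError(
            "signal has fewer than 3 constant runs; no interior run to measure"
        )
    return float(run_lengths[1:-1].mean() / f)


def autocorrelation(
    series: np.ndarray, max_lag: float = 2.0, f: float = DEFAULT_F
) -> tuple[np.ndarray, np.ndarray]:
    """Biased normalized autocovariance up to ``max_lag`` seconds.

    Returns ``(lags_s, ac)`` with ``ac[0] == 1`` exactly. Uses the 1/n
    (biased) estimator of the autocovariance of the mean-subtracted series,
    computed by FFT.
    """
    x = np.asarray(series, dtype=float)
    n_lags = int(round(max_lag * f))
    if x.size <= 2 * n_lags:
        raise ValueError("series must be longer than twice the maximum lag")
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0:
        raise ValueError("zero-variance series has no autocorrelation")
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n - 1)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[: n_lags + 1]
    ac = acov / var
    lags = np.arange(n_lags + 1) / f
    return lags, ac


def _two_phase(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, c, t1, t2 = params
    y_fast = -a - x / t1
    y_slow = -a - c / t1 - (x - c) / t2
    return np.where(x < c, y_fast, y_slow)


def fit_characteristic_timescale(
    ac: np.ndarray, lags: np.ndarray
) -> ACTimescaleFit:
    """Constrained least-squares fit of log(ac) to the two-phase model.

    Lag 0 (where ac is 1 by construction) and nonpositive autocorrelation
    values are masked before taking logs. The optimizer is bounded least
    squares from 5 deterministic starting points spread over the fast
    timescale; the best solution is returned, flagged when any parameter
    other than the offset lands on a box constraint.
    """
    lags = np.asarray(lags, dtype=float)
    ac = np.asarray(ac, dtype=float)
    mask = (lags > 0) & (ac > 0)
    x, y = lags[mask], np.log(ac[mask])
    if x.size < 5:
        raise ValueError(
            f"only {x.size} usable (positive-lag, positive-ac) points; "
            "need at least 5 to fit the two-phase model"
        )
    best = None
    for t1_0 in (0.05, 0.1, 0.3, 0.7, 1.2):
        x0 = np.clip(
            np.array([0.01, 0.1, t1_0, 5.0]), _BOUNDS_LO + 1e-9, _BOUNDS_HI - 1e-9
        )
        sol = least_squares(
            lambda p: _two_phase(p, x) - y,
            x0,
            bounds=(_BOUNDS_LO, _BOUNDS_HI),
            method="trf",
        )
        if best is None or sol.cost < best.cost:
            best = sol
    a, c, t1, t2 = best.x
    tol = 1e-6 * (_BOUNDS_HI - _BOUNDS_LO)
    at_boundary = bool(
        np.any(best.x[1:] - _BOUNDS_LO[1:] < tol[1:])
        or np.any(_BOUNDS_HI[1:] - best.x[1:] < tol[1:])
    )
    return ACTimescaleFit(
        a=float(a),
        c=float(c),
        t1=float(t1),
        t2=float(t2),
        residual=float(2 * best.cost),
        at_boundary=at_boundary,
    )


def default_state_grid(
    s_min: float = 0.010, s_max: float = 3.0, num: int = 20, f: float = DEFAULT_F
) -> np.ndarray:
    """Log-spaced state lengths snapped to integer sample counts.

    Duplicate sample counts after snapping are merged, so the returned grid
    may be shorter than ``num``.
    """
    grid = np.geomspace(s_min, s_max, num)
    samples = np.unique(np.maximum(2, np.round(grid * f).astype(int)))
    return samples / f


def nd_vs_state_length(
    rates: RateMatrix,
    config: DifferentiationConfig | None = None,
    s_grid: np.ndarray | None = None,
    epochs=None,
    mean_rate: float | None = None,
) -> NDCurve:
    """Window-averaged normalized ND for each state length in the grid.

    Every S in the grid must fit at least twice into the analysis window.
    """
    cfg = config or DifferentiationConfig()
    if s_grid is None:
        s_grid = default_state_grid(s_max=cfg.window / 2, f=cfg.f)
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any(s_grid > cfg.window / 2 + 1e-9):
        raise ValueError(
            "every state length must fit at least twice into the window"
        )
    if epochs is None:
        epochs = [(rates.t0, rates.t0 + rates.duration)]
    values = np.empty(s_grid.size)
    for i, s in enumerate(s_grid):
        series = nd_timeseries(rates, epochs, cfg.with_state(s), mean_rate)
        values[i] = series.nd.mean()
    return NDCurve(s_grid=s_grid, nd_values=values)


@dataclass
class OptimalTimescale:
    """Optimum of an ND-vs-S curve.

    ``classification`` is ``interior-optimum``, ``optimum-beyond-range`` (the
    maximum sits at the longest probed S) or ``zero`` (no differentiation at
    any S). ``at_short_boundary`` marks curves maximal at the shortest
    probed S — the ensemble "loss of optimality" signature, where ND keeps
    increasing at shorter and shorter timescales.
    """

    s_opt: float | None
    classification: str
    at_short_boundary: bool = False


def detect_optimal_timescale(curve: NDCurve) -> OptimalTimescale:
    """Locate and classify the maximum of an ND-vs-S curve."""
    if curve.nd_values.size == 0:
        raise ValueError("empty curve")
    if np.all(curve.nd_values == 0):
        curve.classification = "zero"
        return OptimalTimescale(None, "zero")
    i = int(np.argmax(curve.nd_values))
    if i == curve.nd_values.size - 1:
        curve.classification = "optimum-beyond-range"
        return OptimalTimescale(None, "optimum-beyond-range")
    curve.classification = "interior-optimum"
    return OptimalTimescale(
        float(curve.s_grid[i]), "interior-optimum", at_short_boundary=(i == 0)
    )


def power_law_fit(curve: NDCurve, s_min: float) -> tuple[float, float]:
    """Least-squares slope of log(ND) vs log(S) for S > ``s_min``.

    Returns ``(exponent, intercept)`` of ND ≈ exp(intercept) · S^exponent.
    """
    mask = (curve.s_grid > s_min) & (curve.nd_values > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} usable points beyond S={s_min}; "
            "need at least 3 for a power-law fit"
        )
    res = linregress(np.log(curve.s_grid[mask]), np.log(curve.nd_values[mask]))
    return float(res.slope), float(res.intercept)
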