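"""Spectral differentiation of population firing rates.

Neurophysiological differentiation (ND) quantifies how many distinct
activity states an ensemble of N units visits within an analysis window W.
The window is tiled with non-overlapping state windows of length S; the
state of the ensemble within each state window is the concatenation of the
per-unit power spectral densities (PSDs, non-negative frequencies of the
unnormalized discrete Fourier transform, magnitude squared). ND of the
window is the median Euclidean distance between all pairs of state vectors.

To compare across ensembles, the firing rates are first divided by a single
scalar — the mean rate over all units of the ensemble across the whole
session — and the raw median distance is divided by sqrt(N) (state-space
dimensionality grows linearly with N) and by S² (total DFT power grows with
the squared number of samples per state):

    ND = ND_raw(FR / mean(FR)) · N^(−1/2) · S^(−2)

The same machinery applied to stimulus pixel intensities (pixels as units)
yields stimulus differentiation (SD). A simpler control metric, the mean
firing-rate differentiation (mfrD), is the variance across states of the
ensemble-mean normalized firing rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey
from scipy.spatial.distance import pdist

from .preprocess import DEFAULT_F, RateMatrix

#: Minimum ensemble size for ND; guards against artifacts from singular
#: extreme units.
DEFAULT_MIN_UNITS = 10


@dataclass(frozen=True)
class DifferentiationConfig:
    """Parameters of the differentiation computation.

    Attributes
    ----------
    window
        Analysis window length W in seconds (default 3 s — long enough that
        the median pairwise distance is near its asymptote, short enough to
        be tractable).
    state
        State length S in seconds (default 0.3 s, the putative timescale of
        subjective perception). Must give W/S >= 2 so at least one pair of
        states exists, and round to an integer number of samples at ``f``.
    f
        Sampling rate in Hz (default 200).
    taper : {"none", "tukey"}
        Optional Tukey taper (shape parameter 1) applied per state segment
        before the DFT, to probe boundary-leakage sensitivity.
    min_units
        Minimum ensemble size (default 10).
    """

    window: float = 3.0
    state: float = 0.3
    f: float = DEFAULT_F
    taper: str = "none"
    min_units: int = DEFAULT_MIN_UNITS

    def __post_init__(self) -> None:
        if not (self.window >= self.state > 0):
            raise ValueError("require window >= state > 0")
        if self.window / self.state < 2 - 1e-9:
            raise ValueError(
                "window must contain at least 2 states (W/S >= 2); the median "
                "of pairwise state distances is undefined otherwise"
            )
        if self.taper not in ("none", "tukey"):
            raise ValueError(f"unknown taper {self.taper!r}")
        # S must land on an integer number of samples (within half a sample)
        self.state_samples  # noqa: B018 — validates

    @property
    def state_samples(self) -> int:
        n = round(self.state * self.f)
        if n < 1 or abs(self.state * self.f - n) > 0.5 + 1e-9:
            raise ValueError(
                f"state length {self.state} s does not round to an integer "
                f"number of samples at {self.f} Hz"
            )
        return int(n)

    @property
    def n_states(self) -> int:
        """Number of non-overlapping states per window, floor(W/S)."""
        return int(math.floor(self.window / self.state + 1e-9))

    def with_state(self, state: float) -> "DifferentiationConfig":
        return replace(self, state=state)


@dataclass
class NDSeries:
    """Per-window differentiation values with their ensemble context."""

    window_centers: np.ndarray
    nd_raw: np.ndarray
    nd: np.ndarray
    n_units: int
    ensemble_mean_rate: float
    config: DifferentiationConfig
    epoch_index: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    categories: np.ndarray = field(default_factory=lambda: np.empty(0, object))
    max_norm_amplitude: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "window_center_s": self.window_centers,
                "nd_raw": self.nd_raw,
                "nd": self.nd,
                "n_units": self.n_units,
            }
        )
        if self.epoch_index.size:
            df.insert(0, "epoch_id", self.epoch_index)
        if self.categories.size:
            df["category"] = self.categories
        return df


def segment_states(values: np.ndarray, n_state_samples: int) -> np.ndarray:
    """Split a units × samples window into non-overlapping state blocks.

    Returns an array of shape (n_states, n_units, n_state_samples); a
    trailing remainder shorter than one state is dropped.
    """
    values = np.atleast_2d(values)
    n_units, n_samples = values.shape
    n_states = n_samples // n_state_samples
    if n_states < 2:
        raise ValueError(
            "window must contain at least 2 complete states; the median of "
            "pairwise distances is undefined for fewer"
        )
    trimmed = values[:, : n_states * n_state_samples]
    return trimmed.reshape(n_units, n_states, n_state_samples).transpose(1, 0, 2)


def state_psd(block: np.ndarray, taper: str = "none") -> np.ndarray:
    """Concatenated per-unit power spectrum of one state block.

    Uses the unnormalized forward DFT (no 1/n factor) and keeps only the
    non-negative frequencies; each unit contributes floor(f·S/2)+1 entries.
    ``block`` is units × samples; states stacked along a leading axis are
    also accepted (the DFT runs over the last axis).
    """
    block = np.asarray(block, dtype=float)
    if taper == "tukey":
        block = block * tukey(block.shape[-1], alpha=1.0)
    elif taper != "none":
        raise ValueError(f"unknown taper {taper!r}")
    spectrum = np.abs(np.fft.rfft(block, axis=-1)) ** 2
    return spectrum.reshape(*spectrum.shape[:-2], -1)


def spectral_differentiation_raw(state_vectors: np.ndarray) -> float:
    """Median Euclidean distance over all unordered pairs of state vectors.

    ``state_vectors`` is n_states × dim. With an even number of pairs the
    median is the mean of the two middle values.
    """
    state_vectors = np.atleast_2d(np.asarray(state_vectors, dtype=float))
    if state_vectors.shape[0] < 2:
        raise ValueError("need at least 2 states")
    return float(np.median(pdist(state_vectors)))


def normalize_nd(nd_raw: float, n_units: int, state: float) -> float:
    """ND = ND_raw · N^(−1/2) · S^(−2).

    ``nd_raw`` must have been computed on rates divided by the scalar
    ensemble-session mean rate.
    """
    return nd_raw / (math.sqrt(n_units) * state**2)


def bound_raw(amplitude: float, f: float, state: float, n_units: int) -> float:
    """Upper bound N·A²·f²·S² on the raw median state distance.

    ``amplitude`` is the maximum signal amplitude A over the window (units of
    firing rate, or dimensionless for mean-normalized rates).
    """
    if min(amplitude, f, state, n_units) <= 0:
        raise ValueError("all bound arguments must be positive")
    return n_units * amplitude**2 * f**2 * state**2


def bound_normalized(amplitude: float, f: float) -> float:
    """Upper bound A²·f² on normalized ND; independent of N and S."""
    if min(amplitude, f) <= 0:
        raise ValueError("all bound arguments must be positive")
    return amplitude**2 * f**2


def _window_slices(
    rates: RateMatrix, epochs, window: float
) -> list[tuple[int, int, int, float, object]]:
    """Tile each epoch with non-overlapping windows of length ``window``.

    Epochs are (start_s, end_s) or (start_s, end_s, category) tuples, or a
    DataFrame with columns start_s, end_s[, category]. Windows never straddle
    epoch boundaries; incomplete trailing windows are dropped. Returns
    (epoch_idx, bin_start, bin_stop, center_s, category) tuples.
    """
    if isinstance(epochs, pd.DataFrame):
        rows = [
            (r.start_s, r.end_s, getattr(r, "category", None))
            for r in epochs.itertuples()
        ]
    else:
        rows = [(e[0], e[1], e[2] if len(e) > 2 else None) for e in epochs]
    f = rates.sampling_rate
    w_bins = int(round(window * f))
    out = []
    for ei, (start, end, cat) in enumerate(rows):
        if start < rates.t0 - 1e-9 or end > rates.t0 + rates.duration + 1e-9:
            raise ValueError(
                f"epoch [{start}, {end}) outside the rate matrix support"
            )
        b0 = int(round((start - rates.t0) * f))
        n_w = int(math.floor((end - start) / window + 1e-9))
        for k in range(n_w):
            a = b0 + k * w_bins
            out.append((ei, a, a + w_bins, rates.t0 + (a + w_bins / 2) / f, cat))
    return out


def nd_timeseries(
    rates: RateMatrix,
    epochs,
    config: DifferentiationConfig | None = None,
    mean_rate: float | None = None,
) -> NDSeries:
    """Normalized spectral differentiation for every complete window.

    Parameters
    ----------
    rates
        Ensemble firing rates (units × bins).
    epochs
        Iterable of (start_s, end_s[, category]) or a DataFrame; each epoch
        is tiled independently with non-overlapping windows.
    config
        Differentiation parameters; defaults to W=3 s, S=0.3 s, f=200 Hz.
    mean_rate
        Scalar normalizer. Defaults to the mean rate over all units of this
        matrix across the whole session; pass the class-restricted session
        mean explicitly when the matrix holds only part of the session.
    """
    cfg = config or DifferentiationConfig()
    if rates.n_units < cfg.min_units:
        raise ValueError(
            f"ensemble has {rates.n_units} units, fewer than the required "
            f"minimum of {cfg.min_units}; differentiation is only computed "
            f"for ensembles of at least {cfg.min_units} units"
        )
    if abs(rates.sampling_rate - cfg.f) > 1e-9:
        raise ValueError("rate matrix sampling rate does not match config f")
    if mean_rate is None:
        mean_rate = float(rates.values.mean())
    if mean_rate <= 0:
        raise ValueError("ensemble mean rate is zero; cannot normalize")
    norm = rates.values / mean_rate
    n_s = cfg.state_samples
    slices = _window_slices(rates, epochs, cfg.window)
    centers, raws, eidx, cats = [], [], [], []
    max_amp = 0.0
    for ei, a, b, center, cat in slices:
        states = segment_states(norm[:, a:b], n_s)
        max_amp = max(max_amp, float(states.max(initial=0.0)))
        vecs = state_psd(states, cfg.taper)
        raws.append(spectral_differentiation_raw(vecs))
        centers.append(center)
        eidx.append(ei)
        cats.append(cat)
    raws = np.asarray(raws)
    nd = raws / (math.sqrt(rates.n_units) * cfg.state**2)
    return NDSeries(
        window_centers=np.asarray(centers),
        nd_raw=raws,
        nd=nd,
        n_units=rates.n_units,
        ensemble_mean_rate=float(mean_rate),
        config=cfg,
        epoch_index=np.asarray(eidx, int),
        categories=np.asarray(cats, object),
        max_norm_amplitude=max_amp,
    )


def mfr_differentiation(
    rates: RateMatrix, epochs, config: DifferentiationConfig | None = None
) -> NDSeries:
    """Mean firing-rate differentiation per window.

    Each unit's rate is divided by that unit's own session-mean rate (units
    with zero mean are dropped with a warning); per state, the mean across
    units of the normalized rate's time average is taken; the window value is
    the population variance of those per-state means. Windowing matches
    :func:`nd_timeseries`. ``nd_raw`` and ``nd`` both hold the variance (the
    metric has no separate normalization step).
    """
    cfg = config or DifferentiationConfig()
    unit_means = rates.values.mean(axis=1)
    keep = unit_means > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} unit(s) with zero session-mean "
            "rate from mfrD",
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("no units with nonzero mean rate")
    norm = rates.values[keep] / unit_means[keep, None]
    n_s = cfg.state_samples
    centers, vals, eidx, cats = [], [], [], []
    for ei, a, b, center, cat in _window_slices(rates, epochs, cfg.window):
        states = segment_states(norm[:, a:b], n_s)  # (n_states, n_units, n_s)
        state_means = states.mean(axis=(1, 2))
        vals.append(float(np.var(state_means)))  # population variance
        centers.append(center)
        eidx.append(ei)
        cats.append(cat)
    vals = np.asarray(vals)
    return NDSeries(
        window_centers=np.asarray(centers),
        nd_raw=vals,
        nd=vals,
        n_units=int(keep.sum()),
        ensemble_mean_rate=float(unit_means[keep].mean()),
        config=cfg,
        epoch_index=np.asarray(eidx, int),
        categories=np.asarray(cats, object),
    )


def stimulus_differentiation(
    movie: np.ndarray,
    config: DifferentiationConfig | None = None,
    frame_rate: float | None = None,
    epochs=None,
) -> NDSeries:
    """Spectral differentiation of a stimulus movie, pixels as units.

    ``movie`` is pixels × frames. If ``frame_rate`` differs from the config
    sampling rate the movie is resampled by sample-and-hold first. The
    computation (including mean-normalization by the grand mean pixel value
    and the sqrt(N)/S² normalizations) is identical to :func:`nd_timeseries`.
    """
    cfg = config or DifferentiationConfig()
    movie = np.atleast_2d(np.asarray(movie, dtype=float))
    if frame_rate is not None and abs(frame_rate - cfg.f) > 1e-9:
        movie = resample_hold(movie, frame_rate, cfg.f)
    rates = RateMatrix(movie, sampling_rate=cfg.f)
    if epochs is None:
        epochs = [(0.0, rates.duration)]
    return nd_timeseries(rates, epochs, cfg)


def resample_hold(movie: np.ndarray, frame_rate: float, f: float) -> np.ndarray:
    """Resample pixels × frames to sampling rate ``f`` by holding frames."""
    n_frames = movie.shape[1]
    n_out = int(round(n_frames / frame_rate * f))
    idx = np.minimum((np.arange(n_out) / f * frame_rate).astype(int), n_frames - 1)
    return movie[:, idx]


def evoked_nd(
    rates: RateMatrix,
    event_times: np.ndarray,
    window: float = 0.3,
    state: float = 0.06,
    config: DifferentiationConfig | None = None,
    mean_rate: float | None = None,
) -> np.ndarray:
    """Trial-locked ND: one value per event over ``[t, t + window)``.

    Defaults follow the change-detection analysis: a 300 ms post-event
    window split into five 60 ms states. Events whose window overruns the
    recording are skipped with a warning and reported as NaN.
    """
    base = config or DifferentiationConfig()
    cfg = replace(base, window=window, state=state)
    end = rates.t0 + rates.duration
    out = np.full(len(event_times), np.nan)
    if mean_rate is None:
        mean_rate = float(rates.values.mean())
    for i, t in enumerate(np.asarray(event_times, dtype=float)):
        if t < rates.t0 or t + window > end + 1e-9:
            warnings.warn(
                f"event at t={t} s overlaps the recording edge; skipped",
                stacklevel=2,
            )
            continue
        series = nd_timeseries(rates, [(t, t + window)], cfg, mean_rate=mean_rate)
        out[i] = series.nd[0]
    return out
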