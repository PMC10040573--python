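"""Spike-train preprocessing.

Converts per-unit spike times into smoothed firing-rate matrices and
classifies extracellular units into regular-spiking (RS, putatively
excitatory) and fast-spiking (FS, putatively inhibitory) classes based on
mean waveform width, with a signal-to-noise-ratio (SNR) quality gate.

The processing chain is:

1. ``bin_spikes`` — spike times -> binary series (5 ms bins, i.e. 200 Hz):
   a bin is 1 iff at least one spike falls inside it.
2. ``smooth_rates`` — binary series convolved with a truncated, renormalized
   Gaussian kernel (10 ms SD, cut at ±25 ms) and scaled by the sampling
   rate, yielding an instantaneous firing rate in spikes/second.
3. ``build_rate_matrix`` — stacks the per-unit rates into a
   :class:`RateMatrix`, the container every differentiation metric consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default sampling rate in Hz; the bin width is 1/f = 5 ms.
DEFAULT_F = 200.0

#: RS/FS waveform-width boundary in milliseconds.
DEFAULT_WIDTH_THRESHOLD = 0.4

#: Unit-quality gate on signal-to-noise ratio (dimensionless).
DEFAULT_SNR_THRESHOLD = 2.5


@dataclass
class SpikeTable:
    """Per-unit spike times plus unit metadata for one recording session.

    Parameters
    ----------
    spikes
        Mapping ``unit_id -> sorted array of spike times`` in seconds.
    units
        Metadata indexed by ``unit_id``; expected columns are ``area``,
        ``layer``, ``waveform_width_ms``, ``snr`` and ``mouse_id``.
        Missing columns are tolerated (downstream steps that need them warn).
    session_duration
        Recording length in seconds. All spike times must lie in
        ``[0, session_duration]``.
    """

    spikes: dict[str, np.ndarray]
    units: pd.DataFrame
    session_duration: float

    def __post_init__(self) -> None:
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")
        clean = {}
        for uid, st in self.spikes.items():
            st = np.asarray(st, dtype=float)
            if st.size and np.any(np.diff(st) < 0):
                raise ValueError(f"spike times for unit {uid!r} are not sorted")
            if st.size and (st[0] < 0 or st[-1] > self.session_duration):
                raise ValueError(
                    f"spike times for unit {uid!r} fall outside "
                    f"[0, {self.session_duration}]"
                )
            clean[uid] = st
        self.spikes = clean

    @property
    def unit_ids(self) -> list[str]:
        return list(self.spikes.keys())


@dataclass
class RateMatrix:
    """Units × time-bins firing-rate array at a fixed sampling rate.

    ``values[i, b]`` is the smoothed firing rate of ``unit_ids[i]`` in
    spikes/second (or dimensionless once normalized) in the bin starting at
    ``t0 + b / sampling_rate``.
    """

    values: np.ndarray
    sampling_rate: float = DEFAULT_F
    t0: float = 0.0
    unit_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("firing rates must be non-negative")
        if not self.unit_ids:
            self.unit_ids = list(range(self.values.shape[0]))
        if len(self.unit_ids) != self.values.shape[0]:
            raise ValueError("unit_ids length does not match row count")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins / self.sampling_rate

    def times(self) -> np.ndarray:
        """Left edges of the time bins in seconds."""
        return self.t0 + np.arange(self.n_bins) / self.sampling_rate

    def subset(self, unit_ids) -> "RateMatrix":
        """Row subset preserving the requested order."""
        index = {u: i for i, u in enumerate(self.unit_ids)}
        rows = [index[u] for u in unit_ids]
        return RateMatrix(
            self.values[rows], self.sampling_rate, self.t0, list(unit_ids)
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("rates", data=self.values)
            ds.attrs["sampling_rate"] = self.sampling_rate
            ds.attrs["t0"] = self.t0
            fh.create_dataset(
                "unit_ids", data=np.asarray([str(u) for u in self.unit_ids], dtype="S")
            )

    @classmethod
    def from_hdf5(cls, path) -> "RateMatrix":
        with h5py.File(path, "r") as fh:
            ds = fh["rates"]
            return cls(
                ds[()],
                float(ds.attrs["sampling_rate"]),
                float(ds.attrs["t0"]),
                [u.decode() for u in fh["unit_ids"][()]],
            )


def classify_units(
    units: pd.DataFrame,
    width_threshold: float = DEFAULT_WIDTH_THRESHOLD,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
) -> pd.Series:
    """Label each unit RS, FS, or excluded.

    RS (regular spiking): ``snr > snr_threshold`` and waveform width
    ``>= width_threshold``; FS (fast spiking): ``snr > snr_threshold`` and
    width ``< width_threshold``; anything else (including missing width or
    SNR) is excluded. A width exactly at the threshold counts as RS: FS is
    defined by the strict inequality and RS as its complement among
    SNR-passing units.

    Returns a Series of labels indexed like ``units``.
    """
    if width_threshold <= 0 or snr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    width = pd.to_numeric(units.get("waveform_width_ms"), errors="coerce")
    snr = pd.to_numeric(units.get("snr"), errors="coerce")
    missing = width.isna() | snr.isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} unit(s) missing waveform width or SNR; "
            "labelled 'excluded'",
            stacklevel=2,
        )
    labels = pd.Series("excluded", index=units.index, dtype=object)
    ok = (~missing) & (snr > snr_threshold)
    labels[ok & (width >= width_threshold)] = "RS"
    labels[ok & (width < width_threshold)] = "FS"
    return labels


def bin_spikes(
    spikes: np.ndarray, duration: float, bin_width: float = 1.0 / DEFAULT_F
) -> np.ndarray:
    """Binarize spike times into half-open bins ``[b*Δ, (b+1)*Δ)``.

    A bin is 1 iff at least one spike lies inside it; multiple spikes in a
    bin collapse to 1. Length is ``round(duration / bin_width)``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size and np.any(np.diff(spikes) < 0):
        raise ValueError("spike times must be sorted ascending")
    if spikes.size and spikes[0] < 0:
        raise ValueError(f"negative spike time {spikes[0]}")
    n_bins = int(round(duration / bin_width))
    if spikes.size and spikes[-1] >= duration:
        raise ValueError(
            f"spike at t={spikes[-1]} s is at or beyond duration {duration} s"
        )
    out = np.zeros(n_bins, dtype=np.uint8)
    if spikes.size:
        idx = np.floor(spikes / bin_width).astype(int)
        # guard against float round-up at the last edge
        idx = np.minimum(idx, n_bins - 1)
        out[idx] = 1
    return out


def gaussian_kernel(
    kernel_sd: float = 0.010, kernel_cutoff: float = 0.025, f: float = DEFAULT_F
) -> np.ndarray:
    """Truncated Gaussian smoothing kernel, renormalized to sum to 1.

    Renormalizing after truncation conserves total mass, so a constant input
    maps to a constant output away from the series edges.
    """
    if kernel_cutoff < kernel_sd:
        raise ValueError("kernel_cutoff must be >= kernel_sd")
    half = int(round(kernel_cutoff * f))
    t = np.arange(-half, half + 1) / f
    k = np.exp(-0.5 * (t / kernel_sd) ** 2)
    return k / k.sum()


def smooth_rates(
    binary: np.ndarray,
    kernel_sd: float = 0.010,
    kernel_cutoff: float = 0.025,
    f: float = DEFAULT_F,
) -> np.ndarray:
    """Convolve a binary spike series with the Gaussian kernel, in spikes/s.

    Output has the same length as the input (zero-padded edges) and is
    scaled by the sampling rate ``f``, so an isolated spike integrates to 1
    and a spike in every bin gives a constant rate of ``f`` away from edges.
    Accepts a 1-D series or a units × bins array (smoothing along time).
    """
    kernel = gaussian_kernel(kernel_sd, kernel_cutoff, f)
    binary = np.asarray(binary, dtype=float)
    if binary.ndim == 1:
        return np.convolve(binary, kernel, mode="same") * f
    return np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="same"), 1, binary
    ) * f


def build_rate_matrix(
    table: SpikeTable,
    unit_ids=None,
    f: float = DEFAULT_F,
    kernel_sd: float = 0.010,
    kernel_cutoff: float = 0.025,
) -> RateMatrix:
    """Bin and smooth every requested unit into one :class:`RateMatrix`."""
    if unit_ids is None:
        unit_ids = table.unit_ids
    n_bins = int(round(table.session_duration * f))
    values = np.empty((len(unit_ids), n_bins))
    for i, uid in enumerate(unit_ids):
        b = bin_spikes(table.spikes[uid], table.session_duration, 1.0 / f)
        values[i] = smooth_rates(b, kernel_sd, kernel_cutoff, f)
    return RateMatrix(values, sampling_rate=f, t0=0.0, unit_ids=list(unit_ids))
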