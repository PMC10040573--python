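"""Synthetic inputs with the statistical structure the analyses assume.

Everything the pipeline consumes can be generated here: piecewise-constant
toy signals, full-field and per-pixel stimulus movies with stated
characteristic timescales (1.75 s gray / 0.25 s flashes, 250 ms gratings
and Gabors, 33 ms shuffled movies), rate-driven inhomogeneous Poisson spike
trains, jittered virtual-neuron ensembles, passive-viewing sessions, and
image change-detection sessions with hit/miss labels.

All generators are pure functions of (parameters, seed): the same seed
yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_F, SpikeTable

#: Categories understood by :func:`gen_stimulus`.
STIMULUS_CATEGORIES = (
    "gray",
    "flashes",
    "gabor",
    "static_gratings",
    "shuffled_movie",
    "natural_like",
)

_GRAY = 127.0


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_piecewise_constant(
    ct: float,
    duration: float,
    f: float = DEFAULT_F,
    value_range: tuple[int, int] = (0, 255),
    sparse: bool = False,
    active_fraction: float = 0.2,
    baseline: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Piecewise-constant signal resampled every ``ct`` seconds.

    Values are uniform integers over ``value_range``; consecutive segment
    values are forced distinct (redrawn on collision), so the realized
    constant-run duration equals ``ct`` exactly in the dense case. With
    ``sparse=True`` only a fraction ``active_fraction`` of segments take a
    random value; the rest sit at ``baseline`` (active values are forced to
    differ from the baseline too), so most of the window is constant —
    mimicking sparse signals such as the spiking of single neurons.
    """
    if ct < 2.0 / f:
        raise ValueError("ct must span at least 2 samples")
    rng = _rng(seed)
    lo, hi = value_range
    seg_samples = int(round(ct * f))
    n_total = int(round(duration * f))
    n_seg = math.ceil(n_total / seg_samples)
    values = np.empty(n_seg)
    prev = None
    for i in range(n_seg):
        if sparse and rng.random() >= active_fraction:
            v = float(baseline)
        else:
            v = float(rng.integers(lo, hi + 1))
            while v == prev or (sparse and v == baseline):
                v = float(rng.integers(lo, hi + 1))
        values[i] = v
        prev = v
    return np.repeat(values, seg_samples)[:n_total]


def gen_flashes_signal(
    n_cycles: int = 21, f: float = DEFAULT_F, seed=None
) -> np.ndarray:
    """Full-field flashes luminance trace: 1.75 s gray then 0.25 s flash.

    Each 2 s cycle holds gray (127) for 1.75 s then black (0) or white
    (255), drawn at random, for 0.25 s. The trace starts with a gray epoch
    and ends with a flash epoch, so the interior constant runs contain
    equally many gray and flash runs and their mean duration is exactly
    (1.75 + 0.25)/2 = 1 s.
    """
    rng = _rng(seed)
    gray_n = int(round(1.75 * f))
    flash_n = int(round(0.25 * f))
    parts = []
    for _ in range(n_cycles):
        parts.append(np.full(gray_n, _GRAY))
        parts.append(np.full(flash_n, 0.0 if rng.random() < 0.5 else 255.0))
    return np.concatenate(parts)


def gen_stimulus(
    category: str,
    duration: float,
    n_pixels: int = 64,
    f: float = DEFAULT_F,
    seed=None,
    natural_tau: float = 0.8,
    natural_rank: int = 3,
) -> np.ndarray:
    """Pixel movie (pixels × samples at ``f``) for one stimulus category.

    gray — constant mean luminance; flashes — full-field 1.75 s gray /
    0.25 s black-or-white; gabor / static_gratings — per-pixel piecewise
    constant with a 250 ms characteristic timescale; shuffled_movie — the
    same with a 1/30 s timescale; natural_like — a temporally correlated
    surrogate for natural movies (per-pixel AR(1) with correlation time
    ``natural_tau`` seconds driven through ``natural_rank`` shared spatial
    factors), which targets the relevant property of natural stimuli: high
    temporal correlation, hence lower pixelwise differentiation at 300 ms
    states than rapidly changing gratings.
    """
    rng = _rng(seed)
    n_t = int(round(duration * f))
    if category == "gray":
        return np.full((n_pixels, n_t), _GRAY)
    if category == "flashes":
        n_cycles = max(1, int(round(duration / 2.0)))
        row = gen_flashes_signal(n_cycles, f, rng)[:n_t]
        if row.size < n_t:  # pad with gray if duration is not a cycle multiple
            row = np.concatenate([row, np.full(n_t - row.size, _GRAY)])
        return np.tile(row, (n_pixels, 1))
    if category in ("gabor", "static_gratings", "shuffled_movie"):
        ct = 0.25 if category in ("gabor", "static_gratings") else 1.0 / 30.0
        return np.stack(
            [
                gen_piecewise_constant(ct, duration, f, seed=rng)
                for _ in range(n_pixels)
            ]
        )
    if category == "natural_like":
        phi = math.exp(-1.0 / (natural_tau * f))
        innov_sd = math.sqrt(1 - phi**2)
        factors = np.empty((natural_rank, n_t))
        z = rng.standard_normal(natural_rank)
        eps = rng.standard_normal((natural_rank, n_t)) * innov_sd
        for t in range(n_t):
            z = phi * z + eps[:, t]
            factors[:, t] = z
        loadings = rng.standard_normal((n_pixels, natural_rank))
        loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
        movie = _GRAY + 60.0 * loadings @ factors
        return np.clip(movie, 0.0, 255.0)
    raise ValueError(
        f"unknown stimulus category {category!r}; "
        f"expected one of {STIMULUS_CATEGORIES}"
    )


def gen_poisson_spikes(
    rate_signal: np.ndarray,
    duration: float,
    f: float = DEFAULT_F,
    seed=None,
) -> np.ndarray:
    """Inhomogeneous Poisson spike times by thinning.

    ``rate_signal`` gives the instantaneous rate in spikes/s sampled at
    ``f``; candidate events are drawn from a homogeneous process at the
    rate maximum and kept with probability rate(t)/max-rate. The expected
    spike count equals the time integral of the rate.
    """
    rate = np.asarray(rate_signal, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate_signal must be non-negative")
    rng = _rng(seed)
    rmax = rate.max(initial=0.0)
    if rmax == 0:
        return np.empty(0)
    n_cand = rng.poisson(rmax * duration)
    times = np.sort(rng.uniform(0.0, duration, n_cand))
    idx = np.minimum((times * f).astype(int), rate.size - 1)
    keep = rng.uniform(0.0, rmax, n_cand) < rate[idx]
    return times[keep]


def gen_virtual_ensemble(
    spikes: np.ndarray,
    n_copies: int,
    duration: float,
    jitter_sd: float = 0.0,
    offsets=None,
    seed=None,
) -> list[np.ndarray]:
    """Virtual neurons: copies of one spike train with jitter or offsets.

    Each copy is the original spike times plus i.i.d. Gaussian jitter (SD
    ``jitter_sd`` seconds, per spike) or plus a constant per-copy offset
    from ``offsets``. Times are clipped to the session bounds, so every
    copy keeps the original spike count.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rng = _rng(seed)
    spikes = np.asarray(spikes, dtype=float)
    hi = np.nextafter(duration, 0.0)
    out = []
    for i in range(n_copies):
        t = spikes.copy()
        if offsets is not None:
            t = t + offsets[i]
        if jitter_sd > 0:
            t = t + rng.normal(0.0, jitter_sd, t.size)
        out.append(np.sort(np.clip(t, 0.0, hi)))
    return out


def gen_ramp_ensemble(
    n_units: int,
    duration: float,
    f: float = DEFAULT_F,
    rate_range: tuple[float, float] = (5.0, 20.0),
    ct: float = 0.25,
    gain_range: tuple[float, float] = (0.2, 2.0),
    depth_range: tuple[float, float] = (0.1, 1.0),
    seed=None,
) -> list[np.ndarray]:
    """Spike trains whose overall excitability ramps linearly through time.

    Each unit fires as an inhomogeneous Poisson process with rate
    ``base_i · g(t) · (1 + m(t) · u_i(t))`` where ``u_i`` is a unit-specific
    piecewise-constant modulation in [−1, 1] with characteristic timescale
    ``ct`` and ``g``/``m`` ramp linearly over ``gain_range``/``depth_range``.
    Successive analysis windows therefore span a graded range of true
    differentiation — the construction used to check that per-window ND
    orderings are stable under analysis variants (e.g. tapering), where a
    stationary ensemble would only expose estimator noise.
    """
    rng = _rng(seed)
    n_t = int(round(duration * f))
    gain = np.linspace(*gain_range, n_t)
    depth = np.linspace(*depth_range, n_t)
    base = rng.uniform(*rate_range, n_units)
    out = []
    for i in range(n_units):
        u = gen_piecewise_constant(ct, duration, f, seed=rng) / 127.5 - 1.0
        rate = np.clip(base[i] * gain * (1.0 + depth * u), 0.0, None)
        out.append(gen_poisson_spikes(rate, duration, f, rng))
    return out


@dataclass
class SyntheticSessionSpec:
    """Parameters of a generated recording session.

    ``schedule`` lists (stimulus_name, duration_s) blocks for passive
    sessions; stimulus names follow the category map of the comparison
    stage. ``coupling`` sets the per-category modulation depth of unit
    firing rates (0 = no stimulus drive). ``hit_effect`` is the
    multiplicative amplitude of the rate transient on hit trials of
    change-detection sessions: in the 300 ms after a detected change, unit
    rates are multiplied by (1 + hit_effect).
    """

    n_units: int = 30
    rate_range: tuple[float, float] = (2.0, 10.0)
    schedule: list = field(
        default_factory=lambda: [
            ("gray", 30.0),
            ("flashes", 30.0),
            ("static_gratings", 30.0),
            ("shuffled_movie", 30.0),
            ("natural_movie", 30.0),
        ]
    )
    coupling: dict = field(default_factory=dict)
    hit_effect: float = 1.0
    n_changes: int = 40
    hit_rate: float = 0.5
    change_spacing: float = 4.0
    f: float = DEFAULT_F
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d in self.schedule):
            raise ValueError("schedule durations must be positive")
        if self.rate_range[0] < 0:
            raise ValueError("rates must be non-negative")
        if self.hit_effect < 0:
            raise ValueError("hit_effect must be >= 0")


#: Characteristic timescale (s) of the rate modulation driven by each
#: stimulus name in a passive session.
_STIMULUS_CT = {
    "gray": None,
    "flashes": 1.0,
    "gabor": 0.25,
    "gabors": 0.25,
    "static_gratings": 0.25,
    "drifting_gratings": 0.25,
    "shuffled_movie": 1.0 / 30.0,
    "shuffled_movies": 1.0 / 30.0,
    "natural_movie": 0.5,
    "natural_movies": 0.5,
}

_DEFAULT_COUPLING = {
    "gray": 0.0,
    "flashes": 0.5,
    "gabor": 0.5,
    "gabors": 0.5,
    "static_gratings": 0.8,
    "drifting_gratings": 0.8,
    "shuffled_movie": 0.8,
    "shuffled_movies": 0.8,
    "natural_movie": 0.8,
    "natural_movies": 0.8,
}


def gen_passive_session(
    spec: SyntheticSessionSpec,
) -> tuple[SpikeTable, pd.DataFrame]:
    """Passive-viewing session: spike table plus stimulus epoch table.

    Each unit's rate is its baseline times (1 + m·u_i(t)) where u_i is a
    unit-specific piecewise-constant modulation in [−1, 1] with the
    stimulus category's characteristic timescale and m the per-category
    coupling depth; spikes are then drawn as an inhomogeneous Poisson
    process. Epochs are returned as (start_s, end_s, stimulus_name) rows.
    """
    rng = _rng(spec.seed)
    f = spec.f
    duration = sum(d for _, d in spec.schedule)
    n_t = int(round(duration * f))
    baselines = rng.uniform(*spec.rate_range, spec.n_units)
    rates = np.tile(baselines[:, None], (1, n_t))
    epochs, t = [], 0.0
    for name, dur in spec.schedule:
        a, b = int(round(t * f)), int(round((t + dur) * f))
        ct = _STIMULUS_CT.get(name, 0.25)
        m = spec.coupling.get(name, _DEFAULT_COUPLING.get(name, 0.5))
        if ct is not None and m > 0:
            for i in range(spec.n_units):
                u = gen_piecewise_constant(
                    ct, dur, f, value_range=(0, 255), seed=rng
                )
                rates[i, a:b] *= 1.0 + m * (u / 127.5 - 1.0)
        epochs.append((t, t + dur, name))
        t += dur
    rates = np.clip(rates, 0.0, None)
    spikes = {
        f"u{i:03d}": gen_poisson_spikes(rates[i], duration, f, rng)
        for i in range(spec.n_units)
    }
    units = pd.DataFrame(
        {
            "area": "VISp",
            "layer": rng.choice(["2/3", "4", "5", "6"], spec.n_units),
            "waveform_width_ms": rng.uniform(0.45, 0.8, spec.n_units),
            "snr": rng.uniform(3.0, 6.0, spec.n_units),
            "mouse_id": "m000",
        },
        index=pd.Index(list(spikes), name="unit_id"),
    )
    table = SpikeTable(spikes=spikes, units=units, session_duration=duration)
    epoch_df = pd.DataFrame(epochs, columns=["start_s", "end_s", "stimulus"])
    return table, epoch_df


@dataclass
class ChangeDetectionSession:
    """Generated change-detection session."""

    spike_table: SpikeTable
    trials: pd.DataFrame  # change_time_s, outcome
    speed: pd.DataFrame  # time_s, speed_cm_s


def gen_change_detection_session(
    spec: SyntheticSessionSpec,
) -> ChangeDetectionSession:
    """Image change-detection session with hit/miss trials.

    Image changes occur every ``change_spacing`` seconds; each is labelled
    hit with probability ``hit_rate`` (Bernoulli). On hits, every unit's
    rate is multiplied by (1 + ``hit_effect``) for the 300 ms following the
    change — the simplest mechanism producing both the elevated firing and
    the elevated evoked differentiation that successful detection shows.
    The running-speed trace is smoothed non-negative noise.
    """
    rng = _rng(spec.seed)
    f = spec.f
    lead = 2.0
    duration = lead + spec.n_changes * spec.change_spacing + 2.0
    n_t = int(round(duration * f))
    change_times = lead + np.arange(spec.n_changes) * spec.change_spacing
    outcomes = np.where(
        rng.random(spec.n_changes) < spec.hit_rate, "hit", "miss"
    )
    baselines = rng.uniform(*spec.rate_range, spec.n_units)
    gain = np.ones(n_t)
    for t, o in zip(change_times, outcomes):
        if o == "hit":
            a = int(round(t * f))
            gain[a : a + int(round(0.3 * f))] = 1.0 + spec.hit_effect
    rates = baselines[:, None] * gain[None, :]
    spikes = {
        f"u{i:03d}": gen_poisson_spikes(rates[i], duration, f, rng)
        for i in range(spec.n_units)
    }
    units = pd.DataFrame(
        {
            "area": rng.choice(["VISp", "VISl", "VISal"], spec.n_units),
            "layer": rng.choice(["2/3", "4", "5", "6"], spec.n_units),
            "waveform_width_ms": rng.uniform(0.45, 0.8, spec.n_units),
            "snr": rng.uniform(3.0, 6.0, spec.n_units),
            "mouse_id": "m000",
        },
        index=pd.Index(list(spikes), name="unit_id"),
    )
    table = SpikeTable(spikes=spikes, units=units, session_duration=duration)
    trials = pd.DataFrame(
        {"change_time_s": change_times, "outcome": outcomes}
    )
    speed_t = np.arange(0.0, duration, 0.1)
    raw = rng.normal(0.0, 4.0, speed_t.size)
    kernel = np.exp(-0.5 * (np.arange(-20, 21) / 8.0) ** 2)
    smooth = np.convolve(raw, kernel / kernel.sum(), mode="same")
    speed = pd.DataFrame(
        {"time_s": speed_t, "speed_cm_s": np.abs(smooth)}
    )
    return ChangeDetectionSession(table, trials, speed)
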