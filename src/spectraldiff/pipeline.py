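"""Run orchestration: configuration, staged analyses, reproducible outputs.

A :class:`RunConfig` (YAML-serializable) describes inputs, differentiation
parameters, unit-class selection and statistical thresholds. Each ``run_*``
stage reads the tabular inputs, executes one analysis and writes CSV/JSON
outputs plus the resolved config and its hash, so a run can be reproduced
from its artifacts alone. Computation streams window by window; windows
are independent and may be computed in any order with identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, comparison, io, synthetic, timescales
from .differentiation import (
    DifferentiationConfig,
    bound_normalized,
    evoked_nd,
    nd_timeseries,
)
from .preprocess import build_rate_matrix, classify_units

logger = logging.getLogger(__name__)

FLOAT_FORMAT = io.FLOAT_FORMAT


@dataclass
class RunConfig:
    """Everything a run needs, serializable to one YAML file."""

    spikes_csv: str = "spikes.csv"
    units_csv: str = "units.csv"
    epochs_csv: str = "epochs.csv"
    speed_csv: str | None = None
    window: float = 3.0
    state: float = 0.3
    f: float = 200.0
    taper: str = "none"
    min_units: int = 10
    unit_class: str = "RS"
    width_threshold: float = 0.4
    snr_threshold: float = 2.5
    speed_threshold: float = 2.0
    alpha: float = 0.01
    s_grid_min: float = 0.010
    s_grid_max: float = 1.5
    s_grid_num: int = 20
    seed: int = 0
    simulate: dict = field(default_factory=dict)

    def diff_config(self) -> DifferentiationConfig:
        return DifferentiationConfig(
            window=self.window,
            state=self.state,
            f=self.f,
            taper=self.taper,
            min_units=self.min_units,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_summary(outdir: Path, config: RunConfig, extra: dict) -> None:
    summary = {
        "software_version": __version__,
        "config_hash": config.hash(),
        **extra,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    config.to_yaml(outdir / "config_resolved.yaml")


def _load_ensembles(config: RunConfig, indir: Path):
    """Read inputs and return (rate matrices per area, epochs, mean rate)."""
    table = io.read_spike_table(
        indir / config.spikes_csv, indir / config.units_csv
    )
    labels = classify_units(
        table.units, config.width_threshold, config.snr_threshold
    )
    selected = labels[labels == config.unit_class].index.astype(str)
    epochs = io.read_epochs(indir / config.epochs_csv)
    cats = comparison.assign_categories(epochs["stimulus"])
    epochs = epochs.assign(category=cats)
    rates = build_rate_matrix(table, list(selected), f=config.f)
    mean_rate = float(rates.values.mean())
    by_area = table.units.loc[selected, "area"]
    ensembles = {}
    for area, uids in by_area.groupby(by_area):
        ensembles[area] = rates.subset(list(uids.index))
    if len(ensembles) > 1:
        ensembles["all"] = rates
    return ensembles, epochs, mean_rate


def run_simulate(config: RunConfig, outdir) -> Path:
    """Generate a synthetic passive session and write the pipeline inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = synthetic.SyntheticSessionSpec(
        seed=config.seed, f=config.f, **config.simulate
    )
    table, epochs = synthetic.gen_passive_session(spec)
    io.write_spike_table(
        table, outdir / config.spikes_csv, outdir / config.units_csv
    )
    epochs.to_csv(
        outdir / config.epochs_csv, index=False, float_format=FLOAT_FORMAT
    )
    _write_summary(
        outdir,
        config,
        {"stage": "simulate", "n_units": spec.n_units, "seed": config.seed},
    )
    return outdir


def run_nd(config: RunConfig, indir, outdir) -> pd.DataFrame:
    """Per-area windowed ND over all epochs; writes nd.csv + summary."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.diff_config()
    ensembles, epochs, mean_rate = _load_ensembles(config, indir)
    epoch_rows = epochs.rename(
        columns={"start_s": "start_s", "end_s": "end_s"}
    )[["start_s", "end_s", "category"]]
    frames, bound_ok, max_amp = [], True, 0.0
    for area, mat in ensembles.items():
        t0 = time.perf_counter()
        if mat.n_units < cfg.min_units:
            logger.warning(
                "area %s has %d units, fewer than the %d-unit minimum; skipped",
                area,
                mat.n_units,
                cfg.min_units,
            )
            continue
        series = nd_timeseries(mat, epoch_rows, cfg, mean_rate=mean_rate)
        df = series.to_frame()
        df.insert(0, "area", area)
        frames.append(df)
        max_amp = max(max_amp, series.max_norm_amplitude)
        bound_ok &= bool(
            np.all(series.nd <= bound_normalized(max(max_amp, 1e-12), cfg.f))
        )
        logger.info(
            "ND for %s (%d units): %.2f s",
            area,
            mat.n_units,
            time.perf_counter() - t0,
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out.to_csv(outdir / "nd.csv", index=False, float_format=FLOAT_FORMAT)
    _write_summary(
        outdir,
        config,
        {
            "stage": "nd",
            "ensembles": {a: m.n_units for a, m in ensembles.items()},
            "ensemble_mean_rate": mean_rate,
            "bound_check": {
                "max_normalized_amplitude": max_amp,
                "all_windows_within_bound": bound_ok,
            },
        },
    )
    return out


def run_timescales(config: RunConfig, indir, outdir) -> pd.DataFrame:
    """ND-vs-S curves plus autocorrelation timescale fits per ensemble."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.diff_config()
    ensembles, epochs, mean_rate = _load_ensembles(config, indir)
    grid = timescales.default_state_grid(
        config.s_grid_min,
        min(config.s_grid_max, cfg.window / 2),
        config.s_grid_num,
        cfg.f,
    )
    rows, fits = [], {}
    for area, mat in ensembles.items():
        if mat.n_units < cfg.min_units:
            logger.warning(
                "area %s below the %d-unit minimum; skipped", area, cfg.min_units
            )
            continue
        curve = timescales.nd_vs_state_length(
            mat, cfg, grid, mean_rate=mean_rate
        )
        opt = timescales.detect_optimal_timescale(curve)
        for s, v in zip(curve.s_grid, curve.nd_values):
            rows.append((area, s, v))
        pop_rate = mat.values.mean(axis=0)
        try:
            lags, ac = timescales.autocorrelation(pop_rate, max_lag=2.0, f=cfg.f)
            fit = timescales.fit_characteristic_timescale(ac, lags)
            fit_info = asdict(fit)
        except ValueError as err:
            logger.warning("AC fit failed for %s: %s", area, err)
            fit_info = {"error": str(err)}
        fits[area] = {
            "optimal_timescale_s": opt.s_opt,
            "classification": opt.classification,
            "at_short_boundary": opt.at_short_boundary,
            "ac_fit": fit_info,
        }
    pd.DataFrame(rows, columns=["ensemble_id", "S_s", "nd"]).to_csv(
        outdir / "curves.csv", index=False, float_format=FLOAT_FORMAT
    )
    (outdir / "fits.json").write_text(json.dumps(fits, indent=2))
    _write_summary(outdir, config, {"stage": "timescales"})
    return pd.DataFrame(rows, columns=["ensemble_id", "S_s", "nd"])


def run_compare(config: RunConfig, indir, outdir) -> pd.DataFrame:
    """Pairwise category contrasts of window-level ND per ensemble."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nd = run_nd(config, indir, outdir)
    frames = {}
    for area, sub in nd.groupby("area"):
        samples = {
            c: g["nd"].to_numpy() for c, g in sub.groupby("category")
        }
        samples = {c: v for c, v in samples.items() if v.size >= 3}
        if len(samples) < 2:
            logger.warning("area %s has <2 usable categories; skipped", area)
            continue
        res = comparison.compare_groups(samples, alpha=config.alpha)
        df = res.pairwise.copy()
        df.insert(0, "area", area)
        frames[area] = df
    out = (
        pd.concat(frames.values(), ignore_index=True)
        if frames
        else pd.DataFrame()
    )
    out.to_csv(outdir / "pairwise.csv", index=False, float_format=FLOAT_FORMAT)
    _write_summary(outdir, config, {"stage": "compare"})
    return out


def run_behavior(config: RunConfig, outdir) -> pd.DataFrame:
    """Change-detection simulation + evoked hit/miss contrast."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = synthetic.SyntheticSessionSpec(
        seed=config.seed, f=config.f, **config.simulate
    )
    session = synthetic.gen_change_detection_session(spec)
    rates = build_rate_matrix(session.spike_table, f=config.f)
    nd = evoked_nd(rates, session.trials["change_time_s"].to_numpy())
    fr = np.array(
        [
            rates.values[
                :,
                int(round(t * config.f)) : int(round((t + 0.3) * config.f)),
            ].mean()
            for t in session.trials["change_time_s"]
        ]
    )
    trials = pd.DataFrame(
        {
            "ensemble": "all",
            "outcome": session.trials["outcome"],
            "nd": nd,
            "rate": fr,
        }
    )
    contrast = comparison.hit_miss_contrast(trials, alpha=config.alpha)
    contrast.to_csv(
        outdir / "hit_miss.csv", index=False, float_format=FLOAT_FORMAT
    )
    _write_summary(outdir, config, {"stage": "behavior"})
    return contrast


def run_all(config: RunConfig, outdir) -> dict:
    """simulate -> nd -> timescales -> compare -> behavior, one report."""
    outdir = Path(outdir)
    run_simulate(config, outdir / "inputs")
    nd = run_nd(config, outdir / "inputs", outdir / "nd")
    curves = run_timescales(config, outdir / "inputs", outdir / "timescales")
    pairwise = run_compare(config, outdir / "inputs", outdir / "compare")
    behavior = run_behavior(config, outdir / "behavior")
    _write_summary(outdir, config, {"stage": "all"})
    return {
        "nd": nd,
        "curves": curves,
        "pairwise": pairwise,
        "behavior": behavior,
    }
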