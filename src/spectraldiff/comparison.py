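"""Group contrasts of differentiation values with multiplicity control.

Window-level ND samples are grouped by stimulus category, brain area,
cortical layer or behavioral condition and compared pairwise:

* ``games_howell`` — Welch-type pairwise test with studentized-range
  reference distribution; appropriate for >= 3 groups with unequal
  variances and sizes.
* ``benjamini_hochberg`` — step-up false-discovery-rate control.
* ``hit_miss_contrast`` — per-ensemble Welch contrast of evoked ND (and of
  mean firing rate) between hit and miss trials, BH-corrected across
  ensembles.

Stimulus epochs are mapped onto five broad categories of increasing
putative meaningfulness (none, simple artificial, shuffled, complex
artificial, natural).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Raw stimulus name -> broad category of increasing putative meaningfulness.
CATEGORY_MAP = {
    "gray": "none",
    "spontaneous": "none",
    "flashes": "simple_artificial",
    "gabor": "simple_artificial",
    "gabors": "simple_artificial",
    "shuffled_movie": "shuffled",
    "shuffled_movies": "shuffled",
    "static_gratings": "complex_artificial",
    "drifting_gratings": "complex_artificial",
    "natural_movie": "natural",
    "natural_movies": "natural",
    "natural_like": "natural",
}

#: Category order by putative meaningfulness.
CATEGORY_ORDER = [
    "none",
    "simple_artificial",
    "shuffled",
    "complex_artificial",
    "natural",
]

#: Default running-speed threshold, cm/s.
DEFAULT_SPEED_THRESHOLD = 2.0


@dataclass
class ComparisonResult:
    """Pairwise group contrasts with BH-adjusted p-values and stars."""

    groups: list
    samples: dict
    pairwise: pd.DataFrame  # group_a, group_b, diff, p_raw, p_adj, stars

    def to_csv(self, path) -> None:
        self.pairwise.to_csv(path, index=False, float_format="%.10g")


def assign_categories(stimulus_names) -> list[str]:
    """Map raw stimulus names to the five broad categories.

    Unknown names raise, listing every offender.
    """
    names = list(stimulus_names)
    unknown = sorted({n for n in names if n not in CATEGORY_MAP})
    if unknown:
        raise ValueError(f"unmapped stimulus name(s): {', '.join(unknown)}")
    return [CATEGORY_MAP[n] for n in names]


def subsample_units(unit_ids, target_n: int, seed: int):
    """Uniform sample of ``target_n`` units without replacement.

    Used to match ensemble sizes of aggregate areas to individual areas.
    Reproducible under ``seed``; original order is preserved.
    """
    unit_ids = list(unit_ids)
    if target_n > len(unit_ids):
        raise ValueError(
            f"target_n={target_n} exceeds ensemble size {len(unit_ids)}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(unit_ids), size=target_n, replace=False))
    return [unit_ids[i] for i in idx]


def games_howell(groups, labels=None) -> pd.DataFrame:
    """Pairwise Games–Howell tests across ``groups`` (sequences of samples).

    For each pair the Welch statistic t = (m_i − m_j)/sqrt(v_i/n_i + v_j/n_j)
    with Welch–Satterthwaite degrees of freedom is referred to the
    studentized-range distribution with k = number of groups:
    p = P(Q_{k,df} > |t|·√2). Pairs involving a degenerate group (< 3
    observations or zero variance) get NaN p-values with a warning.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if labels is None:
        labels = list(range(k))
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        gi, gj = arrays[i], arrays[j]
        ni, nj = gi.size, gj.size
        vi = gi.var(ddof=1) if ni > 1 else 0.0
        vj = gj.var(ddof=1) if nj > 1 else 0.0
        diff = gi.mean() - gj.mean()
        if ni < 3 or nj < 3 or vi == 0 or vj == 0:
            warnings.warn(
                f"degenerate group in pair ({labels[i]}, {labels[j]}); "
                "p-value undefined",
                stacklevel=2,
            )
            rows.append((labels[i], labels[j], diff, np.nan, np.nan, np.nan))
            continue
        se2 = vi / ni + vj / nj
        t = diff / np.sqrt(se2)
        df = se2**2 / ((vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1))
        p = stats.studentized_range.sf(abs(t) * np.sqrt(2), k, df)
        rows.append((labels[i], labels[j], diff, t, df, float(np.clip(p, 0, 1))))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "diff", "t", "df", "p_raw"]
    )


def benjamini_hochberg(
    pvals, alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up procedure.

    Returns ``(reject, p_adjusted)`` with adjusted
    p_(i) = min_{j >= i} (m · p_(j) / j), capped at 1.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def significance_stars(p_adj) -> np.ndarray:
    """Three-level star coding of adjusted p-values.

    '*' for p < 0.01, '**' for p < 0.001, '***' for p < 0.0001.
    """
    p = np.asarray(p_adj, dtype=float)
    out = np.full(p.shape, "", dtype=object)
    out[p < 1e-2] = "*"
    out[p < 1e-3] = "**"
    out[p < 1e-4] = "***"
    return out


def compare_groups(
    samples: dict, alpha: float = 0.01
) -> ComparisonResult:
    """Games–Howell over labelled sample groups, BH-adjusted, starred."""
    labels = list(samples.keys())
    table = games_howell([samples[k] for k in labels], labels)
    ok = table["p_raw"].notna().to_numpy()
    p_adj = np.full(len(table), np.nan)
    if ok.any():
        _, p_adj[ok] = benjamini_hochberg(table.loc[ok, "p_raw"], alpha)
    table["p_adj"] = p_adj
    table["stars"] = significance_stars(np.where(np.isnan(p_adj), 1.0, p_adj))
    return ComparisonResult(groups=labels, samples=samples, pairwise=table)


def partition_by_running(
    windows,
    speed_times: np.ndarray,
    speed_values: np.ndarray,
    threshold: float = DEFAULT_SPEED_THRESHOLD,
) -> list[str]:
    """Label each (start_s, end_s) window running / stationary / unknown.

    A window is "running" iff the mean speed over it is >= ``threshold``
    (boundary counts as running); windows without any speed samples are
    "unknown".
    """
    speed_times = np.asarray(speed_times, dtype=float)
    speed_values = np.asarray(speed_values, dtype=float)
    labels = []
    for start, end in windows:
        mask = (speed_times >= start) & (speed_times < end)
        if not mask.any():
            labels.append("unknown")
        elif speed_values[mask].mean() >= threshold:
            labels.append("running")
        else:
            labels.append("stationary")
    return labels


def hit_miss_contrast(
    trials: pd.DataFrame,
    alpha: float = 0.01,
    value_cols: tuple[str, ...] = ("nd", "rate"),
) -> pd.DataFrame:
    """Hit-vs-miss contrast per ensemble, BH-corrected across ensembles.

    ``trials`` must carry columns ``ensemble``, ``outcome`` ("hit"/"miss")
    and the per-trial metrics named in ``value_cols`` (typically evoked ND
    and mean firing rate). For each ensemble and metric the difference of
    means (hit − miss) is tested with a two-sample Welch t-test; p-values
    are BH-adjusted across ensembles separately per metric. Ensembles with
    fewer than 3 trials of either outcome are skipped with a warning.

    Returns one row per ensemble with ``diff_<m>``, ``p_<m>``, ``p_adj_<m>``
    and ``stars_<m>`` columns for each metric ``m``.
    """
    rows = []
    for ens, sub in trials.groupby("ensemble", sort=False):
        hits = sub[sub["outcome"] == "hit"]
        miss = sub[sub["outcome"] == "miss"]
        if len(hits) < 3 or len(miss) < 3:
            warnings.warn(
                f"ensemble {ens!r} has fewer than 3 hit or miss trials; "
                "skipped",
                stacklevel=2,
            )
            continue
        row = {"ensemble": ens, "n_hit": len(hits), "n_miss": len(miss)}
        for col in value_cols:
            h = hits[col].dropna().to_numpy(float)
            m = miss[col].dropna().to_numpy(float)
            res = stats.ttest_ind(h, m, equal_var=False)
            row[f"diff_{col}"] = h.mean() - m.mean()
            row[f"p_{col}"] = res.pvalue
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    for col in value_cols:
        _, p_adj = benjamini_hochberg(out[f"p_{col}"], alpha)
        out[f"p_adj_{col}"] = p_adj
        out[f"reject_{col}"] = p_adj < alpha
        out[f"stars_{col}"] = significance_stars(p_adj)
    return out
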