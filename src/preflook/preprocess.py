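"""Conditioning of raw gaze into binned binary fixation series.

Fixed pipeline order: gap-aware Gaussian smoothing -> linear interpolation
onto a regular 20 ms grid (runs of missing data longer than 150 ms are never
reconstructed) -> AOI coding of each grid point against the screen-scaled
target/distractor boxes -> 100 ms binning of the two binary series ->
exclusion of trials with under 25% looking while the pictures are on screen.

Per bin, F is the number of target hits and N the number of grid points that
hit either AOI.  N deliberately counts only AOI samples (not all valid
samples) so that the chance level of p = F/N is exactly 0.5 in a
two-alternative display; valid off-AOI looks reduce N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    AOIBox,
    ConfigurationError,
    GazeTrial,
    TrialTimeline,
    aoi_boxes_for_screen,
)

__all__ = [
    "RegularSeries",
    "EmptyTrialError",
    "smooth_gaussian",
    "interpolate_resample",
    "code_aoi",
    "bin_series",
    "exclude_trials",
    "preprocess_trial",
    "preprocess_cohort",
    "SAMPLE_PERIOD_MS",
    "MAX_GAP_MS",
    "BIN_MS",
    "EXCLUSION_THRESHOLD",
    "EXCLUSION_WINDOW",
]

SAMPLE_PERIOD_MS = 20.0
MAX_GAP_MS = 150.0
BIN_MS = 100.0
EXCLUSION_THRESHOLD = 0.25
EXCLUSION_WINDOW = (0.0, 6000.0)


class EmptyTrialError(ValueError):
    """Raised when a trial has no valid samples to resample."""


@dataclass
class RegularSeries:
    """Gaze on a constant-period grid of relative time (0 = picture onset)."""

    t_rel: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    period: float = SAMPLE_PERIOD_MS

    def __len__(self) -> int:
        return len(self.t_rel)


def smooth_gaussian(trial: GazeTrial, sigma_samples: float = 5.0) -> GazeTrial:
    """Gap-aware Gaussian smoothing of both coordinate channels.

    The kernel (sigma in samples, truncated at 4*sigma) is renormalised over
    the valid neighbours of each sample, so missing runs neither shrink nor
    receive values; invalid samples stay invalid.
    """
    if sigma_samples <= 0:
        raise ValueError("sigma_samples must be > 0")
    valid = trial.valid
    n = len(trial)
    if n == 0 or not valid.any():
        return GazeTrial(
            trial.participant_id, trial.trial_index, trial.screen,
            trial.t_ms.copy(), trial.x.copy(), trial.y.copy(),
        )
    radius = int(np.ceil(4.0 * sigma_samples))
    k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma_samples) ** 2)
    k /= k.sum()

    def _same(a: np.ndarray) -> np.ndarray:
        # np.convolve 'same' returns the kernel length when the kernel is the
        # longer operand; slicing the full convolution keeps the signal length.
        return np.convolve(a, k, mode="full")[radius : radius + n]

    w = valid.astype(float)
    den = _same(w)

    def _channel(v: np.ndarray) -> np.ndarray:
        num = _same(np.where(valid, v, 0.0))
        out = np.full(n, np.nan)
        ok = valid & (den > 0)
        out[ok] = num[ok] / den[ok]
        return out

    return GazeTrial(
        trial.participant_id, trial.trial_index, trial.screen,
        trial.t_ms.copy(), _channel(trial.x), _channel(trial.y),
    )


def interpolate_resample(
    trial: GazeTrial,
    timeline: TrialTimeline | None = None,
    period: float = SAMPLE_PERIOD_MS,
    max_gap: float = MAX_GAP_MS,
) -> RegularSeries:
    """Linear interpolation onto a regular grid of relative time.

    Grid points are multiples of ``period``.  A grid point strictly inside a
    run between consecutive valid samples spaced more than ``max_gap`` apart
    is marked invalid (the strict inequality keeps a run of exactly
    ``max_gap`` interpolable).  No extrapolation happens beyond the first or
    last valid sample.
    """
    timeline = timeline or TrialTimeline()
    valid = trial.valid
    if not valid.any():
        raise EmptyTrialError(
            f"participant {trial.participant_id} trial {trial.trial_index}: no valid samples"
        )
    t_rel = timeline.to_relative(trial.t_ms)
    tv = t_rel[valid]
    xv = trial.x[valid]
    yv = trial.y[valid]

    start = np.ceil(tv[0] / period) * period
    grid = np.arange(start, tv[-1] + 0.5 * period, period)
    grid = grid[grid <= tv[-1]]
    if grid.size == 0:
        raise EmptyTrialError(
            f"participant {trial.participant_id} trial {trial.trial_index}: "
            "valid span shorter than one sample period"
        )
    xg = np.interp(grid, tv, xv)
    yg = np.interp(grid, tv, yv)

    ok = np.ones(grid.size, dtype=bool)
    if tv.size > 1:
        gaps = np.diff(tv)
        left = np.searchsorted(tv, grid, side="right") - 1
        left = np.clip(left, 0, tv.size - 2)
        on_sample = np.isin(grid, tv)
        inside_long_gap = (gaps[left] > max_gap) & ~on_sample
        ok &= ~inside_long_gap
    xg[~ok] = np.nan
    yg[~ok] = np.nan
    return RegularSeries(t_rel=grid, x=xg, y=yg, valid=ok, period=period)


def code_aoi(
    series: RegularSeries, target_box: AOIBox, distractor_box: AOIBox
) -> tuple[np.ndarray, np.ndarray]:
    """Binary AOI membership of each grid point (invalid points yield no flag).

    Boxes must already be scaled to the trial's screen and must not overlap.
    Box edges follow the half-open convention: left/top inside, right/bottom
    outside.
    """
    x_overlap = min(target_box.x_max, distractor_box.x_max) - max(
        target_box.x_min, distractor_box.x_min
    )
    y_overlap = min(target_box.y_max, distractor_box.y_max) - max(
        target_box.y_min, distractor_box.y_min
    )
    if x_overlap > 0 and y_overlap > 0:
        raise ConfigurationError("target and distractor AOIs overlap")
    tgt = target_box.contains(series.x, series.y) & series.valid
    dis = distractor_box.contains(series.x, series.y) & series.valid
    return tgt.astype(int), dis.astype(int)


def _bin_arrays(
    series: RegularSeries,
    target_flags: np.ndarray,
    distractor_flags: np.ndarray,
    bin_ms: float = BIN_MS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(t_start, F, N, n_grid) per present bin; numpy core of bin_series."""
    t = series.t_rel
    idx = np.floor(t / bin_ms).astype(int)
    offset = -idx.min()
    counts_grid = np.bincount(idx + offset)
    F = np.bincount(idx + offset, weights=target_flags, minlength=counts_grid.size)
    D = np.bincount(idx + offset, weights=distractor_flags, minlength=counts_grid.size)
    present = counts_grid > 0
    bin_ids = np.arange(counts_grid.size) - offset
    return (
        bin_ids[present] * bin_ms,
        F[present].astype(int),
        (F + D)[present].astype(int),
        counts_grid[present].astype(int),
    )


def bin_series(
    series: RegularSeries,
    target_flags: np.ndarray,
    distractor_flags: np.ndarray,
    bin_ms: float = BIN_MS,
) -> pd.DataFrame:
    """Aggregate the binary series into half-open [t, t + bin_ms) bins.

    Returns one row per bin with F (target hits), N (target + distractor
    hits), n_grid (all grid points in the bin, valid or not) and p = F/N
    (NaN when N = 0; such bins are dropped downstream).
    """
    t_start, F, N, n_grid = _bin_arrays(series, target_flags, distractor_flags, bin_ms)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(N > 0, F / np.where(N > 0, N, 1), np.nan)
    return pd.DataFrame({"t_start_rel": t_start, "F": F, "N": N, "n_grid": n_grid, "p": p})


def exclude_trials(
    bins: pd.DataFrame,
    threshold: float = EXCLUSION_THRESHOLD,
    window: tuple[float, float] = EXCLUSION_WINDOW,
    period: float = SAMPLE_PERIOD_MS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Drop trials with a looking fraction strictly below ``threshold``.

    The looking fraction is (AOI samples in the window) / (grid points the
    full window would hold at the nominal period), so missing data count
    against it even when the recorded grid is shorter than the window.
    Returns (kept, dropped, per-trial fractions).
    """
    lo, hi = window
    total_slots = int(round((hi - lo) / period))
    key = ["participant_id", "trial_index"]
    in_win = bins[(bins["t_start_rel"] >= lo) & (bins["t_start_rel"] < hi)]
    frac = (
        in_win.groupby(key, sort=False)["N"].sum().div(total_slots).rename("looking_fraction")
    ).reset_index()
    all_trials = bins[key].drop_duplicates()
    frac = all_trials.merge(frac, on=key, how="left").fillna({"looking_fraction": 0.0})
    frac["kept"] = frac["looking_fraction"] >= threshold
    kept_keys = frac.loc[frac["kept"], key]
    kept = bins.merge(kept_keys, on=key, how="inner")
    dropped = bins.merge(frac.loc[~frac["kept"], key], on=key, how="inner")
    return kept, dropped, frac


def preprocess_trial(
    trial: GazeTrial,
    timeline: TrialTimeline | None = None,
    sigma_samples: float = 5.0,
    period: float = SAMPLE_PERIOD_MS,
    max_gap: float = MAX_GAP_MS,
    bin_ms: float = BIN_MS,
    target_side: str = "left",
) -> pd.DataFrame:
    """Run the full pipeline on one trial; returns its bin table."""
    boxes = aoi_boxes_for_screen(trial.screen)
    left, right = boxes
    target_box = left if target_side == "left" else right
    distractor_box = right if target_side == "left" else left
    sm = smooth_gaussian(trial, sigma_samples=sigma_samples)
    series = interpolate_resample(sm, timeline=timeline, period=period, max_gap=max_gap)
    tgt, dis = code_aoi(series, target_box, distractor_box)
    out = bin_series(series, tgt, dis, bin_ms=bin_ms)
    out.insert(0, "participant_id", trial.participant_id)
    out.insert(1, "trial_index", trial.trial_index)
    return out


def preprocess_cohort(
    trials: list[GazeTrial],
    design: pd.DataFrame,
    timeline: TrialTimeline | None = None,
    sigma_samples: float = 5.0,
    period: float = SAMPLE_PERIOD_MS,
    max_gap: float = MAX_GAP_MS,
    bin_ms: float = BIN_MS,
    apply_exclusion: bool = True,
) -> pd.DataFrame:
    """Preprocess a whole cohort into the tidy bin table.

    ``design`` supplies condition, item, target side and group per trial.
    Trials with no valid samples are dropped (as are, optionally, trials
    failing the looking-time exclusion rule).
    """
    meta = design.set_index(["participant_id", "trial_index"])
    cols: dict[str, list] = {k: [] for k in (
        "participant_id", "group", "condition", "item_id", "trial_index",
        "t_start_rel", "F", "N", "n_grid",
    )}
    for trial in trials:
        key = (str(trial.participant_id), int(trial.trial_index))
        row = meta.loc[key]
        boxes = aoi_boxes_for_screen(trial.screen)
        left, right = boxes
        if str(row["target_side"]) == "left":
            target_box, distractor_box = left, right
        else:
            target_box, distractor_box = right, left
        try:
            sm = smooth_gaussian(trial, sigma_samples=sigma_samples)
            series = interpolate_resample(sm, timeline=timeline, period=period, max_gap=max_gap)
        except EmptyTrialError:
            continue
        tgt, dis = code_aoi(series, target_box, distractor_box)
        t_start, F, N, n_grid = _bin_arrays(series, tgt, dis, bin_ms)
        k = len(t_start)
        cols["participant_id"].append(np.repeat(trial.participant_id, k))
        cols["group"].append(np.repeat(str(row.get("group", "")), k))
        cols["condition"].append(np.repeat(str(row["condition"]), k))
        cols["item_id"].append(np.repeat(int(row["item_id"]), k))
        cols["trial_index"].append(np.repeat(int(trial.trial_index), k))
        cols["t_start_rel"].append(t_start)
        cols["F"].append(F)
        cols["N"].append(N)
        cols["n_grid"].append(n_grid)
    if not cols["F"]:
        return pd.DataFrame(
            columns=[
                "participant_id", "group", "condition", "item_id", "trial_index",
                "t_start_rel", "F", "N", "n_grid", "p",
            ]
        )
    table = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    with np.errstate(invalid="ignore", divide="ignore"):
        table["p"] = np.where(table["N"] > 0, table["F"] / table["N"].where(table["N"] > 0, 1), np.nan)
    if apply_exclusion:
        table, _, _ = exclude_trials(table, period=period)
    cols = [
        "participant_id", "group", "condition", "item_id", "trial_index",
        "t_start_rel", "F", "N", "n_grid", "p",
    ]
    return table.loc[:, cols]
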