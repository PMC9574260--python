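"""Synthetic webcam gaze with the statistical structure the pipeline assumes.

No raw recordings are distributed with the original study, so testing and
calibration run on generated cohorts that emulate its data structure: ~60 Hz
irregular sampling, ~100 px positional noise, missing-data runs, variable
screen geometry, and a logistic target-fixation time-course whose crossover
and asymptote differ by group (adult / TD / DS) and condition (CV / MV / UV).

The target-fixation probability is

    p(t) = baseline + (asymptote - baseline) / (1 + exp(-(t - c) / s))

with crossover c = crossover_ms + onset_shift_ms and logistic scale s, on
relative time (0 = picture onset).  Chance level is 0.5 before the
disambiguating word.  Unrelated-verb (UV) parameter sets anchor c after noun
onset (4000 ms), so anticipation appears only in the related conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .design import (
    AOIBox,
    GazeTrial,
    REFERENCE_GEOMETRY,
    ScreenGeometry,
    TrialSpec,
    TrialTimeline,
    aoi_boxes_for_screen,
    build_design,
    design_to_frame,
)

__all__ = [
    "SimParams",
    "default_group_params",
    "null_params",
    "target_curve",
    "sample_trial",
    "generate_cohort",
    "params_to_yaml",
    "params_from_yaml",
]


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for one group x condition cell.

    Amplitude/crossover defaults are set per group and condition by
    :func:`default_group_params`; sampling-noise defaults reflect the webcam
    tracker the study used (60 Hz maximum rate, ~100 px accuracy).
    """

    baseline_p: float = 0.5
    asymptote_p: float = 0.75
    crossover_ms: float = 2800.0
    slope_ms: float = 300.0
    onset_shift_ms: float = 0.0
    noise_sd_px: float = 100.0
    off_aoi_p: float = 0.08
    gap_rate: float = 0.01
    gap_mean_ms: float = 80.0
    sample_period_mean_ms: float = 16.7
    sample_jitter_sd_ms: float = 2.5
    subject_crossover_sd_ms: float = 150.0
    subject_asym_sd_logit: float = 0.3

    def __post_init__(self) -> None:
        for name in ("baseline_p", "asymptote_p", "off_aoi_p", "gap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.slope_ms <= 0:
            raise ValueError("slope_ms must be > 0")
        for name in ("gap_mean_ms", "sample_period_mean_ms", "noise_sd_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def default_group_params(group: str) -> dict[str, SimParams]:
    """Study-condition parameter sets per group.

    Orderings mirror the qualitative pattern of the task: adults and TD
    children anticipate in CV and MV (CV earlier/stronger than MV), the DS
    group anticipates in CV only and ~200 ms later than TD, and UV curves
    rise only after the noun (crossover anchored past 4000 ms relative).
    Amplitudes are unpublished; values here are chosen once as realistic for
    two-alternative preferential looking and are not tuned to any table.
    """
    base = SimParams()
    if group == "adult":
        return {
            "CV": replace(base, asymptote_p=0.80, crossover_ms=2400.0),
            "MV": replace(base, asymptote_p=0.78, crossover_ms=2500.0),
            "UV": replace(base, asymptote_p=0.80, crossover_ms=4700.0),
        }
    if group == "TD":
        return {
            "CV": replace(base, asymptote_p=0.78, crossover_ms=2600.0),
            "MV": replace(base, asymptote_p=0.74, crossover_ms=2900.0),
            "UV": replace(base, asymptote_p=0.78, crossover_ms=4800.0),
        }
    if group == "DS":
        # CV shifted +200 ms relative to TD; MV shows no anticipation (the
        # curve rises only after the noun, like UV).
        return {
            "CV": replace(base, asymptote_p=0.72, crossover_ms=2600.0, onset_shift_ms=200.0),
            "MV": replace(base, asymptote_p=0.72, crossover_ms=4900.0),
            "UV": replace(base, asymptote_p=0.72, crossover_ms=4900.0),
        }
    raise ValueError(f"unknown group {group!r}; expected adult/TD/DS")


def null_params() -> dict[str, SimParams]:
    """Flat-at-chance parameter sets (baseline = asymptote = 0.5) for all conditions."""
    flat = SimParams(baseline_p=0.5, asymptote_p=0.5)
    return {"CV": flat, "MV": flat, "UV": flat}


def target_curve(params: SimParams, t_rel) -> np.ndarray:
    """Probability of fixating the target at relative time ``t_rel`` (ms)."""
    t = np.asarray(t_rel, dtype=float)
    c = params.crossover_ms + params.onset_shift_ms
    with np.errstate(over="ignore"):  # extreme slopes saturate cleanly
        p = params.baseline_p + (params.asymptote_p - params.baseline_p) / (
            1.0 + np.exp(-(t - c) / params.slope_ms)
        )
    return p if p.shape else float(p)


def _gap_mask(n: int, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Missing-run indicator: Bernoulli gap starts, geometric run lengths."""
    invalid = np.zeros(n, dtype=bool)
    if params.gap_rate <= 0 or n == 0:
        return invalid
    # Geometric run-length parameter so mean gap length = gap_mean_ms.
    mean_len = max(params.gap_mean_ms / params.sample_period_mean_ms, 1.0)
    p_end = 1.0 / mean_len
    i = 0
    while i < n:
        run_valid = rng.geometric(params.gap_rate)  # samples until a gap starts
        i += run_valid
        if i >= n:
            break
        run_gap = rng.geometric(p_end)
        invalid[i : i + run_gap] = True
        i += run_gap
    return invalid


def _off_aoi_points(
    n: int, geometry: ScreenGeometry, boxes: tuple[AOIBox, AOIBox], rng: np.random.Generator
) -> np.ndarray:
    """Uniform points outside both AOIs, drawn from a 20% margin around the screen."""
    w, h = geometry.width_px, geometry.height_px
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max((n - got) * 2, 8)
        xs = rng.uniform(-0.2 * w, 1.2 * w, size=m)
        ys = rng.uniform(-0.2 * h, 1.2 * h, size=m)
        ok = ~(boxes[0].contains(xs, ys) | boxes[1].contains(xs, ys))
        k = min(int(ok.sum()), n - got)
        out[got : got + k, 0] = xs[ok][:k]
        out[got : got + k, 1] = ys[ok][:k]
        got += k
    return out


def sample_trial(
    params: SimParams,
    spec: TrialSpec,
    geometry: ScreenGeometry = REFERENCE_GEOMETRY,
    timeline: TrialTimeline | None = None,
    seed: int | np.random.Generator = 0,
) -> GazeTrial:
    """Simulate the raw gaze log of one trial.

    Timestamps are irregular (period jittered around the mean webcam period);
    at each sample the gaze lands uniformly off-AOI with probability
    ``off_aoi_p``, otherwise on the target AOI centre with probability
    ``target_curve(t)`` (the distractor centre otherwise), plus isotropic
    Gaussian noise.  Before picture onset and after picture offset the gaze
    rests at screen centre.  Missing runs start with ``gap_rate`` per sample
    and have geometric length with mean ``gap_mean_ms``.
    """
    timeline = timeline or TrialTimeline()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_max = int(timeline.trial_end_abs / max(params.sample_period_mean_ms, 1e-6)) + 8
    periods = rng.normal(params.sample_period_mean_ms, params.sample_jitter_sd_ms, size=n_max)
    periods = np.clip(periods, 1.0, None)
    t = np.cumsum(periods)
    t = t[t < timeline.trial_end_abs]
    n = len(t)

    boxes = aoi_boxes_for_screen(geometry)
    left, right = boxes
    target_box = left if spec.target_side == "left" else right
    distractor_box = right if spec.target_side == "left" else left

    t_rel = timeline.to_relative(t)
    in_picture = (t >= timeline.picture_onset_abs) & (
        t_rel < timeline.picture_offset_rel
    )

    p_t = target_curve(params, t_rel)
    on_target = rng.random(n) < p_t
    off_aoi = rng.random(n) < params.off_aoi_p

    x = np.where(on_target, target_box.center_x, distractor_box.center_x)
    y = np.where(on_target, target_box.center_y, distractor_box.center_y)
    # Outside the picture window the gaze rests at screen centre.
    x = np.where(in_picture, x, geometry.width_px / 2.0)
    y = np.where(in_picture, y, geometry.height_px / 2.0)

    k = int((off_aoi & in_picture).sum())
    if k:
        pts = _off_aoi_points(k, geometry, boxes, rng)
        sel = off_aoi & in_picture
        x[sel] = pts[:, 0]
        y[sel] = pts[:, 1]

    if params.noise_sd_px > 0:
        x = x + rng.normal(0.0, params.noise_sd_px, size=n)
        y = y + rng.normal(0.0, params.noise_sd_px, size=n)

    invalid = _gap_mask(n, params, rng)
    x[invalid] = np.nan
    y[invalid] = np.nan

    return GazeTrial(
        participant_id=spec.participant_id,
        trial_index=spec.trial_index,
        screen=geometry,
        t_ms=t,
        x=x,
        y=y,
    )


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def _inv_logit(z: float) -> float:
    return float(1.0 / (1.0 + np.exp(-z)))


def generate_cohort(
    n_subjects: int,
    group: str,
    params_by_condition: Mapping[str, SimParams] | None = None,
    seed: int = 0,
    geometry: ScreenGeometry = REFERENCE_GEOMETRY,
    timeline: TrialTimeline | None = None,
) -> tuple[list[GazeTrial], pd.DataFrame]:
    """Simulate a full cohort: one 28-trial design and gaze log per subject.

    Per-subject random effects — a Gaussian shift of the crossover (ms) and of
    the logit asymptote, shared across conditions — induce the
    between-subject variance the mixed models assume.  A single seed sequence
    is split per subject so cohorts are reproducible under subsetting.

    Returns the gaze trials and the design table (with a ``group`` column).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    params_by_condition = dict(params_by_condition or default_group_params(group))
    timeline = timeline or TrialTimeline()

    root = np.random.SeedSequence([int(seed) % (2**31), _group_code(group)])
    subject_seeds = root.spawn(n_subjects)

    trials: list[GazeTrial] = []
    design_frames = []
    for s in range(n_subjects):
        pid = f"{group}{s + 1:02d}"
        ss = subject_seeds[s]
        rng = np.random.default_rng(ss)
        any_params = next(iter(params_by_condition.values()))
        cross_shift = rng.normal(0.0, any_params.subject_crossover_sd_ms)
        asym_shift = rng.normal(0.0, any_params.subject_asym_sd_logit)
        subj_params = {
            cond: replace(
                p,
                crossover_ms=p.crossover_ms + cross_shift,
                asymptote_p=_inv_logit(_logit(p.asymptote_p) + asym_shift),
            )
            for cond, p in params_by_condition.items()
        }
        design = build_design(pid, order_id=(s % 4) + 1, seed=int(ss.generate_state(1)[0] % (2**31)))
        design_frames.append(design_to_frame(design).assign(group=group))
        for spec in design:
            trials.append(
                sample_trial(subj_params[spec.condition], spec, geometry, timeline, seed=rng)
            )
    design_df = pd.concat(design_frames, ignore_index=True)
    return trials, design_df


def _group_code(group: str) -> int:
    return {"adult": 1, "TD": 2, "DS": 3}.get(group, 9)


def params_to_yaml(params_by_condition: Mapping[str, SimParams]) -> str:
    return yaml.safe_dump({k: asdict(v) for k, v in params_by_condition.items()}, sort_keys=True)


def params_from_yaml(text: str) -> dict[str, SimParams]:
    raw = yaml.safe_load(text)
    return {k: SimParams(**v) for k, v in raw.items()}
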