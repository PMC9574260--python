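"""Experimental design, screen/AOI geometry, and gaze-table I/O.

The task is a two-picture preferential-looking experiment: on every trial a
target and a distractor picture share the screen while a spoken sentence
plays.  Sentences come in three conditions — a verb closely related to the
target noun (CV), moderately related (MV), or unrelated (UV) — drawn from an
inventory of 56 sentences (14 CV, 14 MV, 28 UV).  Each participant hears 28
of them: 7 CV, 7 MV and 14 UV, with every image pair shown exactly once.

All analysis windows run on *relative* time, where 0 ms is picture onset
(1000 ms into the 8000 ms trial); the verb starts at 2000 ms and the noun at
4000 ms relative time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialTimeline",
    "ScreenGeometry",
    "AOIBox",
    "TrialSpec",
    "GazeTrial",
    "ConfigurationError",
    "GazeParseError",
    "REFERENCE_GEOMETRY",
    "reference_aoi_boxes",
    "aoi_boxes_for_screen",
    "scale_aoi",
    "build_design",
    "sentence_inventory",
    "read_gaze_table",
    "write_gaze_table",
    "write_bins",
    "read_bins",
]


class ConfigurationError(ValueError):
    """Raised for invalid design / geometry configuration."""


class GazeParseError(ValueError):
    """Raised when a gaze table violates its contract; names the offending row."""


@dataclass(frozen=True)
class TrialTimeline:
    """Landmark times of one trial.

    Absolute times are measured from trial start; relative times from picture
    onset (relative = absolute - picture_onset_abs).
    """

    fixation_onset_abs: float = 0.0
    picture_onset_abs: float = 1000.0
    verb_onset_rel: float = 2000.0
    noun_onset_rel: float = 4000.0
    picture_offset_rel: float = 6000.0
    trial_end_abs: float = 8000.0

    def __post_init__(self) -> None:
        if not (0 <= self.fixation_onset_abs < self.picture_onset_abs):
            raise ConfigurationError("fixation onset must precede picture onset")
        if not (self.verb_onset_rel < self.noun_onset_rel < self.picture_offset_rel):
            raise ConfigurationError("verb < noun < picture offset required")
        if self.trial_end_abs < self.picture_onset_abs + self.picture_offset_rel:
            raise ConfigurationError("trial ends before picture offset")

    def to_relative(self, t_abs):
        return np.asarray(t_abs, dtype=float) - self.picture_onset_abs


@dataclass(frozen=True)
class ScreenGeometry:
    width_px: float
    height_px: float

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ConfigurationError("screen dimensions must be positive")


REFERENCE_GEOMETRY = ScreenGeometry(1920.0, 1080.0)


@dataclass(frozen=True)
class AOIBox:
    """Rectangular area of interest, located by its centre."""

    center_x: float
    center_y: float
    width: float
    height: float
    side: str = "left"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("AOI dimensions must be positive")
        if self.side not in ("left", "right"):
            raise ConfigurationError(f"unknown AOI side {self.side!r}")

    @property
    def x_min(self) -> float:
        return self.center_x - self.width / 2.0

    @property
    def x_max(self) -> float:
        return self.center_x + self.width / 2.0

    @property
    def y_min(self) -> float:
        return self.center_y - self.height / 2.0

    @property
    def y_max(self) -> float:
        return self.center_y + self.height / 2.0

    def contains(self, x, y):
        """Half-open membership: left/top edges inside, right/bottom outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min) & (x < self.x_max) & (y >= self.y_min) & (y < self.y_max)
        )


def reference_aoi_boxes() -> tuple[AOIBox, AOIBox]:
    """The two half-screen AOIs on the 1920x1080 reference display."""
    left = AOIBox(480.0, 540.0, 960.0, 1080.0, side="left")
    right = AOIBox(1440.0, 540.0, 960.0, 1080.0, side="right")
    return left, right


def scale_aoi(box: AOIBox, reference: ScreenGeometry, actual: ScreenGeometry) -> AOIBox:
    """Rescale an AOI from a reference display onto an actual display.

    Width/centre-x scale by actual.width/reference.width and height/centre-y
    by actual.height/reference.height, independently, so a 960x1080 half of a
    1920x1080 screen becomes an 800x1200 half of a 1600x1200 screen and its
    centre moves from (480, 540) to (400, 600).
    """
    fx = actual.width_px / reference.width_px
    fy = actual.height_px / reference.height_px
    return replace(
        box,
        center_x=box.center_x * fx,
        center_y=box.center_y * fy,
        width=box.width * fx,
        height=box.height * fy,
    )


def aoi_boxes_for_screen(actual: ScreenGeometry) -> tuple[AOIBox, AOIBox]:
    left, right = reference_aoi_boxes()
    return (
        scale_aoi(left, REFERENCE_GEOMETRY, actual),
        scale_aoi(right, REFERENCE_GEOMETRY, actual),
    )


# ---------------------------------------------------------------------------
# Design generation
# ---------------------------------------------------------------------------

N_CV_ITEMS = 14
N_MV_ITEMS = 14
N_UV_ITEMS = 28
N_ITEMS = N_CV_ITEMS + N_MV_ITEMS + N_UV_ITEMS  # 56
TRIALS_PER_PARTICIPANT = 28
CONDITION_COUNTS = {"CV": 7, "MV": 7, "UV": 14}


@dataclass(frozen=True)
class TrialSpec:
    participant_id: str
    trial_index: int
    condition: str
    item_id: int
    target_side: str
    order_id: int

    @property
    def image_pair(self) -> int:
        """UV sentences reuse the image pair of their predictive counterpart."""
        return item_id_to_pair(self.item_id)


def item_id_to_pair(item_id: int) -> int:
    if not 1 <= item_id <= N_ITEMS:
        raise ConfigurationError(f"item_id {item_id} outside 1..{N_ITEMS}")
    return item_id if item_id <= 28 else item_id - 28


def sentence_inventory() -> pd.DataFrame:
    """The 56-sentence inventory: 14 CV, 14 MV, 28 UV items.

    Items 1-14 are CV, 15-28 MV; UV item 28+k shares the image pair of
    predictive item k, mirroring the design in which unrelated sentences
    reuse the targets of the predictive ones.
    """
    rows = []
    for i in range(1, N_ITEMS + 1):
        cond = "CV" if i <= 14 else ("MV" if i <= 28 else "UV")
        rows.append({"item_id": i, "condition": cond, "image_pair": item_id_to_pair(i)})
    return pd.DataFrame(rows)


def build_design(participant_id: str, order_id: int, seed: int) -> list[TrialSpec]:
    """Assemble one participant's 28-trial list (7 CV, 7 MV, 14 UV).

    The four counterbalancing orders split the predictive items into two
    complementary halves: odd-numbered predictive items (orders 1 and 3) or
    even-numbered ones (orders 2 and 4) are heard in their predictive form,
    and the complementary image pairs appear as UV sentences, so each image
    pair occurs exactly once per participant and all 56 items are used across
    the rotation.  Presentation order and target side (balanced 14 left /
    14 right) are drawn from a seeded RNG; side counterbalancing is an
    assumption, not a documented property of the original procedure.
    """
    if order_id not in (1, 2, 3, 4):
        raise ConfigurationError(f"order_id must be in 1..4, got {order_id}")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), order_id, _stable_hash(participant_id)])
    )
    parity = 1 if order_id in (1, 3) else 0
    cv_items = [i for i in range(1, 15) if i % 2 == parity]
    mv_items = [i for i in range(15, 29) if i % 2 == parity]
    predictive = cv_items + mv_items
    uv_items = [28 + p for p in range(1, 29) if p not in predictive]

    conditions = ["CV"] * 7 + ["MV"] * 7 + ["UV"] * 14
    items = cv_items + mv_items + uv_items
    order = rng.permutation(TRIALS_PER_PARTICIPANT)
    sides = np.array(["left"] * 14 + ["right"] * 14)
    rng.shuffle(sides)

    trials = []
    for trial_index, k in enumerate(order, start=1):
        trials.append(
            TrialSpec(
                participant_id=str(participant_id),
                trial_index=trial_index,
                condition=conditions[k],
                item_id=items[k],
                target_side=str(sides[trial_index - 1]),
                order_id=order_id,
            )
        )
    return trials


def _stable_hash(s: str) -> int:
    """Deterministic small hash of a string (process-seed independent)."""
    h = 0
    for ch in str(s):
        h = (h * 31 + ord(ch)) % (2**31 - 1)
    return h


def design_to_frame(trials: Iterable[TrialSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": t.participant_id,
                "trial_index": t.trial_index,
                "condition": t.condition,
                "item_id": t.item_id,
                "target_side": t.target_side,
                "order_id": t.order_id,
            }
            for t in trials
        ]
    )


# ---------------------------------------------------------------------------
# Gaze tables
# ---------------------------------------------------------------------------

GAZE_COLUMNS = ["participant_id", "trial_index", "t_ms", "x_px", "y_px", "screen_w", "screen_h"]


@dataclass
class GazeTrial:
    """Raw irregular gaze samples for one trial.

    Invalid samples are kept in place with NaN coordinates so gap structure
    is preserved for the interpolation rule.
    """

    participant_id: str
    trial_index: int
    screen: ScreenGeometry
    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t_ms) == len(self.x) == len(self.y)):
            raise GazeParseError("t/x/y length mismatch")

    @property
    def valid(self) -> np.ndarray:
        return ~(np.isnan(self.x) | np.isnan(self.y))

    def __len__(self) -> int:
        return len(self.t_ms)


def read_gaze_table(path, delimiter: str = ",") -> list[GazeTrial]:
    """Read a long-format gaze CSV (one row per sample) into trials.

    Samples are sorted by timestamp within trial; duplicated timestamps are a
    contract violation and raise :class:`GazeParseError` naming the trial.
    Rows with blank x or y are retained as invalid samples.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise GazeParseError(f"gaze table {path} lacks columns {missing}")
    trials = []
    for (pid, tix), g in df.groupby(["participant_id", "trial_index"], sort=True):
        g = g.sort_values("t_ms", kind="mergesort")
        t = g["t_ms"].to_numpy(dtype=float)
        if np.any(np.isnan(t)):
            raise GazeParseError(f"participant {pid} trial {tix}: missing timestamp")
        dup = np.flatnonzero(np.diff(t) == 0)
        if dup.size:
            raise GazeParseError(
                f"participant {pid} trial {tix}: duplicated timestamp t={t[dup[0]]}"
            )
        screen = ScreenGeometry(float(g["screen_w"].iloc[0]), float(g["screen_h"].iloc[0]))
        trials.append(
            GazeTrial(
                participant_id=str(pid),
                trial_index=int(tix),
                screen=screen,
                t_ms=t,
                x=g["x_px"].to_numpy(dtype=float),
                y=g["y_px"].to_numpy(dtype=float),
            )
        )
    return trials


def write_gaze_table(path, trials: Sequence[GazeTrial], delimiter: str = ",") -> None:
    frames = []
    for tr in trials:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": tr.participant_id,
                    "trial_index": tr.trial_index,
                    "t_ms": tr.t_ms,
                    "x_px": tr.x,
                    "y_px": tr.y,
                    "screen_w": tr.screen.width_px,
                    "screen_h": tr.screen.height_px,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=GAZE_COLUMNS)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep=delimiter, index=False)


BIN_COLUMNS = [
    "participant_id",
    "group",
    "condition",
    "item_id",
    "trial_index",
    "t_start_rel",
    "F",
    "N",
    "n_grid",
    "p",
]


def write_bins(path, bins: pd.DataFrame, delimiter: str = ",") -> None:
    """Write the tidy bin table, the interchange format for all downstream stats."""
    missing = [c for c in BIN_COLUMNS if c not in bins.columns]
    if missing:
        raise ConfigurationError(f"bin table lacks columns {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bins.loc[:, BIN_COLUMNS].to_csv(path, sep=delimiter, index=False)


def read_bins(path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, delimiter=delimiter)
    missing = [c for c in BIN_COLUMNS if c not in df.columns]
    if missing:
        raise GazeParseError(f"bin table {path} lacks columns {missing}")
    return df
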