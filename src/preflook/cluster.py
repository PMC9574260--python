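"""Cluster-mass permutation inference on binned fixation proportions.

Per 100 ms bin, a t statistic is computed across subjects — paired (CV or MV
against UV) or one-sample against chance (0.5).  Maximal runs of contiguous
bins whose |t| exceeds a critical value (Student t quantile at alpha = 0.05,
df = n_subjects - 1) and whose t share one sign form clusters; each cluster's
mass is the sum of its member t values.  The null distribution records, per
permutation (condition-label swap for paired contrasts, sign flip for
one-sample), the maximum |mass| over all clusters; a cluster's p-value is the
add-one exceedance proportion (1 + #{perm max >= |mass|}) / (n_perm + 1).

Subject-level curves are the exchangeable unit.  Bins with an undefined t
(fewer than two complete subjects, or zero variance) break cluster
contiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TSeries",
    "ClusterResult",
    "subject_condition_curves",
    "t_series_paired",
    "t_series_one_sample",
    "find_clusters",
    "permutation_test",
    "critical_t_for",
    "cluster_report",
]

_VAR_FLOOR = 1e-24


@dataclass
class TSeries:
    """Per-bin t statistics over the analysis window (NaN where undefined)."""

    t_start: np.ndarray
    t: np.ndarray
    n_subjects: int
    bin_ms: float = 100.0


@dataclass
class ClusterResult:
    start_ms: float
    end_ms: float  # half-open over bins
    mass: float
    sign: int
    t_max: float
    p: float | None = None
    member_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def subject_condition_curves(
    bins: pd.DataFrame,
    window: tuple[float, float] = (0.0, 6000.0),
    bin_ms: float = 100.0,
) -> tuple[dict[str, np.ndarray], list, np.ndarray]:
    """Subject-level mean fixation-proportion curves per condition.

    Per subject, condition and bin, the curve is the mean of the per-trial
    proportions p = F/N over trials with N > 0.  Returns (curves, subjects,
    bin starts); each curves[cond] is a subjects x bins matrix with NaN where
    a subject has no usable trial in a bin.
    """
    lo, hi = window
    d = bins[(bins["t_start_rel"] >= lo) & (bins["t_start_rel"] < hi) & (bins["N"] > 0)]
    subjects = sorted(d["participant_id"].unique())
    starts = np.arange(lo, hi, bin_ms)
    curves: dict[str, np.ndarray] = {}
    for cond, g in d.groupby("condition"):
        m = (
            g.groupby(["participant_id", "t_start_rel"])["p"]
            .mean()
            .unstack("t_start_rel")
            .reindex(index=subjects, columns=starts)
        )
        curves[str(cond)] = m.to_numpy(dtype=float)
    return curves, subjects, starts


def _t_rows(signs: np.ndarray, data: np.ndarray) -> np.ndarray:
    """t statistics per bin for each row of per-subject sign assignments.

    ``data`` is subjects x bins with NaN for missing; ``signs`` is
    n_perm x subjects of +/-1.  Because a sign flip leaves each subject's
    squared value unchanged, every permutation's t is a function of the
    sign-weighted sum only.
    """
    mask = ~np.isnan(data)
    n = mask.sum(axis=0).astype(float)
    dz = np.where(mask, data, 0.0)
    ss = (dz**2).sum(axis=0)
    sums = signs @ dz  # n_perm x bins
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / n
        var = (ss - n * mean**2) / (n - 1.0)
        t = mean / np.sqrt(var / n)
    t[:, n < 2] = np.nan
    t[np.broadcast_to(var, t.shape) <= _VAR_FLOOR] = np.nan
    return t


def t_series_one_sample(
    curves: np.ndarray, mu: float = 0.5, t_start: np.ndarray | None = None, bin_ms: float = 100.0
) -> TSeries:
    """One-sample t per bin of subject curves against ``mu`` (chance = 0.5)."""
    d = np.asarray(curves, dtype=float) - mu
    t = _t_rows(np.ones((1, d.shape[0])), d)[0]
    if t_start is None:
        t_start = np.arange(d.shape[1]) * bin_ms
    return TSeries(t_start=np.asarray(t_start, float), t=t, n_subjects=d.shape[0], bin_ms=bin_ms)


def t_series_paired(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    t_start: np.ndarray | None = None,
    bin_ms: float = 100.0,
) -> TSeries:
    """Paired t per bin on subject-level differences (A - B).

    Subjects lacking valid data in a bin for either condition are dropped
    pairwise for that bin.
    """
    a = np.asarray(curves_a, dtype=float)
    b = np.asarray(curves_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired curves must have identical shape")
    d = a - b
    t = _t_rows(np.ones((1, d.shape[0])), d)[0]
    if t_start is None:
        t_start = np.arange(d.shape[1]) * bin_ms
    return TSeries(t_start=np.asarray(t_start, float), t=t, n_subjects=d.shape[0], bin_ms=bin_ms)


def critical_t_for(n_subjects: int, alpha: float = 0.05, override: float | None = None) -> float:
    """Two-tailed Student t critical value with df = n - 1.

    ``override`` accepts a literal value (e.g. a published 2.02/2.08) and is
    used verbatim when given.
    """
    if override is not None:
        return float(override)
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    return float(stats.t.ppf(1.0 - alpha / 2.0, n_subjects - 1))


def find_clusters(tseries: TSeries, critical_t: float) -> list[ClusterResult]:
    """Maximal contiguous runs of same-sign bins with |t| > critical_t."""
    if critical_t <= 0:
        raise ValueError("critical_t must be > 0")
    t = tseries.t
    above = np.abs(t) > critical_t
    above &= ~np.isnan(t)
    clusters: list[ClusterResult] = []
    i = 0
    n = len(t)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        s = np.sign(t[i])
        while j + 1 < n and above[j + 1] and np.sign(t[j + 1]) == s:
            j += 1
        members = np.arange(i, j + 1)
        tm = t[members]
        clusters.append(
            ClusterResult(
                start_ms=float(tseries.t_start[i]),
                end_ms=float(tseries.t_start[j] + tseries.bin_ms),
                mass=float(tm.sum()),
                sign=int(s),
                t_max=float(np.abs(tm).max()),
                member_bins=members,
            )
        )
        i = j + 1
    return clusters


def _max_cluster_mass_rows(t: np.ndarray, critical_t: float) -> np.ndarray:
    """Per row of a perms x bins t matrix, the maximum |cluster mass|."""
    P, B = t.shape
    above = np.abs(t) > critical_t
    above &= ~np.isnan(t)
    sgn = np.where(np.isnan(t), 0.0, np.sign(t))
    start = above.copy()
    start[:, 1:] &= ~(above[:, :-1] & (sgn[:, 1:] == sgn[:, :-1]))
    flat_above = above.ravel()
    flat_start = start.ravel()
    ids = np.cumsum(flat_start)
    out = np.zeros(P)
    if flat_above.any():
        masses = np.bincount(ids[flat_above], weights=t.ravel()[flat_above])
        rows_of_start = np.repeat(np.arange(P), B)[flat_start]
        np.maximum.at(out, rows_of_start, np.abs(masses[1:]))
    return out


def permutation_test(
    curves_a: np.ndarray,
    curves_b: np.ndarray | None = None,
    contrast: str = "one_sample",
    mu: float = 0.5,
    n_perm: int = 100_000,
    critical_t: float | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    t_start: np.ndarray | None = None,
    bin_ms: float = 100.0,
    chunk: int = 20_000,
) -> list[ClusterResult]:
    """Cluster-mass permutation test on subject-level curves.

    ``contrast`` is "paired" (curves_a vs curves_b; the label swap is a sign
    flip of per-subject differences) or "one_sample" (curves_a vs ``mu``).
    Per permutation the maximum |cluster mass| is recorded; each observed
    cluster gets p = (1 + #{perm max >= |mass|}) / (n_perm + 1) and the list
    of observed clusters (both signs) is returned, most massive first.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = np.asarray(curves_a, dtype=float)
    if contrast == "paired":
        if curves_b is None:
            raise ValueError("paired contrast needs curves_b")
        d = a - np.asarray(curves_b, dtype=float)
    elif contrast == "one_sample":
        d = a - mu
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    n_subjects = d.shape[0]
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if critical_t is None:
        critical_t = critical_t_for(n_subjects, alpha=alpha)

    if t_start is None:
        t_start = np.arange(d.shape[1]) * bin_ms
    obs = TSeries(
        t_start=np.asarray(t_start, float),
        t=_t_rows(np.ones((1, n_subjects)), d)[0],
        n_subjects=n_subjects,
        bin_ms=bin_ms,
    )
    clusters = find_clusters(obs, critical_t)
    if not clusters:
        return []

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(clusters), dtype=np.int64)
    done = 0
    obs_abs = np.array([abs(c.mass) for c in clusters])
    while done < n_perm:
        m = min(chunk, n_perm - done)
        signs = rng.choice(np.array([-1.0, 1.0]), size=(m, n_subjects))
        t = _t_rows(signs, d)
        perm_max = _max_cluster_mass_rows(t, critical_t)
        exceed += (perm_max[:, None] >= obs_abs[None, :]).sum(axis=0)
        done += m
    for c, e in zip(clusters, exceed):
        c.p = float((1 + e) / (n_perm + 1))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def cluster_report(
    clusters: list[ClusterResult], group: str = "", contrast: str = ""
) -> pd.DataFrame:
    """Tidy cluster table mirroring the in-text (t_cluster, t_max, p) format."""
    return pd.DataFrame(
        [
            {
                "group": group,
                "contrast": contrast,
                "start_ms": c.start_ms,
                "end_ms": c.end_ms,
                "mass": c.mass,
                "sign": c.sign,
                "t_max": c.t_max,
                "p": c.p,
            }
            for c in clusters
        ]
    )
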