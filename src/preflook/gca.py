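"""Growth curve analysis of binned target-fixation log-odds.

The time course inside the analysis window (default 4000-6000 ms relative to
picture onset) is modelled with third-order orthogonal polynomial time terms;
fixed effects are all time terms crossed with condition (and group when two
groups are present), dummy coded against the UV condition and the TD group.
The response is the empirical log-odds of each bin, log((F + c)/(N - F + c))
with a configurable boundary correction c (0.5 by default; c = 0 reproduces
the uncorrected log F/(N-F)).

Estimation uses a linear mixed model (statsmodels MixedLM) with the time-term
slopes varying by subject and an item intercept as a variance component — a
reproducible stand-in for a quasi-likelihood binomial fit.  MixedLM carries
no observation weights, so per-bin N weighting is exact only in the
degenerate no-random-effects rung of the backoff ladder (weighted least
squares); with 20 ms resampling and 100 ms bins N is nearly constant (at most
5), so the approximation is mild.  When the maximal random structure fails to
converge, a deterministic ladder drops the cubic, quadratic, then linear
subject slope, then all slopes, and finally falls back to WLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TimeBasis",
    "GCAModelSpec",
    "GCAFit",
    "orthogonal_time_basis",
    "empirical_log_odds",
    "random_structure_backoff",
    "fit_gca",
]


@dataclass(frozen=True)
class TimeBasis:
    """Orthonormal polynomial contrasts over equally spaced bins."""

    window: tuple[float, float]
    order: int
    columns: np.ndarray  # n_bins x order
    bin_starts: np.ndarray

    def frame(self) -> pd.DataFrame:
        names = ["ot1", "ot2", "ot3", "ot4", "ot5"][: self.order]
        out = pd.DataFrame(self.columns, columns=names)
        out.insert(0, "t_start_rel", self.bin_starts)
        return out


def orthogonal_time_basis(
    n_bins: int,
    order: int = 3,
    window: tuple[float, float] = (0.0, 0.0),
    bin_starts: np.ndarray | None = None,
) -> TimeBasis:
    """Orthonormal polynomial contrasts of degrees 1..order over n_bins bins.

    Columns are mutually orthogonal, sum to zero and have unit norm (the
    convention of R's poly()).  Signs are fixed so each column ends positive.
    """
    if n_bins <= order:
        raise ValueError(f"need n_bins > order, got {n_bins} <= {order}")
    t = np.arange(n_bins, dtype=float)
    powers = np.column_stack([t**k for k in range(order + 1)])
    q, _ = np.linalg.qr(powers)
    cols = q[:, 1 : order + 1]
    # deterministic sign: last element of each column positive
    flips = np.where(cols[-1, :] < 0, -1.0, 1.0)
    cols = cols * flips
    if bin_starts is None:
        bin_starts = t
    return TimeBasis(window=window, order=order, columns=cols, bin_starts=np.asarray(bin_starts))


def empirical_log_odds(F, N, correction: float = 0.5):
    """log((F + c)/(N - F + c)); with c = 0 this is the raw log F/(N-F).

    Undefined (NaN) where N = 0, or at the boundaries F = 0 / F = N when
    c = 0; such bins are dropped downstream.
    """
    F = np.asarray(F, dtype=float)
    N = np.asarray(N, dtype=float)
    num = F + correction
    den = N - F + correction
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((N > 0) & (num > 0) & (den > 0), np.log(num / den), np.nan)
    return out if out.shape else float(out)


@dataclass(frozen=True)
class GCAModelSpec:
    """Fixed/random structure of the growth-curve model.

    Fixed: all time terms x condition (x group when present), treatment-coded
    with UV and TD as references.  Random: time-term slopes by subject plus an
    item intercept (as a variance component); the ladder in
    :func:`random_structure_backoff` progressively simplifies the subject
    slopes when the fit does not converge.
    """

    order: int = 3
    window: tuple[float, float] = (4000.0, 6000.0)
    include_group: bool | None = None  # None = decide from the data
    item_intercept: bool = True
    correction: float = 0.5
    condition_reference: str = "UV"
    group_reference: str = "TD"


def random_structure_backoff(spec: GCAModelSpec) -> list[str]:
    """Deterministic ladder of subject random structures, maximal first.

    Entries are MixedLM re_formula strings; the final entry "none" denotes the
    weighted-least-squares fallback with no random effects.
    """
    terms = [f"ot{k}" for k in range(1, spec.order + 1)]
    ladder = []
    for keep in range(spec.order, 0, -1):
        ladder.append("~" + " + ".join(["1"] + terms[:keep]))
    ladder.append("~1")
    ladder.append("none")
    return ladder


@dataclass
class GCAFit:
    table: pd.DataFrame
    structure_used: str
    attempts: list[str]
    spec: GCAModelSpec
    n_obs: int
    converged: bool
    result: object = field(repr=False, default=None)


def _coef_table(params, bse, df_resid) -> pd.DataFrame:
    est = np.asarray(params, dtype=float)
    se = np.asarray(bse, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = est / se
    if df_resid > 1000:
        p = 2.0 * stats.norm.sf(np.abs(tval))
    else:
        p = 2.0 * stats.t.sf(np.abs(tval), df_resid)
    return pd.DataFrame(
        {
            "term": list(params.index),
            "estimate": est,
            "SE": se,
            "df": float(df_resid),
            "statistic": tval,
            "p": p,
        }
    )


def _prepare_gca_frame(bins: pd.DataFrame, spec: GCAModelSpec) -> pd.DataFrame:
    lo, hi = spec.window
    d = bins[(bins["t_start_rel"] >= lo) & (bins["t_start_rel"] <= hi) & (bins["N"] > 0)].copy()
    if d.empty:
        raise ValueError(f"no bins with data inside window {spec.window}")
    starts = np.sort(d["t_start_rel"].unique())
    basis = orthogonal_time_basis(len(starts), spec.order, spec.window, bin_starts=starts)
    d = d.merge(basis.frame(), on="t_start_rel", how="left")
    d["elog"] = empirical_log_odds(d["F"], d["N"], spec.correction)
    d = d.dropna(subset=["elog"])
    return d


def _fixed_formula(spec: GCAModelSpec, with_group: bool) -> str:
    terms = " + ".join(f"ot{k}" for k in range(1, spec.order + 1))
    cond = f"C(condition, Treatment('{spec.condition_reference}'))"
    f = f"elog ~ ({terms}) * {cond}"
    if with_group:
        grp = f"C(group, Treatment('{spec.group_reference}'))"
        f = f"elog ~ ({terms}) * {cond} * {grp}"
    return f


_TERM_RENAMES = {
    "C(condition, Treatment('UV'))[T.CV]": "CV",
    "C(condition, Treatment('UV'))[T.MV]": "MV",
    "C(group, Treatment('TD'))[T.DS]": "Group",
    "C(group, Treatment('TD'))[T.adult]": "Group",
    "ot1": "Linear",
    "ot2": "Quadratic",
    "ot3": "Cubic",
}


def _pretty_terms(names) -> list[str]:
    out = []
    for name in names:
        parts = [_TERM_RENAMES.get(p, p) for p in name.split(":")]
        out.append(":".join(parts))
    return out


def fit_gca(
    bins: pd.DataFrame,
    spec: GCAModelSpec | None = None,
    window: tuple[float, float] | None = None,
    structure: str | None = None,
) -> GCAFit:
    """Fit the growth-curve model to a tidy bin table.

    Walks the random-structure ladder until a structure converges; raises
    RuntimeError listing every attempted structure if none does (the WLS
    fallback always converges, so this is defensive).  ``structure`` pins a
    single rung of the ladder (e.g. "none" for the weighted-least-squares
    fit with no random effects) instead of walking it.
    """
    spec = spec or GCAModelSpec()
    if window is not None:
        spec = GCAModelSpec(**{**spec.__dict__, "window": window})
    d = _prepare_gca_frame(bins, spec)
    if d["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    with_group = (
        spec.include_group
        if spec.include_group is not None
        else ("group" in d.columns and d["group"].nunique() > 1)
    )
    single_condition = d["condition"].nunique() < 2
    formula = (
        _fixed_formula(spec, with_group)
        if not single_condition
        else "elog ~ " + " + ".join(f"ot{k}" for k in range(1, spec.order + 1))
    )

    vc = {"item": "0 + C(item_id)"} if spec.item_intercept and d["item_id"].nunique() > 1 else None
    ladder = [structure] if structure is not None else random_structure_backoff(spec)
    attempts: list[str] = []
    for re_formula in ladder:
        attempts.append(re_formula)
        try:
            if re_formula == "none":
                model = smf.wls(formula, data=d, weights=d["N"].to_numpy(dtype=float))
                res = model.fit()
                table = _coef_table(res.params, res.bse, res.df_resid)
                table["term"] = _pretty_terms(table["term"])
                return GCAFit(table, re_formula, attempts, spec, len(d), True, res)
            model = smf.mixedlm(
                formula, data=d, groups=d["participant_id"], re_formula=re_formula,
                vc_formula=vc,
            )
            res = model.fit(reml=True, method=["lbfgs", "bfgs"], maxiter=200)
            if not res.converged:
                continue
            fe = res.fe_params
            table = _coef_table(fe, res.bse_fe.loc[fe.index], res.df_resid)
            table["term"] = _pretty_terms(table["term"])
            return GCAFit(table, re_formula, attempts, spec, len(d), True, res)
        except (np.linalg.LinAlgError, ValueError):
            continue
    raise RuntimeError(f"no random structure converged; attempted {attempts}")
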