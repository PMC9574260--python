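"""Prediction-window aggregation, binomial mixed models and model comparison.

Target/AOI fixation counts are summed per trial over the prediction window
(default [2500, 4000) ms relative to picture onset: after the verb, before
the noun) and modelled as binomial counts F of N on the logit scale.  The
reference model has condition fixed effects (UV as the dummy-coded
reference), by-subject condition slopes and an item intercept.  Candidate
covariates (chronological age, mental age, production score, association
strength; each min-max normalised to [-0.5, 0.5]) enter as a main effect
plus covariate x condition interactions, and are judged by the chi-squared
likelihood-ratio test (df = 3: one main effect + two interaction dummies)
and by a BIC-approximated Bayes factor exp((BIC_ref - BIC_ext)/2), with
BF < 1/3 read as support for the null and BF > 3 as support for the
alternative.

Fitting uses lme4::glmer through Rscript (the canonical binomial-GLMM
estimator) with a deterministic random-structure backoff; a pure-Python
binomial GLM with subject-clustered robust errors is available as the
"glm" backend.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "WindowFit",
    "ModelComparisonResult",
    "aggregate_window",
    "minmax_center",
    "fit_window_model",
    "compare_models",
    "bic_bayes_factor",
    "chi2_comparison_p",
    "PREDICTION_WINDOW",
]

PREDICTION_WINDOW = (2500.0, 4000.0)


def aggregate_window(
    bins: pd.DataFrame, window: tuple[float, float] = PREDICTION_WINDOW
) -> pd.DataFrame:
    """Sum F and N per trial over the half-open prediction window.

    Trials with N = 0 in the window carry no information on the logit scale
    and are excluded.
    """
    lo, hi = window
    d = bins[(bins["t_start_rel"] >= lo) & (bins["t_start_rel"] < hi)]
    if d.empty:
        raise ValueError(f"no bins inside window {window}")
    keys = ["participant_id", "condition", "item_id", "trial_index"]
    if "group" in bins.columns:
        keys.insert(1, "group")
    agg = d.groupby(keys, sort=False, as_index=False)[["F", "N"]].sum()
    return agg[agg["N"] > 0].reset_index(drop=True)


def minmax_center(values) -> np.ndarray:
    """Min-max normalise to [-0.5, 0.5]: (x - min)/(max - min) - 0.5."""
    x = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        raise ValueError("minmax_center undefined for a constant vector")
    return (x - lo) / (hi - lo) - 0.5


@dataclass
class WindowFit:
    label: str
    table: pd.DataFrame  # term, estimate, SE, z, p
    loglik: float
    bic: float
    n_obs: int
    formula: str
    backend: str
    converged: bool
    messages: list[str]

    @property
    def minus2_loglik(self) -> float:
        return -2.0 * self.loglik


@dataclass
class ModelComparisonResult:
    label: str
    minus2_loglik: float
    statistic: float
    df_extra: int
    p: float
    bayes_factor: float | None = None
    warning: str | None = None


_R_FIT_SCRIPT = r"""
suppressMessages({library(lme4); library(jsonlite)})
args <- commandArgs(trailingOnly = TRUE)
dat <- read.csv(args[1])
formula_str <- args[2]
out_path <- args[3]
lv <- intersect(c("UV", "CV", "MV"), unique(as.character(dat$condition)))
dat$condition <- factor(dat$condition, levels = lv)
dat$participant_id <- factor(dat$participant_id)
dat$item_id <- factor(dat$item_id)
m <- suppressWarnings(glmer(as.formula(formula_str), data = dat, family = binomial,
           control = glmerControl(optimizer = "bobyqa", optCtrl = list(maxfun = 100000))))
s <- summary(m)
co <- s$coefficients
msgs <- unlist(m@optinfo$conv$lme4$messages)
if (is.null(msgs)) msgs <- character(0)
res <- list(terms = rownames(co), estimate = unname(co[, 1]), se = unname(co[, 2]),
            z = unname(co[, 3]), p = unname(co[, 4]),
            logLik = as.numeric(logLik(m)), bic = BIC(m), nobs = nobs(m),
            messages = msgs)
write(toJSON(res, digits = I(12)), out_path)
"""


def _glmer_random_ladder(with_condition_slope: bool, with_item: bool) -> list[str]:
    ladder = []
    if with_condition_slope and with_item:
        ladder.append("(condition | participant_id) + (1 | item_id)")
    if with_item:
        ladder.append("(1 | participant_id) + (1 | item_id)")
    ladder.append("(1 | participant_id)")
    return ladder


def _run_glmer(data: pd.DataFrame, fixed: str, random: str) -> dict:
    formula = f"cbind(F, N - F) ~ {fixed} + {random}"
    with tempfile.TemporaryDirectory() as td:
        td = Path(td)
        csv_path = td / "data.csv"
        out_path = td / "fit.json"
        r_path = td / "fit.R"
        data.to_csv(csv_path, index=False)
        r_path.write_text(_R_FIT_SCRIPT)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(r_path), str(csv_path), formula, str(out_path)],
            capture_output=True,
            text=True,
            timeout=600,
        )
        if proc.returncode != 0 or not out_path.exists():
            raise RuntimeError(f"glmer failed for {formula!r}: {proc.stderr[-2000:]}")
        res = json.loads(out_path.read_text())
    for key in ("logLik", "bic", "nobs"):
        v = res.get(key)
        res[key] = v[0] if isinstance(v, list) else v
    res["formula"] = formula
    return res


def _fit_glm_fallback(data: pd.DataFrame, fixed: str, label: str) -> WindowFit:
    """Binomial GLM with subject-clustered robust errors (no random effects)."""
    d = data.copy()
    d["condition"] = pd.Categorical(
        d["condition"], categories=[c for c in ["UV", "CV", "MV"] if c in set(d["condition"])]
    )
    formula = f"F + I(N - F) ~ {fixed}"
    endog = np.column_stack([d["F"], d["N"] - d["F"]])
    import patsy

    exog = patsy.dmatrix(fixed, d, return_type="dataframe")
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    res = model.fit(cov_type="cluster", cov_kwds={"groups": d["participant_id"].to_numpy()})
    z = res.params / res.bse
    table = pd.DataFrame(
        {
            "term": _rename_terms(list(res.params.index)),
            "estimate": res.params.to_numpy(),
            "SE": res.bse.to_numpy(),
            "z": z.to_numpy(),
            "p": 2 * stats.norm.sf(np.abs(z.to_numpy())),
        }
    )
    k = len(res.params)
    bic = -2 * res.llf + k * np.log(len(d))
    return WindowFit(
        label=label, table=table, loglik=float(res.llf), bic=float(bic), n_obs=len(d),
        formula=formula, backend="glm", converged=True, messages=[],
    )


_R_TERM_RENAMES = {
    "(Intercept)": "Intercept",
    "conditionCV": "CV",
    "conditionMV": "MV",
}


def _rename_terms(names: list[str]) -> list[str]:
    out = []
    for name in names:
        parts = name.split(":")
        parts = [
            _R_TERM_RENAMES.get(
                p,
                _R_TERM_RENAMES.get(p.replace("[T.CV]", "CV").replace("[T.MV]", "MV"), p),
            )
            for p in parts
        ]
        # patsy-style names
        parts = [
            p.replace("condition[T.CV]", "CV").replace("condition[T.MV]", "MV") for p in parts
        ]
        out.append(":".join(parts))
    return out


def fit_window_model(
    aggregates: pd.DataFrame,
    covariate: pd.Series | np.ndarray | None = None,
    covariate_name: str = "covariate",
    label: str | None = None,
    backend: str = "glmer",
    normalize_covariate: bool = True,
) -> WindowFit:
    """Fit the prediction-window binomial mixed model.

    ``aggregates`` is the per-trial table from :func:`aggregate_window`.
    ``covariate``, when given, must align with the rows of ``aggregates``
    (per-subject scores should be joined beforehand); it is min-max centred
    unless ``normalize_covariate`` is False, and enters as main effect plus
    condition interactions.  The glmer backend walks a deterministic
    random-structure ladder (condition slopes by subject + item intercept,
    then intercepts only) until lme4 reports a clean fit.
    """
    d = aggregates.copy()
    if d["participant_id"].nunique() < 2 or d["item_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects and 2 items")
    fixed = "condition"
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if len(cov) != len(d):
            raise ValueError("covariate must align with aggregate rows")
        d[covariate_name] = minmax_center(cov) if normalize_covariate else cov
        fixed = f"condition * {covariate_name}"
    label = label or ("Condition" if covariate is None else f"Condition x {covariate_name}")

    if backend == "glm":
        return _fit_glm_fallback(d, fixed, label)
    if backend != "glmer":
        raise ValueError(f"unknown backend {backend!r}")

    messages: list[str] = []
    last_err: Exception | None = None
    for random in _glmer_random_ladder(True, True):
        try:
            res = _run_glmer(d, fixed, random)
        except RuntimeError as err:
            last_err = err
            messages.append(str(err))
            continue
        bad = [m for m in res.get("messages", []) if "failed to converge" in m.lower()]
        table = pd.DataFrame(
            {
                "term": _rename_terms(list(res["terms"])),
                "estimate": np.asarray(res["estimate"], dtype=float),
                "SE": np.asarray(res["se"], dtype=float),
                "z": np.asarray(res["z"], dtype=float),
                "p": np.asarray(res["p"], dtype=float),
            }
        )
        fit = WindowFit(
            label=label, table=table, loglik=float(res["logLik"]), bic=float(res["bic"]),
            n_obs=int(res["nobs"]), formula=res["formula"], backend="glmer",
            converged=not bad, messages=messages + res.get("messages", []),
        )
        if not bad:
            return fit
        messages.extend(bad)
        fallback = fit  # keep the deepest structure that at least fitted
    if last_err is not None and "fallback" not in locals():
        raise RuntimeError(f"all glmer structures failed; last error: {last_err}")
    return fallback


def compare_models(
    fit_reference: WindowFit, fit_extended: WindowFit, df_extra: int = 3
) -> ModelComparisonResult:
    """Chi-squared likelihood-ratio comparison of nested fits.

    statistic = (-2 logLik_ref) - (-2 logLik_ext); p is the upper tail of
    chi2(df_extra).  A materially negative statistic signals a convergence
    problem in the extended fit and is flagged, with p reported as 1.
    """
    if df_extra < 1:
        raise ValueError("df_extra must be >= 1")
    statistic = fit_reference.minus2_loglik - fit_extended.minus2_loglik
    warning = None
    if statistic < -1e-6:
        warning = (
            f"extended model fits worse than reference (statistic {statistic:.4f}); "
            "likely convergence failure"
        )
    p = float(stats.chi2.sf(max(statistic, 0.0), df_extra))
    return ModelComparisonResult(
        label=fit_extended.label,
        minus2_loglik=fit_extended.minus2_loglik,
        statistic=float(statistic),
        df_extra=df_extra,
        p=p,
        warning=warning,
    )


def chi2_comparison_p(statistic: float, df_extra: int = 3) -> float:
    """Upper-tail chi-squared p for a printed likelihood-ratio statistic."""
    if df_extra < 1:
        raise ValueError("df_extra must be >= 1")
    return float(stats.chi2.sf(statistic, df_extra))


def bic_bayes_factor(fit_reference: WindowFit, fit_extended: WindowFit) -> tuple[float, str]:
    """BIC-approximated Bayes factor of extended over reference.

    BF = exp((BIC_ref - BIC_ext)/2); the verdict is "null-supported" when
    BF < 1/3, "alternative-supported" when BF > 3, else "inconclusive".
    """
    if fit_reference.n_obs != fit_extended.n_obs:
        raise ValueError("fits must be on identical data (n_obs differ)")
    bf = float(np.exp((fit_reference.bic - fit_extended.bic) / 2.0))
    if bf < 1.0 / 3.0:
        verdict = "null-supported"
    elif bf > 3.0:
        verdict = "alternative-supported"
    else:
        verdict = "inconclusive"
    return bf, verdict


def comparison_table(results: list[ModelComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "minus2_logLik": r.minus2_loglik,
                "statistic": r.statistic,
                "df": r.df_extra,
                "p": r.p,
                "bayes_factor": r.bayes_factor,
            }
            for r in results
        ]
    )
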