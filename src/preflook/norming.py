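"""Stimulus-norming statistics for the sentence validation studies.

Association strength is the percentage of norming respondents who produce the
expected word to a cue in a restricted association task (e.g. "write the
first verb that comes to mind for this noun"); the packaged item-level table
(28 image pairs: 14 closely-related-verb and 14 moderately-related-verb
items, each with its unrelated-verb counterpart) drives the stimulus-level
checks.  Rank-based tests (Kruskal-Wallis across conditions, Mann-Whitney U
post-hocs with switchable continuity and tie corrections) and the
strength-plausibility Pearson correlation follow the validation-study
workflow.  The reverse-direction validation (verb cue, noun response) reuses
the same scorer with the roles swapped.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResponseSet",
    "load_association_table",
    "normalize_word",
    "score_association",
    "kruskal_wallis",
    "mann_whitney",
    "strength_plausibility_correlation",
]


def load_association_table() -> pd.DataFrame:
    """The packaged item-level association-strength table (percent scale)."""
    with resources.files("preflook.data").joinpath("association_table.csv").open() as fh:
        return pd.read_csv(fh)


def normalize_word(word: str) -> str:
    """Case-fold and strip diacritics; no lemmatisation."""
    nfkd = unicodedata.normalize("NFD", str(word).strip().casefold())
    return "".join(ch for ch in nfkd if not unicodedata.combining(ch))


@dataclass(frozen=True)
class ResponseSet:
    """Responses of all norming respondents to one cue word."""

    cue: str
    responses: tuple[str, ...]
    expected: str

    def __post_init__(self) -> None:
        if len(self.responses) == 0:
            raise ValueError("a response set needs at least one respondent")


def score_association(
    responses: ResponseSet, matcher: Callable[[str, str], bool] | None = None
) -> float:
    """Association strength: 100 x (matching responses) / (total responses).

    The default matcher is exact string equality after case-folding and
    accent-stripping; a custom ``matcher(response, expected) -> bool`` can
    apply stricter or looser rules.
    """
    if matcher is None:
        matcher = lambda r, e: normalize_word(r) == normalize_word(e)  # noqa: E731
    hits = sum(1 for r in responses.responses if matcher(r, responses.expected))
    return 100.0 * hits / len(responses.responses)


def kruskal_wallis(groups: Sequence[Iterable[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-squared p-value."""
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def mann_whitney(
    g1: Iterable[float],
    g2: Iterable[float],
    continuity: bool = True,
    tie_correction: bool = True,
) -> tuple[float, float, float]:
    """Mann-Whitney U with a normal-approximation z (|z| reported).

    U counts pairwise wins of g1 over g2 plus half-ties.  The variance is
    tie-corrected when ``tie_correction`` and 0.5 is subtracted from
    |U - n1 n2 / 2| when ``continuity``.  Both corrections default to on,
    the convention that reproduces the published stimulus contrasts.
    Returns (U, |z|, two-sided p).
    """
    x = np.asarray(list(g1), dtype=float)
    y = np.asarray(list(g2), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    wins = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    u = float(wins + 0.5 * ties)

    n = n1 + n2
    var = n1 * n2 * (n + 1) / 12.0
    if tie_correction:
        _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u, 0.0, 1.0
    num = abs(u - n1 * n2 / 2.0)
    if continuity:
        num = max(num - 0.5, 0.0)
    z = num / np.sqrt(var)
    p = 2.0 * stats.norm.sf(z)
    return u, float(z), float(p)


def strength_plausibility_correlation(
    strengths: Iterable[float], plausibilities: Iterable[float]
) -> tuple[float, float]:
    """Pearson correlation between association strength and plausibility."""
    x = np.asarray(list(strengths), dtype=float)
    y = np.asarray(list(plausibilities), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length paired vectors, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
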