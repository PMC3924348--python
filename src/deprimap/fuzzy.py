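"""Fuzzy accuracy assessment of categorical maps.

Validation sites are 2x2-pixel windows compared against reference
imagery. Instead of a hard match/mismatch, each site receives a graded
score from 1 to 5 based on how much of the classified class is actually
present in the reference window:

    1  no match
    2  class present but < 50% of the window
    3  50% <= presence < 75%
    4  75% <= presence <= 90%
    5  presence > 90%

Sites whose reference window is too heterogeneous to carry a dominant
class are tallied in a dedicated "heterogeneous" column of the confusion
matrix. Summary statistics: overall fuzzy accuracy (share of sites at or
above the match threshold), weighted fuzzy accuracy (mean linearly
weighted score), per-class fuzzy user's and producer's accuracies, and
Cohen's unweighted kappa on the hard site-count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssessmentSite",
    "FuzzyConfusion",
    "AccuracyReport",
    "assign_fuzzy_score",
    "build_confusion",
    "summarize_accuracy",
    "cohens_kappa",
]

HETEROGENEOUS = "heterogeneous"

#: Default score -> weight map: linear from 0 (score 1) to 1 (score 5).
DEFAULT_SCORE_WEIGHTS: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class AssessmentSite:
    """One validation site.

    ``reference`` is the dominant class of the reference window, or ``None``
    when the window is too heterogeneous to call. ``presence_fraction`` is
    the fraction of the *classified* class present in the reference window.
    """

    site_id: int
    classified: str
    reference: str | None
    presence_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.presence_fraction <= 1.0):
            raise ValueError(
                f"site {self.site_id}: presence_fraction {self.presence_fraction} "
                "outside [0, 1]"
            )


def assign_fuzzy_score(presence_fraction: float, matches: bool) -> int:
    """Grade a site on the 1-5 fuzzy agreement scale.

    ``matches`` is False when the classified class is entirely absent from
    the reference window (score 1). Otherwise the score depends on the
    presence fraction; boundaries are closed as documented: 0.5 and 0.75
    belong to the higher bracket, 0.90 to score 4.
    """
    if not (0.0 <= presence_fraction <= 1.0):
        raise ValueError(f"presence fraction {presence_fraction} outside [0, 1]")
    if not matches:
        return 1
    if presence_fraction < 0.5:
        return 2
    if presence_fraction < 0.75:
        return 3
    if presence_fraction <= 0.90:
        return 4
    return 5


@dataclass
class FuzzyConfusion:
    """Score tallies per (classified class, reference class or heterogeneous)."""

    classes: tuple[str, ...]
    #: tallies[score-1][i, j]: sites classified as class i with reference column j;
    #: the last column is the heterogeneous category.
    tallies: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        k = len(self.classes)
        if self.tallies is None:
            self.tallies = np.zeros((5, k, k + 1), dtype=np.int64)

    @property
    def columns(self) -> tuple[str, ...]:
        return self.classes + (HETEROGENEOUS,)

    @property
    def n_sites(self) -> int:
        return int(self.tallies.sum())

    def hard_counts(self) -> np.ndarray:
        """Site counts summed over scores: shape (classes, classes + 1)."""
        return self.tallies.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.hard_counts(), index=list(self.classes),
                            columns=list(self.columns))


def build_confusion(sites: Iterable[AssessmentSite],
                    classes: Sequence[str] | None = None) -> FuzzyConfusion:
    """Tally sites into the fuzzy confusion matrix.

    Heterogeneous sites (no dominant reference class) go to the dedicated
    column; their fuzzy score still reflects the presence fraction of the
    classified class, scoring 1 when it is absent.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("no assessment sites given")
    if classes is None:
        seen: dict[str, None] = {}
        for s in sites:
            seen.setdefault(s.classified)
            if s.reference is not None:
                seen.setdefault(s.reference)
        classes = tuple(seen)
    confusion = FuzzyConfusion(classes=tuple(classes))
    index = {c: i for i, c in enumerate(confusion.classes)}
    for s in sites:
        if s.classified not in index:
            raise ValueError(f"site {s.site_id}: unknown classified class {s.classified!r}")
        i = index[s.classified]
        if s.reference is None:
            j = len(confusion.classes)
            matches = s.presence_fraction > 0.0
        else:
            if s.reference not in index:
                raise ValueError(f"site {s.site_id}: unknown reference class {s.reference!r}")
            j = index[s.reference]
            matches = (s.classified == s.reference) or s.presence_fraction > 0.0
        score = assign_fuzzy_score(s.presence_fraction, matches)
        confusion.tallies[score - 1, i, j] += 1
    return confusion


@dataclass
class AccuracyReport:
    overall_pct: float
    weighted_pct: float
    users_pct: dict[str, float | None]
    producers_pct: dict[str, float | None]
    kappa: float
    n_sites: int
    match_threshold: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": c, "users_accuracy_pct": self.users_pct.get(c),
             "producers_accuracy_pct": self.producers_pct.get(c)}
            for c in self.users_pct
        ]
        return pd.DataFrame(rows)


def cohens_kappa(counts: np.ndarray) -> float:
    """Cohen's unweighted kappa for a square (or padded) contingency table."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    k = min(counts.shape)
    po = np.trace(counts[:k, :k]) / n
    pe = float(counts.sum(axis=1)[:k] @ counts.sum(axis=0)[:k]) / n**2
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def summarize_accuracy(
    confusion: FuzzyConfusion,
    *,
    match_threshold: int = 3,
    score_weights: Sequence[float] = DEFAULT_SCORE_WEIGHTS,
) -> AccuracyReport:
    """Summary accuracies from a fuzzy confusion matrix.

    A site "matches" when its fuzzy score is at or above ``match_threshold``
    (default 3: at least half the window holds the mapped class). Weighted
    fuzzy accuracy averages the score-to-weight map over all sites. User's
    accuracy conditions on the classified label (rows), producer's accuracy
    on the reference dominant class (columns, heterogeneous excluded);
    classes with an empty row/column get ``None``. Kappa is computed on the
    hard counts with the heterogeneous column as an extra reference category
    that can never be predicted (it always counts against agreement).
    """
    if not (1 <= match_threshold <= 5):
        raise ValueError("match_threshold must be in 1..5")
    weights = np.asarray(score_weights, dtype=float)
    if weights.shape != (5,):
        raise ValueError("score_weights must have 5 entries")
    tallies = confusion.tallies
    n = confusion.n_sites
    if n == 0:
        raise ValueError("empty confusion matrix")
    k = len(confusion.classes)
    score_counts = tallies.sum(axis=(1, 2))  # per score 1..5
    matched = tallies[match_threshold - 1:].sum(axis=0)  # (k, k+1) site counts

    overall = 100.0 * matched.sum() / n
    weighted = 100.0 * float(score_counts @ weights) / n

    hard = confusion.hard_counts()
    users: dict[str, float | None] = {}
    producers: dict[str, float | None] = {}
    for i, c in enumerate(confusion.classes):
        row_n = hard[i].sum()
        users[c] = 100.0 * matched[i].sum() / row_n if row_n else None
        col_n = hard[:, i].sum()
        producers[c] = 100.0 * matched[:, i].sum() / col_n if col_n else None

    # kappa on the hard matrix, padded with an all-zero "heterogeneous" row so
    # the table is square; heterogeneous reference sites lower observed agreement.
    padded = np.vstack([hard, np.zeros((1, k + 1), dtype=np.int64)])
    kappa = cohens_kappa(padded)
    return AccuracyReport(
        overall_pct=overall,
        weighted_pct=weighted,
        users_pct=users,
        producers_pct=producers,
        kappa=kappa,
        n_sites=n,
        match_threshold=match_threshold,
    )


def sites_to_frame(sites: Iterable[AssessmentSite]) -> pd.DataFrame:
    rows = [
        {"site_id": s.site_id, "classified": s.classified,
         "reference": s.reference if s.reference is not None else HETEROGENEOUS,
         "presence_fraction": s.presence_fraction}
        for s in sites
    ]
    return pd.DataFrame(rows)


def sites_from_frame(df: pd.DataFrame) -> list[AssessmentSite]:
    required = {"site_id", "classified", "reference", "presence_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sites table missing columns {sorted(missing)}")
    return [
        AssessmentSite(
            site_id=int(r.site_id),
            classified=str(r.classified),
            reference=None if str(r.reference) == HETEROGENEOUS else str(r.reference),
            presence_fraction=float(r.presence_fraction),
        )
        for r in df.itertuples()
    ]
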