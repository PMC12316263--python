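"""Inter-rater agreement and human-vs-classifier comparison.

Fleiss' kappa measures chance-corrected agreement among a fixed number of
raters assigning items to nominal categories (here the three QC statuses).
With ``counts[i][j]`` the number of raters placing item *i* in category *j*
and *n* raters per item:

    P_i   = (sum_j counts[i][j]^2 - n) / (n (n - 1))     per-item agreement
    p_j   = sum_i counts[i][j] / (N n)                   category prevalence
    p_bar = mean_i P_i
    p_e   = sum_j p_j^2                                  chance agreement
    kappa = (p_bar - p_e) / (1 - p_e)

Kappa values are conventionally banded on the Landis–Koch scale (fair for
0.21–0.4, moderate for 0.41–0.6, substantial for 0.61–0.8, almost perfect
above 0.8).

For comparison against an automated pass/fail classifier (e.g. image-quality
classifiers trained on MRIQC metrics), three-state human ratings are first
binarized under an explicit maybe-policy, then tallied into a 2x2 confusion
matrix with marginals and percent agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .qc_store import QCTable

__all__ = [
    "RatingPanel",
    "KappaResult",
    "ConfusionMatrix2x2",
    "CoverageError",
    "DEFAULT_CATEGORIES",
    "build_panel",
    "fleiss_kappa",
    "landis_koch_band",
    "binarize",
    "confusion",
]

DEFAULT_CATEGORIES = ("yes", "maybe", "no")

# Landis–Koch banding. The quoted edges (fair 0.21–0.4, moderate 0.41–0.6,
# substantial 0.61–0.8, almost perfect > 0.8) are closed on their interval
# ends; the two-decimal gaps between bands (e.g. 0.405) join the band below
# their upper edge so the partition is exhaustive. Names below "fair"
# (slight/poor) are collapsed into one open-ended bottom band.
BAND_FLOOR = "slight or worse"


class CoverageError(ValueError):
    """Rater tables do not cover the identical set of outputs."""


@dataclass(frozen=True)
class RatingPanel:
    """N items x k categories count matrix with a constant rater count."""

    counts: np.ndarray
    categories: tuple[str, ...] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] < 1:
            raise ValueError(f"counts must be an N x k matrix, got shape {counts.shape}")
        if counts.shape[1] != len(self.categories):
            raise ValueError("counts columns must match the category list")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        row_sums = counts.sum(axis=1)
        if not np.all(row_sums == row_sums[0]):
            raise ValueError("every item must have the same number of raters")
        if row_sums[0] < 2:
            raise ValueError("Fleiss' kappa needs at least 2 raters per item")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "categories", tuple(self.categories))

    @property
    def n_items(self) -> int:
        return self.counts.shape[0]

    @property
    def n_raters(self) -> int:
        return int(self.counts.sum(axis=1)[0])


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_bar: float        # mean observed per-item agreement
    p_e: float          # expected agreement by chance
    band: str
    degenerate: bool = False  # all ratings in one category


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Human (rows) vs machine (columns) pass/reject tallies."""

    a: int  # both pass
    b: int  # human pass / machine reject
    c: int  # human reject / machine pass
    d: int  # both reject

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_totals(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def percent_agreement(self) -> float:
        return 100.0 * (self.a + self.d) / self.total if self.total else float("nan")


def build_panel(tables: Sequence[QCTable],
                categories: Sequence[str] = DEFAULT_CATEGORIES) -> RatingPanel:
    """Tally one QC table per rater into a rating-count panel.

    All tables must cover the identical identifier set; items are ordered
    lexicographically by full identifier key.
    """
    if len(tables) < 2:
        raise ValueError("need at least two raters")
    key_sets = [set(r.identifier.key for r in t.records()) for t in tables]
    universe = key_sets[0]
    for ks in key_sets[1:]:
        if ks != universe:
            diff = sorted(universe.symmetric_difference(ks))
            raise CoverageError(f"rater tables disagree on outputs: {diff}")
    cat_index = {c: j for j, c in enumerate(categories)}
    keys = sorted(universe)
    counts = np.zeros((len(keys), len(categories)), dtype=int)
    key_row = {k: i for i, k in enumerate(keys)}
    for t in tables:
        for rec in t.records():
            counts[key_row[rec.identifier.key], cat_index[rec.status]] += 1
    return RatingPanel(counts=counts, categories=tuple(categories))


def fleiss_kappa(panel: RatingPanel) -> KappaResult:
    """Chance-corrected multi-rater agreement on nominal categories.

    When every rating falls in a single category, p_e == 1 and the ratio is
    undefined; the raters nonetheless agree perfectly, so kappa is reported
    as 1 with ``degenerate`` set.
    """
    counts = panel.counts.astype(float)
    N, _ = counts.shape
    n = panel.n_raters
    P_i = (np.sum(counts ** 2, axis=1) - n) / (n * (n - 1))
    p_j = counts.sum(axis=0) / (N * n)
    p_bar = float(P_i.mean())
    p_e = float(np.sum(p_j ** 2))
    if p_e >= 1.0:
        return KappaResult(kappa=1.0, p_bar=p_bar, p_e=1.0,
                           band=landis_koch_band(1.0), degenerate=True)
    kappa = (p_bar - p_e) / (1.0 - p_e)
    return KappaResult(kappa=float(kappa), p_bar=p_bar, p_e=p_e,
                       band=landis_koch_band(kappa))


def landis_koch_band(kappa: float) -> str:
    """Landis–Koch agreement label for a kappa value (rounded to 3 decimals).

    Edges: fair 0.21–0.4, moderate 0.41–0.6, substantial 0.61–0.8, almost
    perfect > 0.8; anything below fair is reported as "slight or worse".
    """
    if kappa > 1.0 + 1e-12:
        raise ValueError(f"kappa cannot exceed 1: {kappa}")
    k = round(float(kappa), 3)
    if k > 0.8:
        return "almost perfect"
    if k > 0.6:
        return "substantial"
    if k > 0.4:
        return "moderate"
    if k >= 0.21:
        return "fair"
    return BAND_FLOOR


def binarize(statuses: Sequence[str], maybe_policy: str = "as_pass"
             ) -> tuple[list[str], int]:
    """Collapse three-state statuses to pass/reject labels.

    ``yes`` → pass, ``no`` → reject; ``maybe`` follows the policy
    (``as_pass``, ``as_reject`` or ``drop``).  Returns the labels and the
    number of dropped items; under ``drop`` the caller must subset the
    machine labels identically.
    """
    if maybe_policy not in ("as_pass", "as_reject", "drop"):
        raise ValueError(f"bad maybe_policy: {maybe_policy!r}")
    out: list[str] = []
    dropped = 0
    for s in statuses:
        if s == "yes":
            out.append("pass")
        elif s == "no":
            out.append("reject")
        elif s == "maybe":
            if maybe_policy == "drop":
                dropped += 1
            else:
                out.append("pass" if maybe_policy == "as_pass" else "reject")
        else:
            raise ValueError(f"invalid status: {s!r}")
    return out, dropped


def confusion(human: Sequence[str], machine: Sequence[str]) -> ConfusionMatrix2x2:
    """2x2 confusion matrix of human vs machine pass/reject labels.

    Inputs must be aligned by identifier and of equal length.
    """
    if len(human) != len(machine):
        raise ValueError(
            f"label vectors differ in length: {len(human)} vs {len(machine)}")
    tally = {("pass", "pass"): 0, ("pass", "reject"): 0,
             ("reject", "pass"): 0, ("reject", "reject"): 0}
    for h, m in zip(human, machine):
        if h not in ("pass", "reject") or m not in ("pass", "reject"):
            raise ValueError(f"labels must be pass/reject, got {(h, m)!r}")
        tally[(h, m)] += 1
    return ConfusionMatrix2x2(
        a=tally[("pass", "pass")], b=tally[("pass", "reject")],
        c=tally[("reject", "pass")], d=tally[("reject", "reject")])
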