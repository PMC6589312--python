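"""Quadratic-weighted Cohen's kappa on grade panels.

The agreement statistic throughout is the quadratic-weighted kappa on the
fixed four-category severity scale: disagreement between grades i and j is
penalised by (i-j)^2 / 9, so a one-step disagreement costs little and a
none-vs-advanced disagreement costs fully.  Categories absent from a
particular panel still occupy their slots, so values are comparable across
panels.

Images a rater called ungradable, or did not rate, are excluded from each
pairwise computation and counted.  Exclusion is *pairwise* by default; the
grader-qualification screen uses *listwise* exclusion (drop an image if any
rater in the qualification set failed to grade it), matching how a shared
reference image set is built before certifying graders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .panels import MISSING, ORDINAL_GRADES, UNGRADABLE, GradePanel

__all__ = [
    "AgreementError",
    "WeightedKappaResult",
    "KappaMatrix",
    "weighted_kappa",
    "pairwise_kappa_matrix",
    "qualify_graders",
]


class AgreementError(ValueError):
    """Kappa computation impossible on the given data."""


def _is_ordinal(label: object) -> bool:
    return not (label is UNGRADABLE or label is MISSING)


@dataclass(frozen=True)
class WeightedKappaResult:
    """Quadratic-weighted kappa between two raters, with exclusion tallies."""

    kappa: float
    n_used: int
    n_excluded: int

    def __float__(self) -> float:
        return self.kappa


def _paired_grades(
    panel: GradePanel,
    rater_x: str,
    rater_y: str,
    restrict_to: Iterable[str] | None,
) -> tuple[np.ndarray, np.ndarray, int]:
    rx = panel.ratings(rater_x)
    ry = panel.ratings(rater_y)
    common = set(rx) & set(ry)
    if restrict_to is not None:
        common &= set(restrict_to)
    a, b = [], []
    n_excluded = 0
    for img in sorted(common):
        ga, gb = rx[img], ry[img]
        if _is_ordinal(ga) and _is_ordinal(gb):
            a.append(int(ga))
            b.append(int(gb))
        else:
            n_excluded += 1
    return np.asarray(a, dtype=int), np.asarray(b, dtype=int), n_excluded


def quadratic_weighted_kappa(a: Sequence[int], b: Sequence[int]) -> float:
    """Quadratic-weighted kappa of two ordinal vectors on the fixed 0-3 scale.

    kappa = 1 - sum(w * O) / sum(w * E), with w_ij = (i-j)^2 / (K-1)^2,
    O the observed joint proportions and E the outer product of marginals.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if len(a) < 2:
        raise AgreementError(f"need at least 2 usable images, got {len(a)}")
    # Degenerate marginals: both raters constant and identical puts all
    # expected mass on the zero-weight diagonal cell.
    if a.min() == a.max() == b.min() == b.max():
        raise AgreementError("degenerate marginals: both raters constant and identical")
    return float(
        cohen_kappa_score(a, b, labels=list(ORDINAL_GRADES), weights="quadratic")
    )


def weighted_kappa(
    panel: GradePanel,
    rater_x: str,
    rater_y: str,
    restrict_to: Iterable[str] | None = None,
) -> WeightedKappaResult:
    """Quadratic-weighted kappa between two raters of a panel.

    Images where either rater is UNGRADABLE or MISSING are excluded and
    counted in ``n_excluded``.  `restrict_to` limits the computation to an
    image subset (e.g. one validation split, or a listwise-usable set).
    """
    a, b, n_excluded = _paired_grades(panel, rater_x, rater_y, restrict_to)
    try:
        kappa = quadratic_weighted_kappa(a, b)
    except AgreementError as exc:
        raise AgreementError(f"{rater_x} vs {rater_y}: {exc}") from None
    return WeightedKappaResult(kappa=kappa, n_used=len(a), n_excluded=n_excluded)


@dataclass
class KappaMatrix:
    """Symmetric matrix of pairwise weighted kappas over a rater list."""

    raters: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.raters)
        if self.values.shape != (k, k):
            raise AgreementError("kappa matrix shape does not match rater list")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise AgreementError("kappa matrix is not symmetric")

    @property
    def row_means(self) -> np.ndarray:
        """Mean pairwise kappa of each rater against the others (diagonal excluded)."""
        k = len(self.raters)
        off = self.values.copy()
        np.fill_diagonal(off, 0.0)
        return off.sum(axis=1) / (k - 1)

    def submatrix(self, raters: Sequence[str]) -> "KappaMatrix":
        idx = [self.raters.index(r) for r in raters]
        return KappaMatrix(list(raters), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.raters, columns=self.raters)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="rater")

    def to_json(self, path=None) -> str:
        payload = {
            "raters": self.raters,
            "values": [[round(v, 12) for v in row] for row in self.values.tolist()],
            "row_means": [round(v, 12) for v in self.row_means.tolist()],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def listwise_usable_images(panel: GradePanel, raters: Sequence[str]) -> set[str]:
    """Images every listed rater graded with an ordinal grade."""
    usable: set[str] | None = None
    for r in raters:
        imgs = {img for img, g in panel.ratings(r).items() if _is_ordinal(g)}
        usable = imgs if usable is None else usable & imgs
    return usable or set()


def pairwise_kappa_matrix(
    panel: GradePanel,
    raters: Sequence[str],
    restrict_to: Iterable[str] | None = None,
    listwise: bool = False,
) -> KappaMatrix:
    """All pairwise weighted kappas among `raters`; unit diagonal by convention."""
    raters = list(raters)
    if listwise:
        allowed = listwise_usable_images(panel, raters)
        restrict_to = allowed if restrict_to is None else allowed & set(restrict_to)
    k = len(raters)
    values = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                res = weighted_kappa(panel, raters[i], raters[j], restrict_to)
            except AgreementError as exc:
                raise AgreementError(
                    f"pair ({raters[i]}, {raters[j]}): {exc}"
                ) from None
            values[i, j] = values[j, i] = res.kappa
    return KappaMatrix(raters, values)


def qualify_graders(
    panel: GradePanel,
    reference: str,
    candidates: Sequence[str],
    threshold: float = 0.7,
    listwise: bool = True,
    restrict_to: Iterable[str] | None = None,
) -> list[tuple[str, float, bool]]:
    """Screen candidate graders against a reference rater.

    A candidate qualifies iff its weighted kappa against the reference is
    strictly above `threshold`.  By default exclusion is listwise over
    {reference} + candidates: an image any of them failed to grade is
    dropped for everyone, so all kappas are computed on one shared image
    set.
    """
    if listwise:
        allowed = listwise_usable_images(panel, [reference, *candidates])
        restrict_to = allowed if restrict_to is None else allowed & set(restrict_to)
    out = []
    for cand in candidates:
        res = weighted_kappa(panel, reference, cand, restrict_to)
        out.append((cand, res.kappa, res.kappa > threshold))
    return out
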