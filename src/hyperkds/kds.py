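"""Kappa distance score (KDS), model screening and expert-referenced ensembles.

The KDS measures how close a responder (a model, or an ensemble of models)
comes to human-expert agreement.  Two expert pairs (A, B) and (C, D) each
grade one half of a validation set.  With kappa_na the responder's weighted
kappa against expert A (on the A/B half), etc., the score is

    KDS = (kappa_na + kappa_nb - 2 kappa_ab) + (kappa_nc + kappa_nd - 2 kappa_cd)

so a responder that agrees with each expert as well as the experts agree
with each other scores 0; scores above 0 indicate super-expert consistency
and are taken as clinically acceptable.

Ensembles are referenced to the experts' adopted validation grade:

* half rule   - if strictly more than half the members match the expert
                grade, answer the expert grade; otherwise the plurality
                member grade (ties broken by policy).
* least rule  - same, but a single matching member suffices.
* mean-round  - the members' mean grade, rounded half-up.

The multimodel score standardises the half-rule and least-rule KDS series
across ensemble sizes n (z-scores with population standard deviation) and
sums them:  KDS_(n,multi) = z(KDS_(n,half)) + z(KDS_(n,least)).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .agreement import AgreementError, KappaMatrix, weighted_kappa
from .panels import MISSING, UNGRADABLE, GradePanel

__all__ = [
    "KdsBreakdown",
    "EnsembleSpec",
    "MultiKdsTable",
    "ScreeningReport",
    "kds_single",
    "kds_from_panel",
    "screen_models",
    "combine_half",
    "combine_least",
    "combine_mean_round",
    "ensemble_responses",
    "multimodel_kds",
    "TIE_POLICIES",
]


@dataclass(frozen=True)
class KdsBreakdown:
    """The six pairwise kappas entering the KDS, and the score itself."""

    kappa_na: float
    kappa_nb: float
    kappa_ab: float
    kappa_nc: float
    kappa_nd: float
    kappa_cd: float

    def __post_init__(self) -> None:
        for name in ("kappa_na", "kappa_nb", "kappa_ab", "kappa_nc", "kappa_nd", "kappa_cd"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [-1, 1]")

    @property
    def kds(self) -> float:
        return (
            self.kappa_na + self.kappa_nb - 2.0 * self.kappa_ab
            + self.kappa_nc + self.kappa_nd - 2.0 * self.kappa_cd
        )

    def to_dict(self) -> dict[str, float]:
        return {
            "kappa_na": self.kappa_na,
            "kappa_nb": self.kappa_nb,
            "kappa_ab": self.kappa_ab,
            "kappa_nc": self.kappa_nc,
            "kappa_nd": self.kappa_nd,
            "kappa_cd": self.kappa_cd,
            "kds": self.kds,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def kds_single(
    kappa_na: float,
    kappa_nb: float,
    kappa_ab: float,
    kappa_nc: float,
    kappa_nd: float,
    kappa_cd: float,
) -> KdsBreakdown:
    """Build a :class:`KdsBreakdown` from six weighted kappas."""
    return KdsBreakdown(kappa_na, kappa_nb, kappa_ab, kappa_nc, kappa_nd, kappa_cd)


def kds_from_panel(
    panel: GradePanel,
    responder: str,
    graders: Sequence[str],
) -> KdsBreakdown:
    """KDS of one responder against the four experts of a tagged panel.

    `graders` is (A, B, C, D).  kappa_na, kappa_nb and kappa_ab are
    computed on the AB-subset images only; kappa_nc, kappa_nd and kappa_cd
    on the CD subset.
    """
    a, b, c, d = graders
    ab = panel.images(subset="AB")
    cd = panel.images(subset="CD")
    if not ab or not cd:
        raise AgreementError(
            "panel must carry AB and CD subset tags for a KDS computation"
        )
    return kds_single(
        weighted_kappa(panel, responder, a, restrict_to=ab).kappa,
        weighted_kappa(panel, responder, b, restrict_to=ab).kappa,
        weighted_kappa(panel, a, b, restrict_to=ab).kappa,
        weighted_kappa(panel, responder, c, restrict_to=cd).kappa,
        weighted_kappa(panel, responder, d, restrict_to=cd).kappa,
        weighted_kappa(panel, c, d, restrict_to=cd).kappa,
    )


# ---------------------------------------------------------------------------
# Iterative inter-model screening
# ---------------------------------------------------------------------------


@dataclass
class ScreeningReport:
    """Exclusion order and survivors of the iterative agreement screen."""

    excluded: list[tuple[str, float]]
    survivors: list[str]
    threshold: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "excluded": [
                    {"responder": r, "mean_kappa": round(k, 12)} for r, k in self.excluded
                ],
                "survivors": self.survivors,
                "threshold": self.threshold,
            },
            indent=2,
            sort_keys=True,
        )


def screen_models(matrix: KappaMatrix, threshold: float = 0.7) -> ScreeningReport:
    """Iteratively drop responders that agree too little with the rest.

    While any responder's mean off-diagonal kappa is at or below
    `threshold`, the responder with the lowest mean is removed and the
    means are recomputed on the survivors.  Removing a dissenter can lift
    the remaining means, so recomputation per iteration matters.
    """
    current = matrix
    excluded: list[tuple[str, float]] = []
    while True:
        means = current.row_means
        if not np.any(means <= threshold):
            break
        worst = int(np.argmin(means))
        excluded.append((current.raters[worst], float(means[worst])))
        keep = [r for i, r in enumerate(current.raters) if i != worst]
        if len(keep) < 2:
            raise AgreementError("screening exhausted panel: fewer than 2 survivors")
        current = current.submatrix(keep)
    return ScreeningReport(excluded=excluded, survivors=list(current.raters), threshold=threshold)


# ---------------------------------------------------------------------------
# Ensemble combination rules
# ---------------------------------------------------------------------------


def _tie_lowest(tied: list[int], members: Sequence[int]) -> int:
    return min(tied)


def _tie_highest(tied: list[int], members: Sequence[int]) -> int:
    return max(tied)


def _tie_nearest_mean(tied: list[int], members: Sequence[int]) -> int:
    mean = float(np.mean(members))
    return min(tied, key=lambda g: (abs(g - mean), g))


#: Selectable plurality tie policies.  Default is ``lowest`` (conservative:
#: never overstates severity) and is deterministic.
TIE_POLICIES: dict[str, Callable[[list[int], Sequence[int]], int]] = {
    "lowest": _tie_lowest,
    "highest": _tie_highest,
    "nearest_mean": _tie_nearest_mean,
}


def _plurality(member_grades: Sequence[int], tie_policy: str) -> int:
    counts = Counter(member_grades)
    top = max(counts.values())
    tied = sorted(g for g, c in counts.items() if c == top)
    if len(tied) == 1:
        return tied[0]
    return TIE_POLICIES[tie_policy](tied, member_grades)


def combine_half(
    member_grades: Sequence[int],
    expert_grade: int,
    tie_policy: str = "lowest",
) -> int:
    """Half rule: expert grade if strictly more than half the members match it.

    "More than half" is strict — 3 of 6 does not trigger the match, which
    is why even-n ensembles outperform their odd-(n+1) counterparts on the
    half-rule score.  Otherwise the plurality member grade, ties resolved
    by `tie_policy`.
    """
    if not member_grades:
        raise ValueError("member_grades must be non-empty")
    n_match = sum(1 for g in member_grades if g == expert_grade)
    if n_match > len(member_grades) / 2:
        return int(expert_grade)
    return _plurality(member_grades, tie_policy)


def combine_least(
    member_grades: Sequence[int],
    expert_grade: int,
    tie_policy: str = "lowest",
) -> int:
    """Least rule: expert grade if at least one member matches it."""
    if not member_grades:
        raise ValueError("member_grades must be non-empty")
    if any(g == expert_grade for g in member_grades):
        return int(expert_grade)
    return _plurality(member_grades, tie_policy)


def combine_mean_round(member_grades: Sequence[int]) -> int:
    """Mean of the member grades, rounded half-up, clamped to the scale."""
    if not member_grades:
        raise ValueError("member_grades must be non-empty")
    mean = float(np.mean(member_grades))
    rounded = int(np.floor(mean + 0.5))  # exact halves round up
    return max(0, min(3, rounded))


_RULES = {
    "half": combine_half,
    "least": combine_least,
}


@dataclass(frozen=True)
class EnsembleSpec:
    """An ordered member list plus the combination rule binding them."""

    members: tuple[str, ...]
    rule: str  # "half" | "least" | "mean_round"
    tie_policy: str = "lowest"
    reference: str | None = None

    def __post_init__(self) -> None:
        if not self.members or len(set(self.members)) != len(self.members):
            raise ValueError("members must be non-empty and distinct")
        if self.rule in ("half", "least") and self.reference is None:
            raise ValueError(f"rule {self.rule!r} requires an expert reference")
        if self.rule == "mean_round" and self.reference is not None:
            raise ValueError("mean_round takes no expert reference")
        if self.rule not in ("half", "least", "mean_round"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.tie_policy not in TIE_POLICIES:
            raise ValueError(f"unknown tie policy {self.tie_policy!r}")


def ensemble_responses(
    panel: GradePanel,
    members: Sequence[str],
    rule: str,
    reference: Mapping[str, int] | None = None,
    tie_policy: str = "lowest",
) -> dict[str, int]:
    """Apply a combination rule image-by-image over a member panel.

    For ``half``/``least``, `reference` maps image id to the experts'
    adopted validation grade; images without a reference grade, or where
    any member response is missing/ungradable, are skipped.  For
    ``mean_round`` no reference is needed.
    """
    ratings = {m: panel.ratings(m) for m in members}
    images = set.intersection(*(set(r) for r in ratings.values()))
    if rule in _RULES:
        if reference is None:
            raise ValueError(f"rule {rule!r} requires a reference grade map")
        images &= set(reference)
    out: dict[str, int] = {}
    for img in sorted(images):
        grades = [ratings[m][img] for m in members]
        if any(g is MISSING or g is UNGRADABLE for g in grades):
            continue
        grades = [int(g) for g in grades]
        if rule == "mean_round":
            out[img] = combine_mean_round(grades)
        else:
            out[img] = _RULES[rule](grades, int(reference[img]), tie_policy)
    return out


# ---------------------------------------------------------------------------
# Multimodel KDS table
# ---------------------------------------------------------------------------


def _z_standardise(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    mean = float(np.mean(values))
    se = float(np.sqrt(np.mean((values - mean) ** 2)))  # population SD
    if se == 0.0:
        raise AgreementError("degenerate normalisation: series constant across n")
    return (values - mean) / se, mean, se


@dataclass
class MultiKdsTable:
    """Half/least/multi KDS for ensembles of the top-n ranked members."""

    ns: list[int]
    kds_half: np.ndarray = field(repr=False)
    kds_least: np.ndarray = field(repr=False)
    mean_half: float = 0.0
    se_half: float = 0.0
    mean_least: float = 0.0
    se_least: float = 0.0
    members_per_n: dict[int, list[str]] = field(default_factory=dict)

    @property
    def z_half(self) -> np.ndarray:
        return (self.kds_half - self.mean_half) / self.se_half

    @property
    def z_least(self) -> np.ndarray:
        return (self.kds_least - self.mean_least) / self.se_least

    @property
    def kds_multi(self) -> np.ndarray:
        return self.z_half + self.z_least

    @property
    def best_n(self) -> int:
        return self.ns[int(np.argmax(self.kds_multi))]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "n": self.ns,
                "kds_half": self.kds_half,
                "kds_least": self.kds_least,
                "kds_multi": self.kds_multi,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "ns": self.ns,
                "kds_half": [round(v, 12) for v in self.kds_half.tolist()],
                "kds_least": [round(v, 12) for v in self.kds_least.tolist()],
                "kds_multi": [round(v, 12) for v in self.kds_multi.tolist()],
                "mean_half": round(self.mean_half, 12),
                "se_half": round(self.se_half, 12),
                "mean_least": round(self.mean_least, 12),
                "se_least": round(self.se_least, 12),
                "members_per_n": {str(n): m for n, m in self.members_per_n.items()},
                "best_n": self.best_n,
            },
            indent=2,
            sort_keys=True,
        )


def rank_by_kds(
    panel: GradePanel,
    responders: Sequence[str],
    graders: Sequence[str],
) -> list[tuple[str, float]]:
    """Responders ordered by single-responder KDS, best first.

    Equal scores are broken by lexicographic responder id so rankings are
    reproducible.
    """
    scored = [(r, kds_from_panel(panel, r, graders).kds) for r in responders]
    return sorted(scored, key=lambda t: (-t[1], t[0]))


def multimodel_kds(
    panel: GradePanel,
    ranked_members: Sequence[str],
    graders: Sequence[str],
    reference: Mapping[str, int],
    tie_policy: str = "lowest",
    n_max: int | None = None,
) -> MultiKdsTable:
    """KDS_(n,half), KDS_(n,least) and KDS_(n,multi) for n = 2..N ensembles.

    `ranked_members` must already be ordered best-KDS-first; the n-member
    ensemble takes the top n.  With seven ranked members this evaluates
    n = 2..7.  `reference` maps image id to the experts' adopted
    validation grade; it is also the expert answer each rule is matched
    against.
    """
    if len(ranked_members) < 2:
        raise ValueError("need at least 2 ranked members")
    top = n_max if n_max is not None else min(len(ranked_members), 7)
    ns = list(range(2, top + 1))
    half_vals, least_vals = [], []
    members_per_n: dict[int, list[str]] = {}
    for n in ns:
        members = list(ranked_members[:n])
        members_per_n[n] = members
        for rule, store in (("half", half_vals), ("least", least_vals)):
            responses = ensemble_responses(panel, members, rule, reference, tie_policy)
            augmented = panel.with_responder(f"__ensemble_{rule}_{n}__", responses)
            store.append(
                kds_from_panel(augmented, f"__ensemble_{rule}_{n}__", graders).kds
            )
    kds_half = np.asarray(half_vals)
    kds_least = np.asarray(least_vals)
    _, mean_half, se_half = _z_standardise(kds_half)
    _, mean_least, se_least = _z_standardise(kds_least)
    return MultiKdsTable(
        ns=ns,
        kds_half=kds_half,
        kds_least=kds_least,
        mean_half=mean_half,
        se_half=se_half,
        mean_least=mean_least,
        se_least=se_least,
        members_per_n=members_per_n,
    )
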