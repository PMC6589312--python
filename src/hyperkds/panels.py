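"""Grade-response panels and the two-grader + specialist adjudication workflow.

A *panel* is a long-format table of ordinal severity responses: one record
per (image, rater), where the response is a grade on the four-level
none/mild/moderate/advanced scale (0-3), or the rater declared the image
ungradable, or the rater gave no response at all.  Panels are the single
currency of every agreement computation in this package.

Reference labels are built by *adjudication*: two graders rate the same
images; agreement defines the label, an image either grader calls
ungradable is excluded, and disagreements are referred to a specialist who
either supplies the final grade or excludes the image.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import pandas as pd

__all__ = [
    "GradeLabel",
    "UNGRADABLE",
    "MISSING",
    "ORDINAL_GRADES",
    "GradePanel",
    "AdjudicationResult",
    "PanelError",
    "read_panel",
    "adjudicate",
]

#: The fixed four-category ordinal scale (0 none, 1 mild, 2 moderate, 3 advanced).
ORDINAL_GRADES = (0, 1, 2, 3)


class _Sentinel(enum.Enum):
    UNGRADABLE = "U"
    MISSING = ""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: Rater declared the image impossible to grade.  Distinct from MISSING.
UNGRADABLE = _Sentinel.UNGRADABLE
#: Rater gave no response for the image.
MISSING = _Sentinel.MISSING

#: A grade label: an ordinal grade in 0..3, or UNGRADABLE, or MISSING.
GradeLabel = int | _Sentinel

_SUBSETS = ("AB", "CD", "NONE")


class PanelError(ValueError):
    """Structural problem in a grade panel or adjudication input."""


def parse_grade(token: object, row: int | None = None) -> GradeLabel:
    """Parse a CSV grade token under the default dialect.

    ``"0"``-``"3"`` are ordinal grades, ``"U"`` (case-insensitive) is
    UNGRADABLE, an empty cell is MISSING.
    """
    if token is None or (isinstance(token, float) and pd.isna(token)):
        return MISSING
    s = str(token).strip()
    if s == "":
        return MISSING
    if s.upper() == "U":
        return UNGRADABLE
    try:
        g = int(s)
    except ValueError:
        g = -1
    if g not in ORDINAL_GRADES:
        where = f" (row {row})" if row is not None else ""
        raise PanelError(f"unparseable grade token {token!r}{where}")
    return g


def _grade_token(label: GradeLabel) -> str:
    if isinstance(label, _Sentinel):
        return label.value
    return str(label)


@dataclass(frozen=True)
class GradePanel:
    """Long-format table of (image_id, rater_id, label, subset) records.

    Invariants enforced on construction: at most one record per
    (image, rater) pair; every image carries exactly one subset tag
    (one of ``AB``, ``CD``, ``NONE``).
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"image_id", "rater_id", "grade"}
        missing_cols = required - set(self.frame.columns)
        if missing_cols:
            raise PanelError(f"panel missing columns: {sorted(missing_cols)}")
        df = self.frame
        if "subset" not in df.columns:
            df = df.assign(subset="NONE")
        bad = set(df["subset"].unique()) - set(_SUBSETS)
        if bad:
            raise PanelError(f"unknown subset tags: {sorted(bad)}")
        dup = df.duplicated(subset=["image_id", "rater_id"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["image_id", "rater_id"]]
            raise PanelError(
                f"duplicate record for image {pair['image_id']!r}, "
                f"rater {pair['rater_id']!r}"
            )
        tags_per_image = df.groupby("image_id")["subset"].nunique()
        conflicted = tags_per_image[tags_per_image > 1]
        if not conflicted.empty:
            raise PanelError(
                f"images with conflicting subset tags: {list(conflicted.index)}"
            )
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
    ) -> "GradePanel":
        """Build a panel from (image_id, rater_id, label[, subset]) tuples."""
        rows = []
        for rec in records:
            if len(rec) == 3:
                img, rater, label = rec
                subset = "NONE"
            else:
                img, rater, label, subset = rec
            rows.append(
                {
                    "image_id": str(img),
                    "rater_id": str(rater),
                    "grade": label if isinstance(label, _Sentinel) else int(label),
                    "subset": subset,
                }
            )
        return cls(pd.DataFrame(rows, columns=["image_id", "rater_id", "grade", "subset"]))

    @classmethod
    def from_csv(cls, path) -> "GradePanel":
        return read_panel(path)

    # -- accessors ---------------------------------------------------------

    def images(self, subset: str | None = None) -> list[str]:
        df = self.frame
        if subset is not None:
            df = df[df["subset"] == subset]
        return sorted(df["image_id"].unique())

    def raters(self) -> list[str]:
        return sorted(self.frame["rater_id"].unique())

    def ratings(self, rater_id: str) -> dict[str, GradeLabel]:
        """All recorded labels of one rater, keyed by image id."""
        df = self.frame[self.frame["rater_id"] == rater_id]
        return dict(zip(df["image_id"], df["grade"]))

    def label_of(self, image_id: str, rater_id: str) -> GradeLabel:
        """Label of a rater for an image; MISSING when no record exists."""
        df = self.frame
        hit = df[(df["image_id"] == image_id) & (df["rater_id"] == rater_id)]
        if hit.empty:
            return MISSING
        return hit["grade"].iloc[0]

    def subset_of(self, image_id: str) -> str:
        hit = self.frame[self.frame["image_id"] == image_id]
        if hit.empty:
            raise PanelError(f"unknown image {image_id!r}")
        return hit["subset"].iloc[0]

    def with_responder(
        self, rater_id: str, responses: Mapping[str, GradeLabel]
    ) -> "GradePanel":
        """Return a new panel with an extra responder's records appended.

        Subset tags are inherited from the images already in the panel.
        """
        rows = [
            {
                "image_id": img,
                "rater_id": rater_id,
                "grade": label,
                "subset": self.subset_of(img),
            }
            for img, label in responses.items()
        ]
        return GradePanel(pd.concat([self.frame, pd.DataFrame(rows)], ignore_index=True))

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["grade"] = out["grade"].map(_grade_token)
        out.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.frame)


def read_panel(path, dialect: Mapping[str, str] | None = None) -> GradePanel:
    """Read a grade panel from CSV.

    Expected columns: ``image_id``, ``rater_id``, ``grade`` and optionally
    ``subset``.  Grade tokens follow the default dialect ("0".."3", "U",
    empty = missing); `dialect` may remap tokens (token -> canonical token)
    before parsing.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"image_id", "rater_id", "grade"}
    if not required <= set(df.columns):
        raise PanelError(
            f"panel CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if dialect:
        df["grade"] = df["grade"].map(lambda t: dialect.get(t, t))
    labels = [parse_grade(t, row=i + 2) for i, t in enumerate(df["grade"])]
    out = df.assign(grade=labels)
    if "subset" in out.columns:
        out["subset"] = out["subset"].replace("", "NONE")
    return GradePanel(out)


@dataclass
class AdjudicationResult:
    """Outcome of the two-grader + specialist labelling workflow."""

    labeled: dict[str, int]
    excluded: dict[str, str]  # image_id -> reason
    counts: dict[str, int]

    def __post_init__(self) -> None:
        overlap = set(self.labeled) & set(self.excluded)
        if overlap:
            raise PanelError(f"images both labeled and excluded: {sorted(overlap)}")

    def to_json(self, path=None) -> str:
        payload = {
            "labeled": self.labeled,
            "excluded": self.excluded,
            "counts": self.counts,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


EXCLUDE = object()
"""Specialist response meaning: exclude this image from the labeled set."""


def adjudicate(
    panel: GradePanel,
    grader1: str,
    grader2: str,
    specialist: GradePanel | Callable[[str], object] | None = None,
    specialist_id: str | None = None,
    images: Iterable[str] | None = None,
) -> AdjudicationResult:
    """Derive reference labels from two graders with specialist arbitration.

    Per image: agreement on an ordinal grade adopts that grade; an
    ungradable call by either grader excludes the image; a missing response
    from either grader excludes it as missing; a disagreement is referred
    to the specialist, whose ordinal grade is adopted, while a specialist
    UNGRADABLE (or :data:`EXCLUDE`) excludes the image.

    `specialist` may be a :class:`GradePanel` (with `specialist_id` naming
    the specialist's rater id, defaulting to its only rater) or a callback
    ``image_id -> grade | UNGRADABLE | EXCLUDE``.  If a disagreeing image
    has no specialist response, the adjudication fails listing every
    unresolved image.
    """
    if images is None:
        common = sorted(
            set(panel.ratings(grader1)) | set(panel.ratings(grader2))
        )
    else:
        common = sorted(images)

    lookup: Callable[[str], object]
    if specialist is None:
        lookup = lambda img: MISSING  # noqa: E731
    elif isinstance(specialist, GradePanel):
        sid = specialist_id
        if sid is None:
            sraters = specialist.raters()
            if len(sraters) != 1:
                raise PanelError(
                    "specialist panel has several raters; pass specialist_id"
                )
            sid = sraters[0]
        sratings = specialist.ratings(sid)
        lookup = lambda img: sratings.get(img, MISSING)  # noqa: E731
    else:
        lookup = specialist

    r1 = panel.ratings(grader1)
    r2 = panel.ratings(grader2)

    labeled: dict[str, int] = {}
    excluded: dict[str, str] = {}
    unresolved: list[str] = []
    n_agree = n_specialist = 0
    for img in common:
        a = r1.get(img, MISSING)
        b = r2.get(img, MISSING)
        if a is UNGRADABLE or b is UNGRADABLE:
            excluded[img] = "ungradable"
        elif a is MISSING or b is MISSING:
            excluded[img] = "missing"
        elif a == b:
            labeled[img] = int(a)
            n_agree += 1
        else:
            s = lookup(img)
            if s is MISSING or s is None:
                unresolved.append(img)
            elif s is EXCLUDE or s is UNGRADABLE:
                excluded[img] = "specialist_excluded"
            else:
                labeled[img] = int(s)
                n_specialist += 1
    if unresolved:
        raise PanelError(
            f"no specialist response for disagreeing images: {unresolved}"
        )
    counts = {
        "agreement": n_agree,
        "specialist_resolved": n_specialist,
        "ungradable": sum(1 for r in excluded.values() if r == "ungradable"),
        "specialist_excluded": sum(
            1 for r in excluded.values() if r == "specialist_excluded"
        ),
        "missing": sum(1 for r in excluded.values() if r == "missing"),
    }
    return AdjudicationResult(labeled=labeled, excluded=excluded, counts=counts)
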