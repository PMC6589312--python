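"""Model/Results interface over the KDS evaluation pipeline.

:class:`KdsEvaluation` is built from a tagged grade panel, a set of
responders (models), and the four expert graders; ``fit()`` runs the full
evaluation — pairwise inter-responder kappas, the iterative agreement
screen, single-responder KDS ranking, and the multimodel half/least/multi
table — and returns a :class:`KdsEvaluationResults` carrying every
intermediate quantity with a printable ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .agreement import KappaMatrix, pairwise_kappa_matrix
from .kds import (
    KdsBreakdown,
    MultiKdsTable,
    ScreeningReport,
    kds_from_panel,
    multimodel_kds,
    rank_by_kds,
    screen_models,
)
from .panels import GradePanel, adjudicate

__all__ = ["KdsEvaluation", "KdsEvaluationResults"]


def adopted_reference(
    panel: GradePanel,
    graders: Sequence[str],
    specialist: object | None = None,
) -> dict[str, int]:
    """Experts' adopted validation grades: AB pair on the AB subset, CD on CD.

    Agreements define the grade; disagreements go to the specialist when
    one is given and are otherwise dropped (along with ungradable and
    missing images).
    """
    a, b, c, d = graders
    ref: dict[str, int] = {}
    for pair, subset in (((a, b), "AB"), ((c, d), "CD")):
        images = panel.images(subset=subset)
        res = adjudicate(
            panel,
            *pair,
            specialist=specialist if specialist is not None else _drop_disagreements,
            images=images,
        )
        ref.update(res.labeled)
    return ref


def _drop_disagreements(img: str):
    from .panels import EXCLUDE

    return EXCLUDE


class KdsEvaluation:
    """KDS evaluation of a set of responders against four expert graders.

    Parameters
    ----------
    panel:
        Grade panel containing the responders' and graders' records, with
        AB/CD subset tags on every image.
    responders:
        Ids of the models (or humans) being evaluated.
    graders:
        The four expert ids (A, B, C, D).
    reference:
        Experts' adopted grade per image, used as the expert answer of the
        ensemble rules.  Built by pairwise adjudication (disagreements
        dropped) when not given.
    """

    def __init__(
        self,
        panel: GradePanel,
        responders: Sequence[str],
        graders: Sequence[str],
        reference: Mapping[str, int] | None = None,
        screen_threshold: float = 0.7,
        tie_policy: str = "lowest",
        n_max: int | None = None,
    ) -> None:
        if len(graders) != 4:
            raise ValueError("graders must be the four expert ids (A, B, C, D)")
        self.panel = panel
        self.responders = list(responders)
        self.graders = list(graders)
        self.reference = (
            dict(reference)
            if reference is not None
            else adopted_reference(panel, graders)
        )
        self.screen_threshold = screen_threshold
        self.tie_policy = tie_policy
        self.n_max = n_max

    def fit(self) -> "KdsEvaluationResults":
        matrix = pairwise_kappa_matrix(self.panel, self.responders)
        screening = screen_models(matrix, threshold=self.screen_threshold)
        ranking = rank_by_kds(self.panel, screening.survivors, self.graders)
        ranked_ids = [r for r, _ in ranking]
        breakdowns = {
            r: kds_from_panel(self.panel, r, self.graders) for r in ranked_ids
        }
        multi = multimodel_kds(
            self.panel,
            ranked_ids,
            self.graders,
            self.reference,
            tie_policy=self.tie_policy,
            n_max=self.n_max,
        )
        return KdsEvaluationResults(
            model=self,
            kappa_matrix=matrix,
            screening=screening,
            ranking=ranking,
            breakdowns=breakdowns,
            multi=multi,
        )


@dataclass
class KdsEvaluationResults:
    """Fitted KDS evaluation: kappas, screening, ranking, multimodel table."""

    model: KdsEvaluation
    kappa_matrix: KappaMatrix
    screening: ScreeningReport
    ranking: list[tuple[str, float]]
    breakdowns: dict[str, KdsBreakdown] = field(repr=False)
    multi: MultiKdsTable = field(repr=False)

    @property
    def best_responder(self) -> str:
        return self.ranking[0][0]

    @property
    def best_ensemble(self) -> list[str]:
        return self.multi.members_per_n[self.multi.best_n]

    def single_table(self) -> pd.DataFrame:
        rows = []
        for responder, kds in self.ranking:
            b = self.breakdowns[responder]
            rows.append({"responder": responder, **b.to_dict()})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["KDS evaluation", "=" * 70]
        lines.append(
            f"responders: {len(self.model.responders)}  "
            f"survivors after screening (threshold {self.screening.threshold}): "
            f"{len(self.screening.survivors)}"
        )
        if self.screening.excluded:
            for rid, mk in self.screening.excluded:
                lines.append(f"  excluded {rid} (mean inter-responder kappa {mk:.3f})")
        lines.append("")
        lines.append("Single-responder KDS (best first)")
        lines.append(self.single_table().to_string(index=False, float_format="%.3f"))
        lines.append("")
        lines.append("Multimodel KDS")
        lines.append(self.multi.to_frame().to_string(index=False, float_format="%.3f"))
        lines.append(
            f"best ensemble: n={self.multi.best_n} -> "
            + ", ".join(self.best_ensemble)
        )
        return "\n".join(lines)
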