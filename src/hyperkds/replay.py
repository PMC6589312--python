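"""End-to-end synthetic replay of the grading-evaluation workflow.

One root seed drives every stage through named substreams, so the whole
run — panel simulation, adjudication, grader qualification, stand-in model
training, screening, KDS ranking, the multimodel table, and the
vessel-area comparison — is reproducible byte for byte.

Stage order:

1. simulate a training panel (graders A, B + specialist) and a tagged
   validation panel (A, B on the AB half; C, D on the CD half; specialist
   everywhere);
2. adjudicate the training panel into reference labels;
3. qualify the graders against the specialist (threshold 0.7);
4. render synthetic images and train several stand-in classifiers, made
   diverse by bootstrap subsampling and feature jitter;
5. let every classifier grade the validation images, screen the
   responders by mean inter-responder kappa (threshold 0.7), rank the
   survivors by single-responder KDS, and build the multimodel table;
6. grade the validation images with the best ensemble's mean-round
   combiner, measure vessel-area occupancy, and run the Spearman /
   Kruskal–Wallis / Steel–Dwass comparisons.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .agreement import qualify_graders
from .evaluation import KdsEvaluation, adopted_reference
from .grading_model import BaselineGrader, extract_features
from .kds import ensemble_responses
from .panels import GradePanel, adjudicate
from .stats import kruskal_wallis, spearman, steel_dwass
from .synthetic import ImageSpec, PanelSpec, RaterSpec, simulate_images, simulate_panel
from .vessel_area import DEFAULT_THRESHOLD, grade_vs_area_table, measure_vessel_area

__all__ = ["RunConfig", "ReplayError", "replay"]

log = logging.getLogger("hyperkds.replay")


class ReplayError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _jsonable(obj):
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds, sizes and seeds of one replay run."""

    seed: int = 0
    n_train: int = 400
    n_validation: int = 400
    n_models: int = 6
    grader_epsilon: float = 0.22
    specialist_epsilon: float = 0.08
    ungradable_rate: float = 0.01
    qualification_threshold: float = 0.7
    screening_threshold: float = 0.7
    vessel_threshold: float = DEFAULT_THRESHOLD
    tie_policy: str = "lowest"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("qualification_threshold", "screening_threshold"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1]")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")


def _substream(root_seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([root_seed, zlib.crc32(stage.encode())])


def _stage_seed(root_seed: int, stage: str) -> int:
    return int(_substream(root_seed, stage).generate_state(1)[0] % (2**31))


def replay(config: RunConfig) -> dict:
    """Run the full synthetic pipeline; return (and optionally write) reports."""
    # out_dir is where the report lands, not part of what it reports
    report: dict = {
        "config": {
            k: getattr(config, k)
            for k in RunConfig.__dataclass_fields__
            if k != "out_dir"
        }
    }

    # -- stage: simulate ---------------------------------------------------
    try:
        graders = [
            RaterSpec(r, config.grader_epsilon, config.ungradable_rate)
            for r in ("A", "B", "C", "D")
        ]
        specialist = RaterSpec("S", config.specialist_epsilon, 0.0)
        train_spec = PanelSpec(
            n_images=config.n_train,
            raters=(graders[0], graders[1], specialist),
            seed=_stage_seed(config.seed, "train_panel"),
        )
        train_panel, train_truth = simulate_panel(train_spec)
        val_spec = PanelSpec(
            n_images=config.n_validation,
            raters=(*graders, specialist),
            seed=_stage_seed(config.seed, "validation_panel"),
        )
        val_panel, val_truth = simulate_panel(val_spec)
        # training ids must not collide with validation ids
        train_panel = GradePanel(
            train_panel.frame.assign(
                image_id="tr_" + train_panel.frame["image_id"]
            )
        )
        train_truth = {f"tr_{k}": v for k, v in train_truth.items()}
        log.info("simulate: %d training, %d validation images", config.n_train, config.n_validation)
    except Exception as exc:
        raise ReplayError(f"stage simulate: {exc}") from exc

    # -- stage: adjudicate -------------------------------------------------
    try:
        adj = adjudicate(train_panel, "A", "B", specialist=train_panel, specialist_id="S")
        train_labels = adj.labeled
        report["adjudication_counts"] = adj.counts
        log.info("adjudicate: %d labeled, %d excluded", len(adj.labeled), len(adj.excluded))
    except Exception as exc:
        raise ReplayError(f"stage adjudicate: {exc}") from exc

    # -- stage: qualify ----------------------------------------------------
    try:
        qual = qualify_graders(
            val_panel, "S", ["A", "B", "C", "D"], threshold=config.qualification_threshold
        )
        report["grader_qualification"] = [
            {"rater": r, "kappa": round(k, 6), "qualified": q} for r, k, q in qual
        ]
        log.info("qualify: %s", report["grader_qualification"])
    except Exception as exc:
        raise ReplayError(f"stage qualify: {exc}") from exc

    # -- stage: train stand-in models -------------------------------------
    try:
        img_spec_train = ImageSpec(seed=_stage_seed(config.seed, "train_images"))
        train_images = simulate_images(img_spec_train, train_labels)
        X_train = np.vstack(
            [extract_features(train_images[i].image) for i in sorted(train_labels)]
        )
        y_train = np.array([train_labels[i] for i in sorted(train_labels)])
        models: dict[str, BaselineGrader] = {}
        for m in range(config.n_models):
            name = f"M{m}"
            seed_m = _stage_seed(config.seed, f"model_{m}")
            grader = BaselineGrader(
                seed=seed_m,
                feature_jitter=0.35,
                subsample=0.7,
            )
            grader.fit_features(X_train, y_train)
            models[name] = grader
        log.info("train: fitted %d stand-in models on %d labeled images", len(models), len(y_train))
    except Exception as exc:
        raise ReplayError(f"stage train: {exc}") from exc

    # -- stage: model responses on validation ------------------------------
    try:
        img_spec_val = ImageSpec(seed=_stage_seed(config.seed, "validation_images"))
        val_images = simulate_images(img_spec_val, val_truth)
        val_ids = sorted(val_truth)
        X_val = {i: extract_features(val_images[i].image) for i in val_ids}
        panel = val_panel
        for name, model in models.items():
            responses = {i: model.predict_features(X_val[i]) for i in val_ids}
            panel = panel.with_responder(name, responses)
    except Exception as exc:
        raise ReplayError(f"stage respond: {exc}") from exc

    # -- stage: screen / rank / multimodel ---------------------------------
    try:
        reference = adopted_reference(panel, ["A", "B", "C", "D"], specialist=panel.ratings("S").get)
        evaluation = KdsEvaluation(
            panel,
            responders=sorted(models),
            graders=["A", "B", "C", "D"],
            reference=reference,
            screen_threshold=config.screening_threshold,
            tie_policy=config.tie_policy,
        )
        results = evaluation.fit()
        report["screening"] = json.loads(results.screening.to_json())
        report["single_kds"] = [
            {"responder": r, "kds": round(k, 12)} for r, k in results.ranking
        ]
        report["multimodel"] = json.loads(results.multi.to_json())
        log.info("kds: best single %s, best ensemble n=%d", results.best_responder, results.multi.best_n)
    except Exception as exc:
        raise ReplayError(f"stage kds: {exc}") from exc

    # -- stage: vessel-area comparison -------------------------------------
    try:
        ensemble_grades = ensemble_responses(
            panel, results.best_ensemble, rule="mean_round"
        )
        areas = {
            i: measure_vessel_area(val_images[i].image, threshold=config.vessel_threshold)
            for i in ensemble_grades
        }
        groups, summary, n_dropped = grade_vs_area_table(ensemble_grades, areas)
        ids = sorted(set(ensemble_grades) & {i for i, a in areas.items() if a.measurable})
        rho, p_rho = spearman(
            [ensemble_grades[i] for i in ids], [areas[i].percent for i in ids]
        )
        present = [groups[g] for g in sorted(groups) if len(groups[g]) >= 2]
        h, p_h = kruskal_wallis(present)
        sd = (
            steel_dwass(present)
            if len(present) >= 3
            else []
        )
        report["vessel_area"] = {
            "spearman_rho": round(rho, 12),
            "spearman_p": round(p_rho, 12),
            "kruskal_H": round(h, 12),
            "kruskal_p": round(p_h, 12),
            "steel_dwass": [
                {
                    "pair": [c.group_a, c.group_b],
                    "statistic": round(c.statistic, 12),
                    "p": round(c.p_value, 12),
                }
                for c in sd
            ],
            "per_grade": summary.to_dict(orient="records"),
            "n_unmeasurable": n_dropped,
        }
        log.info("vessel-area: spearman rho=%.3f", rho)
    except Exception as exc:
        raise ReplayError(f"stage vessel_area: {exc}") from exc

    # -- stage: write ------------------------------------------------------
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=_jsonable) + "\n"
        )
        results.kappa_matrix.to_csv(out / "kappa_matrix.csv")
        results.single_table().to_csv(out / "single_kds.csv", index=False)
        results.multi.to_frame().to_csv(out / "multimodel_kds.csv", index=False)
        summary.to_csv(out / "vessel_area_by_grade.csv", index=False)
    return report
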