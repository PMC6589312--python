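"""Grade-stratified image amplification planning and processing operations.

Severe hyperaemia is rare in clinical archives, so the training corpus is
rebalanced by amplifying each grade a different number of times: grade 0
fourfold, grades 1 and 2 twofold, grade 3 eighteenfold.  Amplification
works by sampling, once per grade, a number of processing types (2/1/1/9
of the nine available) and emitting every processed image both as-is and
horizontally mirrored — mirroring is mandatory, which is what doubles the
type count into the multiplier (m_g = 2 * t_g).

The nine processing types: no correction, contrast up/down, gamma 0.75,
gamma 1.5, histogram equalisation, Gaussian noise, salt-and-pepper noise,
and mirroring itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage import exposure

__all__ = [
    "ProcessingOp",
    "AugmentationPlan",
    "NINE_OPS",
    "MULTIPLIERS",
    "N_TYPES",
    "make_plan",
    "apply_op",
    "amplified_counts",
]

#: Per-grade amplification multiplier.
MULTIPLIERS = {0: 4, 1: 2, 2: 2, 3: 18}
#: Per-grade number of processing types sampled (multiplier = 2 * types).
N_TYPES = {0: 2, 1: 1, 2: 1, 3: 9}


@dataclass(frozen=True)
class ProcessingOp:
    """One of the nine image-processing types, with its parameters."""

    kind: str
    gamma: float | None = None
    contrast_factor: float | None = None
    noise_sigma: float | None = None
    sp_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.kind.startswith("gamma") and self.gamma not in (0.75, 1.5):
            raise ValueError("gamma must be 0.75 or 1.5")
        if self.noise_sigma is not None and self.noise_sigma <= 0:
            raise ValueError("noise sigma must be positive")
        if self.sp_fraction is not None and not 0 < self.sp_fraction < 1:
            raise ValueError("salt-pepper fraction must be in (0, 1)")

    def label(self) -> str:
        return self.kind


def default_ops(
    contrast: float = 0.25,
    noise_sigma: float = 10.0,
    sp_fraction: float = 0.01,
) -> list[ProcessingOp]:
    """The nine processing types at their default parameters.

    Contrast defaults to +/-25% linear scaling about mid-grey, Gaussian
    sigma to 10 grey levels, salt-and-pepper to 1% of pixels — visually
    mild values typical for photographic augmentation.
    """
    return [
        ProcessingOp("none"),
        ProcessingOp("contrast_up", contrast_factor=1.0 + contrast),
        ProcessingOp("contrast_down", contrast_factor=1.0 - contrast),
        ProcessingOp("gamma_0.75", gamma=0.75),
        ProcessingOp("gamma_1.5", gamma=1.5),
        ProcessingOp("hist_equalise"),
        ProcessingOp("gaussian_noise", noise_sigma=noise_sigma),
        ProcessingOp("salt_pepper", sp_fraction=sp_fraction),
        ProcessingOp("mirror"),
    ]


#: The canonical nine-op list at default parameters.
NINE_OPS = default_ops()


@dataclass
class AugmentationPlan:
    """Deterministic expansion of a labelled image set into processing jobs.

    ``jobs`` lists (image_id, op, mirrored) triples; each sampled
    (image, op) pair appears exactly twice, unmirrored and mirrored.
    """

    chosen_types: dict[int, list[ProcessingOp]]
    seed: int
    jobs: list[tuple[str, ProcessingOp, bool]] = field(repr=False)

    def job_counts(self) -> dict[int, int]:
        return {g: 2 * len(ops) for g, ops in self.chosen_types.items()}

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "chosen_types": {
                    str(g): [op.label() for op in ops]
                    for g, ops in self.chosen_types.items()
                },
                "jobs": [
                    {"image_id": img, "op": op.label(), "mirrored": m}
                    for img, op, m in self.jobs
                ],
            },
            indent=2,
            sort_keys=True,
        )


def make_plan(
    labels: Mapping[str, int],
    seed: int,
    ops: Sequence[ProcessingOp] | None = None,
) -> AugmentationPlan:
    """Sample per-grade processing types and expand to a job list.

    Types are sampled once per grade (not per image), without replacement
    from the nine kinds: 2 for grade 0, 1 each for grades 1 and 2, all 9
    for grade 3.  Every chosen type is applied to every image of the
    grade, once plain and once mirrored, so an image of grade g yields
    exactly ``MULTIPLIERS[g]`` jobs.  Identical seeds give identical
    plans.
    """
    pool = list(ops) if ops is not None else list(NINE_OPS)
    if len(pool) != 9:
        raise ValueError(f"expected nine processing types, got {len(pool)}")
    rng = np.random.default_rng(seed)
    grades_present = sorted({int(g) for g in labels.values()})
    chosen: dict[int, list[ProcessingOp]] = {}
    for g in grades_present:
        idx = rng.choice(len(pool), size=N_TYPES[g], replace=False)
        chosen[g] = [pool[i] for i in sorted(idx)]
    jobs: list[tuple[str, ProcessingOp, bool]] = []
    for img in sorted(labels):
        g = int(labels[img])
        for op in chosen[g]:
            jobs.append((img, op, False))
            jobs.append((img, op, True))
    return AugmentationPlan(chosen_types=chosen, seed=seed, jobs=jobs)


def amplified_counts(labels: Mapping[str, int] | Mapping[int, int]) -> dict[int, int]:
    """Per-grade image counts after amplification (n_g * m_g).

    Accepts either an image->grade label map or a grade->count map.
    """
    if labels and all(isinstance(k, (int, np.integer)) for k in labels):
        counts = {int(g): int(n) for g, n in labels.items()}
    else:
        counts = {}
        for g in labels.values():
            counts[int(g)] = counts.get(int(g), 0) + 1
    return {g: n * MULTIPLIERS[g] for g, n in sorted(counts.items())}


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError("expected an 8-bit RGB raster of shape (H, W, 3)")
    return image


def apply_op(
    image: np.ndarray,
    op: ProcessingOp,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply one processing type to an 8-bit RGB raster.

    Dimensions are preserved.  Gamma maps each channel value v to
    round(255 * (v/255)^gamma); contrast scales linearly about mid-grey
    (128); noise ops draw from `rng` (a fresh seeded generator when not
    given, so plans replay deterministically when the caller threads one
    through).
    """
    image = _check_rgb(image)
    if rng is None:
        rng = np.random.default_rng(0)
    kind = op.kind
    if kind == "none":
        return image.copy()
    if kind == "mirror":
        return image[:, ::-1].copy()
    if kind.startswith("gamma"):
        lut = np.round(255.0 * (np.arange(256) / 255.0) ** op.gamma).astype(np.uint8)
        return lut[image]
    if kind in ("contrast_up", "contrast_down"):
        out = 128.0 + op.contrast_factor * (image.astype(float) - 128.0)
        return np.clip(np.round(out), 0, 255).astype(np.uint8)
    if kind == "hist_equalise":
        out = np.empty_like(image)
        for c in range(3):
            eq = exposure.equalize_hist(image[..., c])
            out[..., c] = np.clip(np.round(eq * 255.0), 0, 255).astype(np.uint8)
        return out
    if kind == "gaussian_noise":
        noisy = image.astype(float) + rng.normal(0.0, op.noise_sigma, image.shape)
        return np.clip(np.round(noisy), 0, 255).astype(np.uint8)
    if kind == "salt_pepper":
        out = image.copy()
        h, w = image.shape[:2]
        n_px = int(round(op.sp_fraction * h * w))
        ys = rng.integers(0, h, size=n_px)
        xs = rng.integers(0, w, size=n_px)
        vals = rng.integers(0, 2, size=n_px) * 255
        out[ys, xs] = vals[:, None].astype(np.uint8)
        return out
    raise ValueError(f"unsupported processing op kind {kind!r}")
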