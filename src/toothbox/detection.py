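"""Hierarchical detection: main area first, then the five tooth blocks.

Detection is a pluggable contract: any backend exposing
``detect(image, target, slice_index=None, origin=(0, 0))`` and returning
``[Detection(box, label, score), ...]`` in the coordinates of the image it
was given can drive the pipeline — a truth-backed oracle for deterministic
tests, the bundled Otsu/connected-component heuristic for phantom-like
images, or a trained single-stage CNN detector.  Block detection runs on
the crop of the detected main area and results are mapped back to
full-image coordinates.

The grid utilities describe the single-stage detector geometry: a 416-px
input with a 32-px stride yields a 13x13 cell grid, which is why main-area
and block-sized objects (rather than single teeth) are the detected units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Protocol, Tuple

import numpy as np

from .geometry import BlockId, BlockName, Box, Chirality, Jaw

__all__ = [
    "Detection",
    "Detector",
    "GridSpec",
    "grid_cells",
    "DetectionError",
    "detect_main_area",
    "BlockDetectionResult",
    "detect_blocks",
    "HeuristicBlockDetector",
]


class Detection(NamedTuple):
    box: Box
    label: str
    score: float


class Detector(Protocol):
    def detect(
        self,
        image: np.ndarray,
        target: str,
        slice_index: Optional[int] = None,
        origin: Tuple[float, float] = (0.0, 0.0),
    ) -> List[Detection]:
        """Detect ``target`` ("main_area" or "blocks") objects on ``image``.

        ``origin`` is the full-image coordinate of the crop's top-left pixel;
        returned boxes are in crop coordinates.
        """
        ...


@dataclass(frozen=True)
class GridSpec:
    """Detector grid geometry: square input of ``input_size`` px, cell
    ``stride`` px."""

    input_size: int
    stride: int

    def __post_init__(self) -> None:
        if self.input_size <= 0 or self.stride <= 0:
            raise ValueError("input_size and stride must be positive")
        if self.input_size % self.stride:
            raise ValueError(
                f"input_size {self.input_size} not divisible by stride {self.stride}"
            )


def grid_cells(spec: GridSpec) -> int:
    """Cells per side of the detection grid (416/32 -> 13)."""
    return spec.input_size // spec.stride


class DetectionError(RuntimeError):
    """No acceptable detection; carries the best score seen (None if none)."""

    def __init__(self, message: str, best_score: Optional[float] = None):
        super().__init__(message)
        self.best_score = best_score


def detect_main_area(
    image: np.ndarray,
    detector: Detector,
    score_threshold: float = 0.5,
    slice_index: Optional[int] = None,
) -> Box:
    """The highest-scoring main-area box, clamped to the image bounds."""
    dets = detector.detect(image, "main_area", slice_index=slice_index)
    dets = [d for d in dets if d.label == "main_area"]
    if not dets:
        raise DetectionError("no main-area detection returned")
    best = max(dets, key=lambda d: d.score)
    if best.score < score_threshold:
        raise DetectionError(
            f"best main-area score {best.score:.3f} below threshold "
            f"{score_threshold}",
            best_score=best.score,
        )
    h, w = image.shape[:2]
    return best.box.clamp(w, h)


@dataclass
class BlockDetectionResult:
    """Per-block boxes (at most one per block, highest score wins) and the
    blocks for which no detection was produced."""

    blocks: Dict[BlockId, Tuple[Box, float]]
    missing: List[BlockId] = field(default_factory=list)


def detect_blocks(
    image: np.ndarray,
    main_area: Box,
    detector: Detector,
    jaw: Jaw,
    score_threshold: float = 0.5,
    slice_index: Optional[int] = None,
) -> BlockDetectionResult:
    """Detect the five tooth blocks inside the main-area crop.

    The detector sees the crop and labels blocks by :class:`BlockName`
    value; boxes are mapped back to full-image coordinates.  Missing blocks
    are reported, never extrapolated.
    """
    h, w = image.shape[:2]
    main = main_area.clamp(w, h)
    l, t = int(np.floor(main.L)), int(np.floor(main.T))
    r, b = int(np.ceil(main.R)), int(np.ceil(main.B))
    crop = image[t:b, l:r]
    if crop.size == 0:
        raise DetectionError("main area crop is empty")
    dets = detector.detect(
        crop, "blocks", slice_index=slice_index, origin=(float(l), float(t))
    )
    best: Dict[BlockName, Tuple[Box, float]] = {}
    for d in dets:
        if d.score < score_threshold:
            continue
        try:
            name = BlockName(d.label)
        except ValueError as e:
            raise DetectionError(f"unknown block label {d.label!r}") from e
        box = d.box.translate(float(l), float(t)).clamp(w, h)
        if name not in best or d.score > best[name][1]:
            best[name] = (box, d.score)
    if not best:
        raise DetectionError("zero blocks detected", best_score=None)
    blocks = {BlockId(jaw, name): v for name, v in best.items()}
    missing = [
        BlockId(jaw, name) for name in BlockName if BlockId(jaw, name) not in blocks
    ]
    return BlockDetectionResult(blocks=blocks, missing=missing)


class HeuristicBlockDetector:
    """Reference detection backend for bright-teeth-on-dark phantom images.

    Pipeline: 3-class Otsu threshold isolates the brightest structures
    (tooth crowns) from bone and background; connected components above
    ``min_area`` become candidate teeth; a parabola fitted to the component
    centroids models the dental arch, and components are grouped into the
    five blocks by their normalized arc-length position along the arch
    (cut points at 3/16, 6/16, 10/16 and 13/16 of the arch, matching the
    3+3+4+3+3 block layout of a full dentition).
    """

    def __init__(
        self, min_area: int = 6, chirality: Chirality = Chirality.RADIOLOGICAL
    ):
        self.min_area = min_area
        self.chirality = Chirality(chirality)

    # --- internals ---------------------------------------------------------

    def _components(self, image: np.ndarray):
        from skimage.filters import threshold_multiotsu
        from skimage.measure import label as cc_label, regionprops

        img = np.asarray(image, dtype=np.float64)
        if img.max() <= img.min():
            raise DetectionError("blank image: no foreground components")
        try:
            thr = threshold_multiotsu(img, classes=3)[-1]
        except ValueError as e:
            raise DetectionError("image has too few gray levels") from e
        regions = [
            r for r in regionprops(cc_label(img > thr)) if r.area >= self.min_area
        ]
        if len(regions) < 3:
            raise DetectionError(
                f"only {len(regions)} foreground components; need >= 3"
            )
        return regions

    @staticmethod
    def _component_box(region) -> Box:
        minr, minc, maxr, maxc = region.bbox
        return Box(float(minc), float(minr), float(maxc), float(maxr))

    @staticmethod
    def _arc_positions(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Arc length along the fitted parabolic arch at each component x."""
        coef = np.polyfit(xs, ys, deg=2) if len(xs) >= 3 else np.array([0, 0, 0])
        a = coef[0]

        def arc(x0: float, x1: float) -> float:
            # integral of sqrt(1 + (y')^2) along the parabola
            xs_ = np.linspace(x0, x1, 64)
            dy = 2 * a * xs_ + coef[1]
            return float(np.trapezoid(np.sqrt(1 + dy * dy), xs_))

        order = np.argsort(xs, kind="stable")
        s = np.empty(len(xs))
        acc = 0.0
        prev = xs[order[0]]
        for k in order:
            acc += arc(prev, xs[k])
            s[k] = acc
            prev = xs[k]
        return s

    # --- contract ----------------------------------------------------------

    def detect(
        self,
        image: np.ndarray,
        target: str,
        slice_index: Optional[int] = None,
        origin: Tuple[float, float] = (0.0, 0.0),
    ) -> List[Detection]:
        regions = self._components(image)
        boxes = [self._component_box(r) for r in regions]
        if target == "main_area":
            return [Detection(Box.union_of(boxes), "main_area", 1.0)]
        if target != "blocks":
            raise ValueError(f"unknown detection target {target!r}")

        xs = np.array([r.centroid[1] for r in regions])
        ys = np.array([r.centroid[0] for r in regions])
        s = self._arc_positions(xs, ys)
        # map measured arc positions onto the canonical 16-slot arch: the
        # first and last components are assumed to sit at the first and
        # last occupied slot centers (exact for a full dentition)
        from .phantom import arch_slot_fractions

        slots = arch_slot_fractions()
        span = s.max() - s.min()
        if span <= 0:
            raise DetectionError("degenerate arch: all components coincide")
        u = slots[0] + (s - s.min()) / span * (slots[-1] - slots[0])

        image_left_blocks = [
            BlockName.RIGHT_MOLAR,
            BlockName.RIGHT_CANINE_PREMOLAR,
            BlockName.INCISORS,
            BlockName.LEFT_CANINE_PREMOLAR,
            BlockName.LEFT_MOLAR,
        ]
        if self.chirality is Chirality.ANATOMICAL:
            image_left_blocks.reverse()
        # slot index -> block: 3 molars, 3 canine/premolars, 4 incisors, ...
        slot_block = [0] * 3 + [1] * 3 + [2] * 4 + [3] * 3 + [4] * 3
        groups: Dict[BlockName, List[Box]] = {}
        for ui, box in zip(u, boxes):
            k = int(np.argmin(np.abs(slots - ui)))
            groups.setdefault(image_left_blocks[slot_block[k]], []).append(box)
        return [
            Detection(Box.union_of(bs), name.value, 1.0)
            for name, bs in groups.items()
        ]
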