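"""Deterministic dental-phantom generator with full ground truth.

The phantom emulates the geometry a bottom-to-top axial CBCT stack presents
to the detection pipeline: five z-regions (lower no-tooth, lower crown,
overlap, upper crown, upper no-tooth), up to 16 teeth per jaw drawn as
bright axis-aligned ellipses placed at equal arc-length intervals along a
parabolic dental arch, a duller jaw-bone band under the arch, configurable
missing teeth, optional metal-artefact streaks radiating from a chosen
tooth, and additive Gaussian noise.  Intensities before noise are 0.1
(background), 0.4 (bone) and 0.9 (teeth) of the dynamic range; uint8 by
default, uint16 optionally, mirroring 16-bit clinical exports.

Ground truth is exact by construction: each tooth's mask is the rasterized
ellipse, its box the tight bounding box of that mask, block boxes the union
of their member tooth boxes, and the main area the union of all tooth boxes
on the slice — so the containment chain mask <= tooth box <= block box <=
main area holds identically.

The module also provides truth-backed oracle backends (a slice classifier
with an optional seeded label-flip rate, and a detector with optional
uniform box jitter and block suppression) used to exercise the pipeline
deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .geometry import (
    BlockId,
    Box,
    Chirality,
    ClassLabel,
    FdiTooth,
    Jaw,
    LayerLabel,
    arch_order,
    block_of,
)
from .io import SliceStack, ZDirection
from .layers import LAYER_SEQUENCE

__all__ = [
    "ArchSpec",
    "ArtefactConfig",
    "PhantomConfig",
    "PhantomTruth",
    "generate_stack",
    "add_metal_artefacts",
    "OracleSliceClassifier",
    "OracleDetector",
    "DEFAULT_TOOTH_RADII",
]


@dataclass(frozen=True)
class ArchSpec:
    """Parabolic dental arch ``y = apex_y + curvature * (x - apex_x)**2``
    over ``x`` in ``[apex_x - width/2, apex_x + width/2]`` (y grows toward
    the posterior edge of the image)."""

    apex_x: float
    apex_y: float
    curvature: float
    width: float

    def y(self, x: np.ndarray) -> np.ndarray:
        return self.apex_y + self.curvature * (np.asarray(x) - self.apex_x) ** 2


#: (rx, ry) half-axes in px per FDI position (1 = central incisor .. 8 =
#: third molar), anatomically sized at the default 0.4 mm pixel spacing:
#: mesiodistal crown widths of ~7.5/6.5/7/7/7/10.5/10/9.5 mm.
DEFAULT_TOOTH_RADII: Dict[int, Tuple[float, float]] = {
    1: (9.0, 9.0),
    2: (8.0, 9.0),
    3: (9.0, 10.0),
    4: (9.0, 11.0),
    5: (9.0, 11.0),
    6: (13.0, 12.0),
    7: (12.0, 12.0),
    8: (12.0, 11.0),
}


def arch_slot_fractions(
    tooth_radii: Mapping[int, Tuple[float, float]] = DEFAULT_TOOTH_RADII,
) -> np.ndarray:
    """Arc-length center fraction of each of a jaw's 16 teeth.

    Teeth occupy arc in proportion to their mesiodistal width, so tooth k's
    center sits at ``(cum_width_before + width_k / 2) / total_width`` of the
    arch, in image order (third molar .. third molar).
    """
    positions = list(range(8, 0, -1)) + list(range(1, 9))
    widths = np.array([2.0 * tooth_radii[p][0] for p in positions])
    cum = np.concatenate([[0.0], np.cumsum(widths)])
    return (cum[:-1] + widths / 2.0) / cum[-1]


@dataclass(frozen=True)
class ArtefactConfig:
    """Metal-artefact streaks radiating from one (restored) tooth."""

    tooth: FdiTooth
    n_streaks: int = 8
    intensity: float = 1.0  # fraction of dynamic range for bright streaks
    n_dark_bands: int = 2


@dataclass
class PhantomConfig:
    image_size: int = 256
    region_lengths: Tuple[int, int, int, int, int] = (7, 10, 6, 10, 7)
    lower_arch: ArchSpec = field(
        default_factory=lambda: ArchSpec(128.0, 45.0, 0.021, 190.0)
    )
    upper_arch: ArchSpec = field(
        default_factory=lambda: ArchSpec(128.0, 82.0, 0.034, 130.0)
    )
    upper_radius_scale: float = 0.8
    pixel_spacing: float = 0.4
    slice_thickness: float = 0.4
    tooth_radii: Mapping[int, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TOOTH_RADII)
    )
    missing: FrozenSet[FdiTooth] = frozenset()
    artefact: Optional[ArtefactConfig] = None
    noise_sigma: float = 0.02  # fraction of dynamic range
    bone_half_width: float = 14.0
    dtype: str = "uint8"
    seed: int = 0

    @property
    def n_slices(self) -> int:
        return int(sum(self.region_lengths))

    def __post_init__(self) -> None:
        if len(self.region_lengths) != 5 or any(l < 0 for l in self.region_lengths):
            raise ValueError("region_lengths must be 5 nonnegative ints")
        if self.n_slices < 1:
            raise ValueError("phantom needs at least one slice")
        for rx, ry in self.tooth_radii.values():
            if rx <= 0 or ry <= 0:
                raise ValueError("tooth radii must be positive")
        self.missing = frozenset(self.missing)


@dataclass
class PhantomTruth:
    """Exact per-slice ground truth of a generated phantom."""

    class_labels: List[ClassLabel]
    layer_labels: List[LayerLabel]
    masks: List[Dict[FdiTooth, np.ndarray]]
    boxes: List[Dict[FdiTooth, Box]]
    block_boxes: List[Dict[BlockId, Box]]
    main_box: List[Optional[Box]]

    def labelmap(self, slice_index: int, jaw: Jaw) -> np.ndarray:
        """uint8 map of one jaw's tooth masks, pixel value = FDI code."""
        masks = self.masks[slice_index]
        any_mask = next(iter(masks.values()), None)
        if any_mask is None:
            raise ValueError(f"slice {slice_index} carries no teeth")
        out = np.zeros(any_mask.shape, dtype=np.uint8)
        for tooth, m in masks.items():
            if tooth.jaw is jaw:
                out[m] = tooth.code
        return out


def _arc_x_positions(arch: ArchSpec, fractions: np.ndarray) -> np.ndarray:
    """x coordinates at given arc-length fractions along the arch."""
    xs = np.linspace(arch.apex_x - arch.width / 2, arch.apex_x + arch.width / 2, 2048)
    dy = 2 * arch.curvature * (xs - arch.apex_x)
    ds = np.sqrt(1.0 + dy * dy)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(xs))])
    return np.interp(fractions * s[-1], s, xs)


def _jaw_layout(
    cfg: PhantomConfig, jaw: Jaw
) -> Tuple[Dict[FdiTooth, np.ndarray], Dict[FdiTooth, Box], np.ndarray]:
    """Masks, tight boxes and the bone band for one jaw's crown plane."""
    n = cfg.image_size
    arch = cfg.lower_arch if jaw is Jaw.LOWER else cfg.upper_arch
    scale = 1.0 if jaw is Jaw.LOWER else cfg.upper_radius_scale
    teeth = [t for t in arch_order(jaw, Chirality.RADIOLOGICAL) if t not in cfg.missing]
    all_teeth = arch_order(jaw, Chirality.RADIOLOGICAL)
    slot = arch_slot_fractions(cfg.tooth_radii)
    fractions = np.array([slot[all_teeth.index(t)] for t in teeth])
    cx = _arc_x_positions(arch, fractions)
    cy = arch.y(cx)

    Y, X = np.mgrid[0:n, 0:n]
    Xc, Yc = X + 0.5, Y + 0.5
    masks: Dict[FdiTooth, np.ndarray] = {}
    boxes: Dict[FdiTooth, Box] = {}
    for tooth, x0, y0 in zip(teeth, cx, cy):
        rx, ry = cfg.tooth_radii[tooth.position]
        rx, ry = rx * scale, ry * scale
        mask = ((Xc - x0) / rx) ** 2 + ((Yc - y0) / ry) ** 2 <= 1.0
        if not mask.any():
            raise ValueError(f"tooth {tooth.code} rasterized to an empty mask")
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        masks[tooth] = mask
        boxes[tooth] = Box(
            float(cols[0]), float(rows[0]), float(cols[-1] + 1), float(rows[-1] + 1)
        )
    band = (np.abs(Yc - arch.y(Xc)) <= cfg.bone_half_width) & (
        np.abs(Xc - arch.apex_x) <= arch.width / 2 + 6.0
    )
    return masks, boxes, band


def _block_boxes(boxes: Mapping[FdiTooth, Box]) -> Dict[BlockId, Box]:
    grouped: Dict[BlockId, List[Box]] = {}
    for tooth, box in boxes.items():
        grouped.setdefault(block_of(tooth), []).append(box)
    return {b: Box.union_of(bs) for b, bs in grouped.items()}


def generate_stack(cfg: PhantomConfig) -> Tuple[SliceStack, PhantomTruth]:
    """Render the phantom stack and its exact ground truth.

    Deterministic for a fixed config (including the seed).  The overlap
    region draws both jaws; no-tooth regions draw only the bone band.
    """
    n = cfg.image_size
    dtype = np.dtype(cfg.dtype)
    if dtype not in (np.dtype("uint8"), np.dtype("uint16")):
        raise ValueError("dtype must be uint8 or uint16")
    rng = np.random.default_rng([cfg.seed, 1])
    dyn = float(np.iinfo(dtype).max)

    lower_masks, lower_boxes, lower_bone = _jaw_layout(cfg, Jaw.LOWER)
    upper_masks, upper_boxes, upper_bone = _jaw_layout(cfg, Jaw.UPPER)
    lower_blocks = _block_boxes(lower_boxes)
    upper_blocks = _block_boxes(upper_boxes)

    region_class = [
        ClassLabel.NO_TOOTH,
        ClassLabel.CROWN,
        ClassLabel.OVERLAP,
        ClassLabel.CROWN,
        ClassLabel.NO_TOOTH,
    ]
    # (teeth dicts, box dicts, block dicts, bone mask) per region
    empty: Dict = {}
    region_content = [
        (empty, empty, empty, lower_bone),
        (lower_masks, lower_boxes, lower_blocks, lower_bone),
        (
            {**lower_masks, **upper_masks},
            {**lower_boxes, **upper_boxes},
            {**lower_blocks, **upper_blocks},
            lower_bone | upper_bone,
        ),
        (upper_masks, upper_boxes, upper_blocks, upper_bone),
        (empty, empty, empty, upper_bone),
    ]

    class_labels: List[ClassLabel] = []
    layer_labels: List[LayerLabel] = []
    masks, boxes, blocks, mains = [], [], [], []
    slices = np.empty((cfg.n_slices, n, n), dtype=dtype)
    z = 0
    for region, length in enumerate(cfg.region_lengths):
        r_masks, r_boxes, r_blocks, bone = region_content[region]
        teeth_union = np.zeros((n, n), dtype=bool)
        for m in r_masks.values():
            teeth_union |= m
        base = np.full((n, n), 0.1)
        base[bone] = 0.4
        base[teeth_union] = 0.9
        main = Box.union_of(r_boxes.values()) if r_boxes else None
        for _ in range(length):
            img = base + rng.normal(0.0, cfg.noise_sigma, size=(n, n))
            slices[z] = np.clip(img, 0.0, 1.0) * dyn
            class_labels.append(region_class[region])
            layer_labels.append(LAYER_SEQUENCE[region])
            masks.append(r_masks)
            boxes.append(r_boxes)
            blocks.append(r_blocks)
            mains.append(main)
            z += 1

    stack = SliceStack(
        slices,
        pixel_spacing=cfg.pixel_spacing,
        slice_thickness=cfg.slice_thickness,
        z_direction=ZDirection.BOTTOM_TO_TOP,
    )
    truth = PhantomTruth(class_labels, layer_labels, masks, boxes, blocks, mains)
    if cfg.artefact is not None:
        stack = add_metal_artefacts(stack, truth, cfg)
    return stack, truth


def add_metal_artefacts(
    stack: SliceStack, truth: PhantomTruth, cfg: PhantomConfig
) -> SliceStack:
    """Overlay bright radial streaks plus dark bands around a restored tooth.

    Streak rays emanate from the named tooth's box center on every slice
    where the tooth is present; ground truth is unchanged.  Deterministic
    for a fixed config seed; a zero streak count is a no-op.
    """
    from skimage.draw import line as draw_line

    art = cfg.artefact
    if art is None:
        raise ValueError("no artefact config present")
    hit_slices = [i for i, b in enumerate(truth.boxes) if art.tooth in b]
    if not hit_slices:
        raise ValueError(
            f"artefact tooth {art.tooth.code} is missing from the phantom"
        )
    if art.n_streaks == 0 and art.n_dark_bands == 0:
        return stack

    rng = np.random.default_rng([cfg.seed, 777])
    angles = rng.uniform(0.0, 2 * np.pi, size=art.n_streaks)
    dark_angles = rng.uniform(0.0, 2 * np.pi, size=art.n_dark_bands)
    out = stack.slices.copy()
    dyn = float(np.iinfo(out.dtype).max)
    h, w = out.shape[1:]
    bright = min(art.intensity, 1.0) * dyn
    reach = float(np.hypot(h, w))

    for i in hit_slices:
        cx, cy = truth.boxes[i][art.tooth].center
        r0, c0 = int(round(cy)), int(round(cx))
        for ang, value in [(a, bright) for a in angles] + [
            (a, 0.05 * dyn) for a in dark_angles
        ]:
            r1 = int(round(cy + reach * np.sin(ang)))
            c1 = int(round(cx + reach * np.cos(ang)))
            rr, cc = draw_line(r0, c0, r1, c1)
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            out[i, rr[keep], cc[keep]] = value
    return SliceStack(
        out, stack.pixel_spacing, stack.slice_thickness, stack.z_direction
    )


# ---------------------------------------------------------------------------
# Truth-backed oracles
# ---------------------------------------------------------------------------

class OracleSliceClassifier:
    """Slice classifier that returns the true class, optionally corrupted.

    With ``error_rate > 0`` each slice's label is flipped, independently and
    reproducibly (seeded), to a uniformly chosen wrong class — used to
    exercise the anti-noise switch under realistic misclassification.
    """

    def __init__(
        self,
        class_labels: Sequence[ClassLabel],
        error_rate: float = 0.0,
        seed: int = 0,
    ):
        if not 0.0 <= error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        rng = np.random.default_rng([seed, 101])
        all_classes = list(ClassLabel)
        self.labels: List[ClassLabel] = []
        for true in class_labels:
            true = ClassLabel(true)
            if rng.random() < error_rate:
                wrong = [c for c in all_classes if c != true]
                self.labels.append(wrong[int(rng.integers(len(wrong)))])
            else:
                self.labels.append(true)

    def classify(self, image, slice_index: Optional[int] = None) -> ClassLabel:
        if slice_index is None:
            raise ValueError("oracle classifier needs the slice index")
        return self.labels[slice_index]


class OracleDetector:
    """Detector that replays ground-truth main-area and block boxes.

    ``jitter_px`` displaces each box by a uniform offset in [-j, +j] per
    axis (seeded per slice and target, so repeated calls are identical);
    ``drop`` suppresses
    blocks by :class:`BlockName` or :class:`BlockId`.  Scores are 1.0.
    """

    def __init__(
        self,
        truth: PhantomTruth,
        jitter_px: float = 0.0,
        drop: FrozenSet = frozenset(),
        seed: int = 0,
    ):
        self.truth = truth
        self.jitter_px = float(jitter_px)
        self.drop = frozenset(drop)
        self.seed = int(seed)

    def _jitter(self, box: Box, rng: np.random.Generator) -> Box:
        # positional jitter: the box is displaced, not reshaped, so the
        # worst-case IoU against truth is (W-j)(H-j) / ((W+j)(H+j))
        if self.jitter_px == 0.0:
            return box
        dx, dy = rng.uniform(-self.jitter_px, self.jitter_px, size=2)
        return box.translate(float(dx), float(dy))

    def detect(
        self,
        image,
        target: str,
        slice_index: Optional[int] = None,
        origin: Tuple[float, float] = (0.0, 0.0),
    ):
        from .detection import Detection

        if slice_index is None:
            raise ValueError("oracle detector needs the slice index")
        ox, oy = origin
        if target == "main_area":
            main = self.truth.main_box[slice_index]
            if main is None:
                return []
            rng = np.random.default_rng([self.seed, slice_index, 11])
            return [Detection(self._jitter(main, rng).translate(-ox, -oy),
                              "main_area", 1.0)]
        if target != "blocks":
            raise ValueError(f"unknown detection target {target!r}")
        out = []
        items = sorted(
            self.truth.block_boxes[slice_index].items(), key=lambda kv: kv[0].key
        )
        for k, (block, box) in enumerate(items):
            if block in self.drop or block.block in self.drop:
                continue
            rng = np.random.default_rng([self.seed, slice_index, 23, k])
            out.append(
                Detection(self._jitter(box, rng).translate(-ox, -oy),
                          block.block.value, 1.0)
            )
        return out
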