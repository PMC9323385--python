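"""Geometry primitives, FDI tooth numbering, and the five-block dental anatomy.

Coordinate convention: continuous pixel coordinates, origin at the top-left
corner of the image, x rightward, y downward.  A box is the half-open region
``[L, R) x [T, B)`` on the real plane, so its area is ``(R - L) * (B - T)``;
this matches Pascal-VOC-style box arithmetic once the 1-based inclusive
integers of the XML dialect are converted (see :mod:`toothbox.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, List, Tuple

__all__ = [
    "Box",
    "FdiTooth",
    "Jaw",
    "BlockName",
    "BlockId",
    "ClassLabel",
    "LayerLabel",
    "Chirality",
    "ALL_BLOCKS",
    "BLOCK_POSITIONS",
    "block_teeth",
    "iou",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle ``(L, T, R, B)`` in pixel coordinates.

    Invariants: ``L <= R``, ``T <= B``, all coordinates finite.
    """

    L: float
    T: float
    R: float
    B: float

    def __post_init__(self) -> None:
        for v in (self.L, self.T, self.R, self.B):
            if not math.isfinite(v):
                raise ValueError(f"box coordinates must be finite, got {self!r}")
        if self.L > self.R or self.T > self.B:
            raise ValueError(f"degenerate box ordering: {self!r}")

    @property
    def width(self) -> float:
        return self.R - self.L

    @property
    def height(self) -> float:
        return self.B - self.T

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> Tuple[float, float]:
        return (0.5 * (self.L + self.R), 0.5 * (self.T + self.B))

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.L, self.T, self.R, self.B)

    def translate(self, dx: float, dy: float) -> "Box":
        return Box(self.L + dx, self.T + dy, self.R + dx, self.B + dy)

    def clamp(self, width: float, height: float) -> "Box":
        """Clamp the box into the image rectangle ``[0, width) x [0, height)``."""
        clip = lambda v, hi: min(max(v, 0.0), float(hi))
        L, R = clip(self.L, width), clip(self.R, width)
        T, B = clip(self.T, height), clip(self.B, height)
        return Box(L, T, R, B)

    def contains_box(self, other: "Box", tol: float = 0.0) -> bool:
        return (
            other.L >= self.L - tol
            and other.T >= self.T - tol
            and other.R <= self.R + tol
            and other.B <= self.B + tol
        )

    @staticmethod
    def union_of(boxes: Iterable["Box"]) -> "Box":
        boxes = list(boxes)
        if not boxes:
            raise ValueError("union of empty box collection")
        return Box(
            min(b.L for b in boxes),
            min(b.T for b in boxes),
            max(b.R for b in boxes),
            max(b.B for b in boxes),
        )


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 for disjoint or both-degenerate."""
    iw = min(a.R, b.R) - max(a.L, b.L)
    ih = min(a.B, b.B) - max(a.T, b.T)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return inter / union


@dataclass(frozen=True, order=True)
class FdiTooth:
    """One permanent tooth in FDI two-digit notation.

    ``quadrant`` runs 1 (upper right) .. 4 (lower right) clockwise as seen
    from the patient's perspective; ``position`` runs 1 (central incisor) ..
    8 (third molar) from the midline outward.  ``code = 10*quadrant +
    position``, e.g. 45 = lower-right second premolar.
    """

    quadrant: int
    position: int

    def __post_init__(self) -> None:
        if self.quadrant not in (1, 2, 3, 4):
            raise ValueError(f"FDI quadrant must be 1..4, got {self.quadrant}")
        if not 1 <= self.position <= 8:
            raise ValueError(f"FDI position must be 1..8, got {self.position}")

    @property
    def code(self) -> int:
        return 10 * self.quadrant + self.position

    @classmethod
    def from_code(cls, code: int) -> "FdiTooth":
        return cls(code // 10, code % 10)

    @property
    def jaw(self) -> "Jaw":
        return Jaw.UPPER if self.quadrant in (1, 2) else Jaw.LOWER

    def __repr__(self) -> str:  # compact: the FDI code is the universal name
        return f"FdiTooth({self.code})"


class Jaw(str, Enum):
    UPPER = "upper"
    LOWER = "lower"


class BlockName(str, Enum):
    """The five anatomical blocks each jaw's arch is divided into.

    ``right``/``left`` are patient sides (quadrants 1/4 are the patient's
    right); how they map to image left/right depends on :class:`Chirality`.
    """

    INCISORS = "incisors"
    RIGHT_CANINE_PREMOLAR = "right_canine_premolar"
    LEFT_CANINE_PREMOLAR = "left_canine_premolar"
    RIGHT_MOLAR = "right_molar"
    LEFT_MOLAR = "left_molar"


class Chirality(str, Enum):
    """Display convention of axial slices.

    ``RADIOLOGICAL``: the patient's right appears on the image left (the
    common viewing convention for axial CT); ``ANATOMICAL``: mirrored.
    """

    RADIOLOGICAL = "radiological"
    ANATOMICAL = "anatomical"


@dataclass(frozen=True)
class BlockId:
    jaw: Jaw
    block: BlockName

    def __repr__(self) -> str:
        return f"BlockId({self.jaw.value}.{self.block.value})"

    @property
    def key(self) -> str:
        return f"{self.jaw.value}_{self.block.value}"

    @classmethod
    def from_key(cls, key: str) -> "BlockId":
        jaw, _, block = key.partition("_")
        return cls(Jaw(jaw), BlockName(block))


class ClassLabel(str, Enum):
    """Appearance class of a single axial slice (3-way classifier output)."""

    NO_TOOTH = "no_tooth"
    CROWN = "crown"
    OVERLAP = "overlap"


class LayerLabel(str, Enum):
    """The five z-regions of a bottom-to-top scan, in anatomical order."""

    LOWER_NO_TOOTH = "lower_no_tooth"
    LOWER_CROWN = "lower_crown"
    OVERLAP = "overlap"
    UPPER_CROWN = "upper_crown"
    UPPER_NO_TOOTH = "upper_no_tooth"


ALL_BLOCKS: Tuple[BlockId, ...] = tuple(
    BlockId(jaw, block) for jaw in Jaw for block in BlockName
)

# Positions (distance from midline) belonging to each block; the side of the
# canine/premolar and molar blocks selects the quadrant.
BLOCK_POSITIONS = {
    BlockName.INCISORS: (1, 2),
    BlockName.RIGHT_CANINE_PREMOLAR: (3, 4, 5),
    BlockName.LEFT_CANINE_PREMOLAR: (3, 4, 5),
    BlockName.RIGHT_MOLAR: (6, 7, 8),
    BlockName.LEFT_MOLAR: (6, 7, 8),
}

# Quadrant on the patient's right / left side, per jaw.
_RIGHT_QUADRANT = {Jaw.UPPER: 1, Jaw.LOWER: 4}
_LEFT_QUADRANT = {Jaw.UPPER: 2, Jaw.LOWER: 3}


def arch_order(jaw: Jaw, chirality: Chirality = Chirality.RADIOLOGICAL) -> List[FdiTooth]:
    """All 16 teeth of one jaw ordered left-to-right in image coordinates.

    Under the radiological convention the image-left end of the arch is the
    patient's right third molar, so the upper jaw reads 18..11, 21..28.
    """
    rq, lq = _RIGHT_QUADRANT[jaw], _LEFT_QUADRANT[jaw]
    order = [FdiTooth(rq, p) for p in range(8, 0, -1)] + [
        FdiTooth(lq, p) for p in range(1, 9)
    ]
    if chirality is Chirality.ANATOMICAL:
        order.reverse()
    return order


def block_of(tooth: FdiTooth) -> BlockId:
    """The block a tooth belongs to."""
    side_right = tooth.quadrant in (1, 4)
    if tooth.position <= 2:
        name = BlockName.INCISORS
    elif tooth.position <= 5:
        name = BlockName.RIGHT_CANINE_PREMOLAR if side_right else BlockName.LEFT_CANINE_PREMOLAR
    else:
        name = BlockName.RIGHT_MOLAR if side_right else BlockName.LEFT_MOLAR
    return BlockId(tooth.jaw, name)


def block_teeth(
    block: BlockId, chirality: Chirality = Chirality.RADIOLOGICAL
) -> List[FdiTooth]:
    """Teeth of a block, ordered left-to-right in image coordinates.

    E.g. the upper incisor block under the radiological convention is
    [12, 11, 21, 22]; the lower-right canine/premolar block is {43, 44, 45}.
    """
    chirality = Chirality(chirality)
    return [t for t in arch_order(block.jaw, chirality) if block_of(t) == block]
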