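"""Slice classification plumbing and the anti-noise layer-label switch.

An axial CBCT stack scanned bottom-to-top traverses five z-regions: lower
no-tooth, lower crown, overlap (both dentitions visible), upper crown, upper
no-tooth.  A per-slice classifier only distinguishes three appearance
classes (no-tooth / crown / overlap); the 3-class sequence is lifted to the
5-region labeling by a monotone state machine that advances to the next
region only after a *confirmed run* of the expected new class.  A lone
misclassified slice therefore never flips the region: with per-slice error
rate p, a spurious run of k consecutive identical errors has probability
p**k under the independent-error model (0.25% for p=0.05, k=2).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import ClassLabel, LayerLabel

__all__ = [
    "ClassLabel",
    "LayerLabel",
    "LAYER_SEQUENCE",
    "LAYER_CLASS",
    "SwitchConfig",
    "LayerLabeling",
    "consecutive_error_probability",
    "anti_noise_switch",
    "select_key_slices",
    "key_slice_jaws",
    "preprocess_stack",
    "AntiNoiseLayerLabeler",
    "ThresholdSliceClassifier",
]


#: Region order along the scan direction (bottom to top).
LAYER_SEQUENCE: Tuple[LayerLabel, ...] = (
    LayerLabel.LOWER_NO_TOOTH,
    LayerLabel.LOWER_CROWN,
    LayerLabel.OVERLAP,
    LayerLabel.UPPER_CROWN,
    LayerLabel.UPPER_NO_TOOTH,
)

#: Appearance class each region presents to the slice classifier.
LAYER_CLASS = {
    LayerLabel.LOWER_NO_TOOTH: ClassLabel.NO_TOOTH,
    LayerLabel.LOWER_CROWN: ClassLabel.CROWN,
    LayerLabel.OVERLAP: ClassLabel.OVERLAP,
    LayerLabel.UPPER_CROWN: ClassLabel.CROWN,
    LayerLabel.UPPER_NO_TOOTH: ClassLabel.NO_TOOTH,
}


class ScanDirection(str, Enum):
    BOTTOM_TO_TOP = "bottom_to_top"
    TOP_TO_BOTTOM = "top_to_bottom"


@dataclass
class SwitchConfig:
    """Anti-noise switch parameters.

    ``confirm_run`` is the total number of consecutive identical new-class
    labels (including the first changed slice) required before the region
    label advances.  The default of 3 makes a spurious switch require three
    consecutive identical classifier errors.
    """

    confirm_run: int = 3
    scan_direction: ScanDirection = ScanDirection.BOTTOM_TO_TOP

    def __post_init__(self) -> None:
        if self.confirm_run < 1:
            raise ValueError("confirm_run must be >= 1")
        self.scan_direction = ScanDirection(self.scan_direction)


@dataclass
class LayerLabeling:
    """Per-slice class labels, 5-region layer labels, and region boundaries.

    ``boundaries`` holds, for each of the four regions after the first, the
    index of its first slice (``n_slices`` when the region is empty).
    Indices refer to the sequence as supplied (slice order of the stack).
    """

    class_labels: List[ClassLabel]
    layer_labels: List[LayerLabel]
    boundaries: List[int]

    def __len__(self) -> int:
        return len(self.layer_labels)

    def region_indices(self, layer: LayerLabel) -> List[int]:
        return [i for i, l in enumerate(self.layer_labels) if l == layer]

    def to_json_obj(self) -> dict:
        return {
            "class_labels": [c.value for c in self.class_labels],
            "layer_labels": [l.value for l in self.layer_labels],
            "boundaries": list(self.boundaries),
        }

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_json_obj(), indent=1))

    @classmethod
    def from_json_obj(cls, obj: dict) -> "LayerLabeling":
        return cls(
            [ClassLabel(c) for c in obj["class_labels"]],
            [LayerLabel(l) for l in obj["layer_labels"]],
            [int(b) for b in obj["boundaries"]],
        )


def consecutive_error_probability(per_slice_error: float, k: int) -> float:
    """Probability of k consecutive misclassifications (independent errors).

    With 95% per-slice accuracy this gives 0.25% for k=2 and 0.0125% for
    k=3 — the chance that noise defeats a confirm run of that length.
    """
    if not 0.0 <= per_slice_error <= 1.0:
        raise ValueError("per_slice_error must be in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return per_slice_error ** k


def _switch_bottom_to_top(
    labels: Sequence[ClassLabel], confirm_run: int
) -> Tuple[List[LayerLabel], List[int]]:
    n = len(labels)
    # run_len[i]: length of the run of identical labels starting at i
    run_len = [0] * n
    run_len[-1] = 1
    for i in range(n - 2, -1, -1):
        run_len[i] = run_len[i + 1] + 1 if labels[i] == labels[i + 1] else 1

    state = 0
    boundaries: List[int] = []
    out: List[LayerLabel] = []
    for i in range(n):
        if (
            state < len(LAYER_SEQUENCE) - 1
            and labels[i] == LAYER_CLASS[LAYER_SEQUENCE[state + 1]]
            and run_len[i] >= confirm_run
        ):
            state += 1
            boundaries.append(i)
        out.append(LAYER_SEQUENCE[state])
    boundaries += [n] * (4 - len(boundaries))
    return out, boundaries


def anti_noise_switch(
    class_labels: Sequence[ClassLabel], cfg: Optional[SwitchConfig] = None
) -> LayerLabeling:
    """Lift a 3-class slice sequence to the 5-region labeling.

    Starting in the lower no-tooth region, the state advances to the next
    region at the first slice of a run of at least ``cfg.confirm_run``
    identical labels matching the next region's expected class.  Labels that
    do not match the next expected class are treated as noise and never
    trigger a switch; the region index never decreases.
    """
    cfg = cfg or SwitchConfig()
    labels = [ClassLabel(l) for l in class_labels]
    if not labels:
        raise ValueError("anti_noise_switch needs a nonempty label sequence")

    flipped = cfg.scan_direction is ScanDirection.TOP_TO_BOTTOM
    seq = labels[::-1] if flipped else labels
    layer, _ = _switch_bottom_to_top(seq, cfg.confirm_run)
    if flipped:
        layer = layer[::-1]
    # boundaries expressed in the supplied index order: first slice of each
    # region after the first in LAYER_SEQUENCE, n when the region is empty
    n = len(labels)
    boundaries = []
    for region in LAYER_SEQUENCE[1:]:
        idx = [i for i, l in enumerate(layer) if l == region]
        boundaries.append(idx[0] if idx else n)
    return LayerLabeling(labels, layer, boundaries)


def select_key_slices(labeling: LayerLabeling) -> List[int]:
    """The detection key slices: 10th and 10th-from-last of each crown region.

    For a crown region of length Lr starting at r0 this picks offsets
    ``min(9, Lr-1)`` and ``max(Lr-10, 0)``; short regions clamp into the
    region and deduplicate.  Returns the sorted unique union over the lower
    and upper crown regions.
    """
    keys = set()
    for region in (LayerLabel.LOWER_CROWN, LayerLabel.UPPER_CROWN):
        idx = labeling.region_indices(region)
        if not idx:
            raise ValueError(
                f"empty {region.value} region: no key slices can be selected; "
                "override the region boundaries manually"
            )
        r0, lr = idx[0], len(idx)
        if lr < 20:
            warnings.warn(
                f"{region.value} region has only {lr} slices; key-slice "
                "offsets clamped",
                stacklevel=2,
            )
        keys.add(r0 + min(9, lr - 1))
        keys.add(r0 + max(lr - 10, 0))
    return sorted(keys)


def key_slice_jaws(labeling: LayerLabeling, key_slices: Sequence[int]) -> dict:
    """Map each key slice to the jaw whose crown region it belongs to."""
    from .geometry import Jaw

    out = {}
    for k in key_slices:
        label = labeling.layer_labels[k]
        if label == LayerLabel.LOWER_CROWN:
            out[k] = Jaw.LOWER
        elif label == LayerLabel.UPPER_CROWN:
            out[k] = Jaw.UPPER
        else:
            raise ValueError(f"key slice {k} is not in a crown region ({label.value})")
    return out


def preprocess_stack(slices: np.ndarray, size: int = 128) -> np.ndarray:
    """Classifier preprocessing: per-stack min-max to [0,1], bilinear resize.

    Returns a float array of shape (n, size, size).
    """
    from skimage.transform import resize

    arr = np.asarray(slices, dtype=np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return np.stack(
        [resize(s, (size, size), order=1, anti_aliasing=False) for s in arr]
    )


class AntiNoiseLayerLabeler(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`anti_noise_switch`.

    ``transform`` maps a sequence of :class:`ClassLabel` (or their string
    values) to a :class:`LayerLabeling`.  Stateless; ``fit`` is a no-op.
    """

    def __init__(
        self,
        confirm_run: int = 3,
        scan_direction: str = ScanDirection.BOTTOM_TO_TOP.value,
    ):
        self.confirm_run = confirm_run
        self.scan_direction = scan_direction

    def fit(self, X=None, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[ClassLabel]) -> LayerLabeling:
        cfg = SwitchConfig(self.confirm_run, ScanDirection(self.scan_direction))
        return anti_noise_switch(X, cfg)


class ThresholdSliceClassifier:
    """Reference slice classifier for phantom-like images.

    Measures the tooth-intensity (brightest-tissue) area fraction: a slice
    showing one dentition's crowns carries roughly half the bright area of
    a slice where both dentitions overlap, and a no-tooth slice (bone band
    only) close to none.  Expects stack-normalized [0, 1] input as produced
    by :func:`preprocess_stack`, where enamel sits near the top of the
    range and bone well below ``bright_threshold``.  This intensity
    heuristic stands behind the classifier contract; any model exposing
    ``classify(image, slice_index=None) -> ClassLabel`` plugs in the same
    way.
    """

    def __init__(
        self,
        bright_threshold: float = 0.65,
        crown_fraction: float = 0.02,
        overlap_fraction: float = 0.10,
    ):
        self.bright_threshold = bright_threshold
        self.crown_fraction = crown_fraction
        self.overlap_fraction = overlap_fraction

    def classify(self, image: np.ndarray, slice_index: Optional[int] = None) -> ClassLabel:
        img = np.asarray(image, dtype=np.float64)
        fraction = float((img > self.bright_threshold).mean())
        if fraction >= self.overlap_fraction:
            return ClassLabel.OVERLAP
        if fraction >= self.crown_fraction:
            return ClassLabel.CROWN
        return ClassLabel.NO_TOOTH
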