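"""End-to-end orchestration: classify -> anti-noise switch -> key slices ->
main area -> blocks -> proportion division -> propagation.

Detection only ever runs on the four key slices (the 10th and 10th-from-last
slice of each crown region); every other slice inherits the tooth boxes of
the nearest key slice of its own jaw, which is what makes the procedure fast
on full stacks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

from sklearn.base import BaseEstimator

from .detection import Detector, detect_blocks, detect_main_area
from .division import LambdaTable, divide_block, propagate_boxes
from .geometry import BlockId, Box, Chirality, FdiTooth
from .io import Annotation, AnnotationSource, SliceStack, ZDirection
from .layers import (
    LayerLabeling,
    ScanDirection,
    SwitchConfig,
    anti_noise_switch,
    key_slice_jaws,
    preprocess_stack,
    select_key_slices,
)

__all__ = ["PipelineConfig", "PipelineResult", "StageError", "run_pipeline",
           "TeethDetectionPipeline"]


class StageError(RuntimeError):
    """Failure of one pipeline stage, naming the stage and slice."""

    def __init__(self, stage: str, slice_index: Optional[int], cause: Exception):
        loc = f" (slice {slice_index})" if slice_index is not None else ""
        super().__init__(f"stage '{stage}'{loc}: {cause}")
        self.stage = stage
        self.slice_index = slice_index
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    switch: SwitchConfig = field(default_factory=SwitchConfig)
    score_threshold: float = 0.5
    chirality: Chirality = Chirality.RADIOLOGICAL
    missing: FrozenSet[FdiTooth] = frozenset()
    classifier_input_size: int = 128

    def __post_init__(self) -> None:
        self.chirality = Chirality(self.chirality)
        self.missing = frozenset(self.missing)


@dataclass
class PipelineResult:
    """All intermediate and final artifacts of one pipeline run."""

    labeling: LayerLabeling
    key_slices: List[int]
    main_boxes: Dict[int, Box]
    block_boxes: Dict[int, Dict[BlockId, Tuple[Box, float]]]
    missing_blocks: Dict[int, List[BlockId]]
    key_tooth_boxes: Dict[int, List[Tuple[FdiTooth, Box]]]
    tooth_boxes: Dict[int, List[Tuple[FdiTooth, Box]]]

    def to_annotations(self) -> List[Annotation]:
        return [
            Annotation(i, str(tooth.code), box, AnnotationSource.PREDICTION, 1.0)
            for i, items in sorted(self.tooth_boxes.items())
            for tooth, box in items
        ]

    def to_json_obj(self) -> dict:
        return {
            "labeling": self.labeling.to_json_obj(),
            "key_slices": self.key_slices,
            "main_boxes": {str(i): b.as_tuple() for i, b in self.main_boxes.items()},
            "block_boxes": {
                str(i): {
                    bid.key: [list(box.as_tuple()), score]
                    for bid, (box, score) in blocks.items()
                }
                for i, blocks in self.block_boxes.items()
            },
            "missing_blocks": {
                str(i): [b.key for b in bs] for i, bs in self.missing_blocks.items()
            },
            "tooth_boxes": {
                str(i): [[t.code, list(b.as_tuple())] for t, b in items]
                for i, items in sorted(self.tooth_boxes.items())
            },
        }

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_json_obj(), indent=1))


def run_pipeline(
    stack: SliceStack,
    classifier,
    detector: Detector,
    table: LambdaTable,
    cfg: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full teeth-detection procedure on a slice stack.

    ``classifier`` exposes ``classify(image, slice_index=None) ->
    ClassLabel``; ``detector`` implements the :class:`~toothbox.detection.
    Detector` contract.  Stage failures are re-raised as :class:`StageError`
    naming the stage and slice.
    """
    cfg = cfg or PipelineConfig()
    h, w = stack.image_shape
    switch_cfg = cfg.switch
    if stack.z_direction is ZDirection.TOP_TO_BOTTOM:
        switch_cfg = SwitchConfig(cfg.switch.confirm_run, ScanDirection.TOP_TO_BOTTOM)

    try:
        prepped = preprocess_stack(stack.slices, cfg.classifier_input_size)
    except Exception as e:  # pragma: no cover - defensive
        raise StageError("preprocess", None, e)

    class_labels = []
    for i in range(len(stack)):
        try:
            class_labels.append(classifier.classify(prepped[i], i))
        except Exception as e:
            raise StageError("classify", i, e)

    try:
        labeling = anti_noise_switch(class_labels, switch_cfg)
    except Exception as e:
        raise StageError("anti_noise_switch", None, e)

    try:
        keys = select_key_slices(labeling)
        jaws = key_slice_jaws(labeling, keys)
    except Exception as e:
        raise StageError("select_key_slices", None, e)

    main_boxes: Dict[int, Box] = {}
    block_boxes: Dict[int, Dict[BlockId, Tuple[Box, float]]] = {}
    missing_blocks: Dict[int, List[BlockId]] = {}
    key_tooth_boxes: Dict[int, List[Tuple[FdiTooth, Box]]] = {}
    for k in keys:
        image = stack[k]
        try:
            main = detect_main_area(
                image, detector, cfg.score_threshold, slice_index=k
            )
        except Exception as e:
            raise StageError("detect_main_area", k, e)
        main_boxes[k] = main
        try:
            result = detect_blocks(
                image, main, detector, jaws[k], cfg.score_threshold, slice_index=k
            )
        except Exception as e:
            raise StageError("detect_blocks", k, e)
        block_boxes[k] = result.blocks
        missing_blocks[k] = result.missing
        teeth: List[Tuple[FdiTooth, Box]] = []
        for bid, (bbox, _score) in sorted(
            result.blocks.items(), key=lambda kv: kv[0].key
        ):
            try:
                teeth.extend(
                    divide_block(
                        bbox,
                        bid,
                        table,
                        missing=cfg.missing,
                        chirality=cfg.chirality,
                        image_shape=(h, w),
                    )
                )
            except Exception as e:
                raise StageError("divide_block", k, e)
        key_tooth_boxes[k] = teeth

    try:
        tooth_boxes = propagate_boxes(key_tooth_boxes, labeling)
    except Exception as e:
        raise StageError("propagate_boxes", None, e)

    return PipelineResult(
        labeling=labeling,
        key_slices=keys,
        main_boxes=main_boxes,
        block_boxes=block_boxes,
        missing_blocks=missing_blocks,
        key_tooth_boxes=key_tooth_boxes,
        tooth_boxes=tooth_boxes,
    )


class TeethDetectionPipeline(BaseEstimator):
    """sklearn-style facade over :func:`run_pipeline`.

    Parameters mirror :class:`PipelineConfig`; ``predict(stack)`` returns
    the per-slice tooth boxes and stores all intermediate artifacts as
    fitted attributes (``labeling_``, ``key_slices_``, ``main_boxes_``,
    ``block_boxes_``, ``result_``).
    """

    def __init__(
        self,
        classifier=None,
        detector=None,
        lambda_table: Optional[LambdaTable] = None,
        confirm_run: int = 3,
        score_threshold: float = 0.5,
        chirality: str = Chirality.RADIOLOGICAL.value,
        missing: FrozenSet[FdiTooth] = frozenset(),
    ):
        self.classifier = classifier
        self.detector = detector
        self.lambda_table = lambda_table
        self.confirm_run = confirm_run
        self.score_threshold = score_threshold
        self.chirality = chirality
        self.missing = missing

    def fit(self, X=None, y=None):
        return self

    def predict(self, X: SliceStack) -> Dict[int, List[Tuple[FdiTooth, Box]]]:
        if self.classifier is None or self.detector is None:
            raise ValueError("pipeline needs a classifier and a detector backend")
        from .division import default_lambda_table

        table = self.lambda_table or default_lambda_table()
        cfg = PipelineConfig(
            switch=SwitchConfig(confirm_run=self.confirm_run),
            score_threshold=self.score_threshold,
            chirality=Chirality(self.chirality),
            missing=frozenset(self.missing),
        )
        result = run_pipeline(X, self.classifier, self.detector, table, cfg)
        self.result_ = result
        self.labeling_ = result.labeling
        self.key_slices_ = result.key_slices
        self.main_boxes_ = result.main_boxes
        self.block_boxes_ = result.block_boxes
        return result.tooth_boxes
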