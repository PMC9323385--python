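"""Reading and writing slice stacks and box annotations.

Supported formats: single-frame grayscale DICOM series (one file per axial
slice), Pascal VOC XML in the labelImg dialect, and a JSON annotation schema
``{"slices": [{"index": i, "boxes": [{"label": s, "ltrb": [l,t,r,b],
"score": f|null}]}]}``.

VOC pixel convention: VOC/labelImg stores 1-based inclusive integer corners.
We convert to the internal 0-based continuous half-open convention with
``L = xmin - 1, T = ymin - 1, R = xmax, B = ymax`` so that box widths are
preserved exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
from lxml import etree

from .geometry import Box

__all__ = [
    "ZDirection",
    "SliceStack",
    "AnnotationSource",
    "Annotation",
    "read_dicom_series",
    "read_voc_annotations",
    "write_annotations",
    "read_annotations_json",
]


class ZDirection(str, Enum):
    BOTTOM_TO_TOP = "bottom_to_top"
    TOP_TO_BOTTOM = "top_to_bottom"


@dataclass
class SliceStack:
    """A z-ordered stack of 2-D grayscale axial slices.

    ``slices`` has shape ``(n_slices, H, W)``; ``pixel_spacing`` is the
    in-plane voxel size in mm and ``slice_thickness`` the z step in mm.
    ``z_direction`` records whether index 0 is the caudal (bottom) or
    cranial (top) end of the scan.
    """

    slices: np.ndarray
    pixel_spacing: float = 0.3
    slice_thickness: float = 0.3
    z_direction: ZDirection = ZDirection.BOTTOM_TO_TOP

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ValueError("SliceStack needs >= 1 slice of identical shape")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("spacings must be positive")
        self.z_direction = ZDirection(self.z_direction)

    def __len__(self) -> int:
        return int(self.slices.shape[0])

    @property
    def image_shape(self) -> tuple:
        return self.slices.shape[1:]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.slices[i]


class AnnotationSource(str, Enum):
    GROUND_TRUTH = "ground_truth"
    PREDICTION = "prediction"


@dataclass
class Annotation:
    """One labeled box on one slice.

    ``label`` is an FDI code string ("45"), a block key ("lower_incisors"),
    or "main_area".  ``score`` must be present iff the annotation is a
    prediction.
    """

    slice_index: int
    label: str
    box: Box
    source: AnnotationSource = AnnotationSource.GROUND_TRUTH
    score: Optional[float] = None

    def __post_init__(self) -> None:
        self.source = AnnotationSource(self.source)
        if self.source is AnnotationSource.PREDICTION:
            if self.score is None or not 0.0 <= self.score <= 1.0:
                raise ValueError("prediction annotations need a score in [0, 1]")
        elif self.score is not None:
            raise ValueError("ground-truth annotations must not carry a score")


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def read_dicom_series(directory, z_direction: Optional[ZDirection] = None) -> SliceStack:
    """Read a directory of single-frame grayscale DICOM files as a stack.

    Slices are sorted by z position ascending (ImagePositionPatient[2], then
    SliceLocation); when no position tag is present anywhere, filename order
    is used with a warning.  Mixed image shapes, multi-frame or color files
    are rejected.
    """
    import pydicom

    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in paths:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue  # non-DICOM clutter in the directory
        if not hasattr(ds, "PixelData"):
            continue
        datasets.append((p, ds))
    if not datasets:
        raise ValueError(f"no DICOM image files found in {directory}")

    for p, ds in datasets:
        if int(getattr(ds, "NumberOfFrames", 1)) != 1:
            raise ValueError(f"{p.name}: multi-frame DICOM is not supported")
        if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
            raise ValueError(f"{p.name}: only grayscale DICOM is supported")

    def zpos(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return float(ipp[2])
        loc = getattr(ds, "SliceLocation", None)
        return float(loc) if loc is not None else None

    positions = [zpos(ds) for _, ds in datasets]
    if all(z is not None for z in positions):
        order = np.argsort(positions, kind="stable")
        datasets = [datasets[i] for i in order]
        positions = [positions[i] for i in order]
    else:
        warnings.warn(
            "DICOM series lacks slice position tags; falling back to filename order",
            stacklevel=2,
        )
        positions = None

    arrays = [ds.pixel_array for _, ds in datasets]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"mixed slice shapes in series: {sorted(shapes)}")

    first = datasets[0][1]
    spacing = float(getattr(first, "PixelSpacing", [0.3, 0.3])[0])
    if positions is not None and len(positions) > 1:
        thickness = float(abs(positions[1] - positions[0])) or float(
            getattr(first, "SliceThickness", 0.3)
        )
    else:
        thickness = float(getattr(first, "SliceThickness", 0.3))

    return SliceStack(
        slices=np.stack(arrays),
        pixel_spacing=spacing,
        slice_thickness=thickness,
        z_direction=z_direction or ZDirection.BOTTOM_TO_TOP,
    )


# ---------------------------------------------------------------------------
# Pascal VOC XML (labelImg dialect)
# ---------------------------------------------------------------------------

def read_voc_annotations(
    xml_path,
    slice_index: int = 0,
    source: AnnotationSource = AnnotationSource.GROUND_TRUTH,
) -> List[Annotation]:
    """Parse one labelImg-style Pascal VOC XML file into Annotations.

    VOC stores one XML per image; ``slice_index`` tags the result with its
    position in the stack.
    """
    try:
        tree = etree.parse(str(xml_path))
    except etree.XMLSyntaxError as e:
        raise ValueError(f"malformed VOC XML {xml_path}: {e}") from e
    root = tree.getroot()
    out: List[Annotation] = []
    for obj in root.iter("object"):
        name_el = obj.find("name")
        bb = obj.find("bndbox")
        if name_el is None or bb is None:
            raise ValueError(f"VOC object missing <name> or <bndbox> in {xml_path}")
        vals = {}
        for tag in ("xmin", "ymin", "xmax", "ymax"):
            el = bb.find(tag)
            if el is None or el.text is None:
                raise ValueError(f"VOC <bndbox> missing <{tag}> in {xml_path}")
            vals[tag] = float(el.text)
        if vals["xmax"] < vals["xmin"] or vals["ymax"] < vals["ymin"]:
            raise ValueError(
                f"VOC box with xmax<xmin or ymax<ymin in {xml_path}: {vals}"
            )
        box = Box(vals["xmin"] - 1.0, vals["ymin"] - 1.0, vals["xmax"], vals["ymax"])
        score = None
        score_el = obj.find("score")
        src = source
        if score_el is not None and score_el.text:
            score = float(score_el.text)
            src = AnnotationSource.PREDICTION
        out.append(Annotation(slice_index, name_el.text.strip(), box, src, score))
    return out


def _write_voc(annotations: Sequence[Annotation], path: Path) -> None:
    indices = {a.slice_index for a in annotations}
    if len(indices) > 1:
        raise ValueError("VOC XML holds a single image; annotations span slices")
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = path.stem
    for a in annotations:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = a.label
        bb = etree.SubElement(obj, "bndbox")
        # inverse of the read conversion, rounded to VOC integers
        etree.SubElement(bb, "xmin").text = str(int(round(a.box.L)) + 1)
        etree.SubElement(bb, "ymin").text = str(int(round(a.box.T)) + 1)
        etree.SubElement(bb, "xmax").text = str(int(round(a.box.R)))
        etree.SubElement(bb, "ymax").text = str(int(round(a.box.B)))
        if a.score is not None:
            etree.SubElement(obj, "score").text = repr(a.score)
    path.write_bytes(etree.tostring(root, pretty_print=True))


def _annotations_to_json_obj(annotations: Sequence[Annotation]) -> dict:
    by_slice: Dict[int, list] = {}
    for a in annotations:
        by_slice.setdefault(a.slice_index, []).append(
            {"label": a.label, "ltrb": list(a.box.as_tuple()), "score": a.score}
        )
    return {
        "slices": [
            {"index": i, "boxes": by_slice[i]} for i in sorted(by_slice)
        ]
    }


def write_annotations(annotations: Sequence[Annotation], path, format: str = "json"):
    """Write annotations as VOC XML (integer px) or the JSON schema (exact)."""
    path = Path(path)
    if format == "voc_xml":
        _write_voc(annotations, path)
    elif format == "json":
        path.write_text(json.dumps(_annotations_to_json_obj(annotations), indent=1))
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return path


def read_annotations_json(
    path, source: AnnotationSource = AnnotationSource.GROUND_TRUTH
) -> List[Annotation]:
    obj = json.loads(Path(path).read_text())
    out: List[Annotation] = []
    for sl in obj.get("slices", []):
        for b in sl["boxes"]:
            score = b.get("score")
            src = AnnotationSource.PREDICTION if score is not None else source
            out.append(
                Annotation(int(sl["index"]), b["label"], Box(*b["ltrb"]), src, score)
            )
    return out
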