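"""Spatial mapping and marker/population co-localization.

Two quantitative readings of "the marker localizes to the population's
territory" are provided: a cell-coordinate reading (a marker-positive cell
co-localizes iff a population-annotated cell lies within a given Euclidean
radius) and a pixel reading on rendered spatial maps (RGB thresholding of
the marker image, binary dilation for visibility, and a composite where the
marker is shown on a red gradient over grayscale tissue and the population
in yellow, with the mask intersection counted as overlap).

Rendering constants are fixed for bit-stable output: grayscale uses ITU-R
601 luma weights, the red gradient runs from (80, 0, 0) to (255, 0, 0)
scaled by the marker image's original intensity, and the population is pure
yellow (255, 255, 0).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.morphology import dilation as _sk_dilation
from skimage.morphology import disk, footprint_rectangle

from .synthdata import ExpressionSection

__all__ = [
    "ColocResult",
    "positive_cell_fraction",
    "annotation_overlap",
    "parse_rule",
    "threshold_rgb",
    "dilate",
    "compose",
]

_LUMA = np.array([0.299, 0.587, 0.114])  # ITU-R 601
_RED_LO, _RED_HI = 80, 255
_YELLOW = (255, 255, 0)


@dataclass
class ColocResult:
    """Co-localization bookkeeping for one section or image pair.

    In the pixel reading, overlap is a set intersection and cannot exceed
    either mask.  In the cell-coordinate reading (``cell_based``), overlap
    counts marker-positive cells with an annotated neighbour within the
    radius, so it is bounded by the marker count only (one annotated cell
    can serve many positives).
    """

    marker_pixels: int
    population_pixels: int
    overlap_pixels: int
    overlap_fraction_of_marker: float
    positive_cell_fraction: float | None = None
    cell_based: bool = False

    def __post_init__(self) -> None:
        bound = self.marker_pixels if self.cell_based else min(
            self.marker_pixels, self.population_pixels
        )
        if self.overlap_pixels > bound:
            raise ValueError("overlap cannot exceed its bounding count")


def positive_cell_fraction(
    section: ExpressionSection, gene: str, threshold: float = 0.0
) -> float:
    """Fraction of marker-positive cells among *all* cells of the section.

    A cell is positive when its normalized expression exceeds ``threshold``
    (default: any expression above zero).  The denominator is the full
    section, not an annotation subset.
    """
    expr = section.expression(gene)  # KeyError for unknown genes
    return float((expr > threshold).sum() / section.n_cells)


def annotation_overlap(
    section: ExpressionSection,
    gene: str,
    annotation: str,
    radius: float,
    threshold: float = 0.0,
) -> ColocResult:
    """Cell-coordinate co-localization of a marker with an annotated
    population.

    A marker-positive cell co-localizes iff a cell carrying ``annotation``
    lies within Euclidean distance ``radius`` (a positive cell that is
    itself annotation-labelled co-localizes at any radius >= 0).  Counts are
    reported in the pixel slots of :class:`ColocResult` with cells as the
    unit.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    ann_mask = (section.cells["celltype"] == annotation).to_numpy()
    if not ann_mask.any():
        raise ValueError(f"annotation {annotation!r} absent from section {section.condition!r}")
    expr = section.expression(gene)
    pos_mask = expr > threshold
    n_pos = int(pos_mask.sum())
    xy = section.cells[["x", "y"]].to_numpy()
    if n_pos == 0:
        return ColocResult(0, int(ann_mask.sum()), 0, 0.0, 0.0, cell_based=True)
    tree = cKDTree(xy[ann_mask])
    dist, _ = tree.query(xy[pos_mask], k=1)
    n_coloc = int((dist <= radius).sum())
    return ColocResult(
        marker_pixels=n_pos,
        population_pixels=int(ann_mask.sum()),
        overlap_pixels=n_coloc,
        overlap_fraction_of_marker=n_coloc / n_pos,
        positive_cell_fraction=n_pos / section.n_cells,
        cell_based=True,
    )


# ---------------------------------------------------------------------------
# image operations

_RULE_RE = re.compile(r"^\s*([RGBA])\s*(>=|<=)\s*(\d+)\s*$")
_CHANNEL = {"R": 0, "G": 1, "B": 2, "A": 3}


def parse_rule(rule: str) -> list[tuple[str, str, int]]:
    """Parse a rule string like ``"R>=120,G<=80,B<=80"`` into clauses."""
    clauses = []
    for part in rule.split(","):
        m = _RULE_RE.match(part)
        if not m:
            raise ValueError(f"unparseable rule clause {part!r}")
        clauses.append((m.group(1), m.group(2), int(m.group(3))))
    return clauses


def threshold_rgb(img: np.ndarray, rule: str | list[tuple[str, str, int]]) -> np.ndarray:
    """Boolean mask of pixels satisfying every per-channel inequality.

    ``rule`` is either a string (``"R>=128,G<=50"``) or pre-parsed clauses
    of ``(channel, op, bound)``; the alpha channel is ignored unless the
    rule names it.  Contradictory bounds on one channel are rejected.
    """
    clauses = parse_rule(rule) if isinstance(rule, str) else list(rule)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an RGB(A) image array")
    lower: dict[str, int] = {}
    upper: dict[str, int] = {}
    for ch, op, bound in clauses:
        if op == ">=":
            lower[ch] = max(lower.get(ch, 0), bound)
        else:
            upper[ch] = min(upper.get(ch, 255), bound)
    for ch in set(lower) & set(upper):
        if lower[ch] > upper[ch]:
            raise ValueError(f"contradictory rule for channel {ch}: >= {lower[ch]} and <= {upper[ch]}")
    mask = np.ones(img.shape[:2], dtype=bool)
    for ch, op, bound in clauses:
        idx = _CHANNEL[ch]
        if idx >= img.shape[2]:
            raise ValueError(f"image has no {ch} channel")
        chan = img[..., idx]
        mask &= (chan >= bound) if op == ">=" else (chan <= bound)
    return mask


def dilate(mask: np.ndarray, radius: int, element: str = "disk") -> np.ndarray:
    """Morphological binary dilation with a disk (Euclidean, default) or
    square (Chebyshev) structuring element; radius 0 is the identity."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if radius == 0:
        return mask.copy()
    if element == "disk":
        footprint = disk(radius)
    elif element == "square":
        footprint = footprint_rectangle((2 * radius + 1, 2 * radius + 1))
    else:
        raise ValueError("element must be 'disk' or 'square'")
    return _sk_dilation(mask, footprint)


def compose(
    marker_img: np.ndarray,
    marker_mask: np.ndarray,
    population_mask: np.ndarray,
) -> tuple[np.ndarray, ColocResult]:
    """Composite the marker signal (red gradient over grayscale) with the
    population territory (yellow) and count mask overlap.

    The background is the grayscale of ``marker_img``; marker pixels are
    tinted on a red gradient scaled by their original intensity; population
    pixels are yellow; pixels in both masks count as overlap and keep the
    marker's red encoding drawn over the yellow.  The alpha channel is
    opaque on tissue/mask pixels and transparent elsewhere.
    """
    if marker_mask.shape != marker_img.shape[:2] or population_mask.shape != marker_img.shape[:2]:
        raise ValueError("mask shapes must match the marker image")
    rgb = marker_img[..., :3].astype(float)
    gray = (rgb @ _LUMA).astype(np.uint8)
    out = np.zeros((*gray.shape, 4), dtype=np.uint8)
    out[..., 0] = gray
    out[..., 1] = gray
    out[..., 2] = gray
    tissue = gray > 0
    out[..., 3] = np.where(tissue, 255, 0).astype(np.uint8)

    out[population_mask, 0] = _YELLOW[0]
    out[population_mask, 1] = _YELLOW[1]
    out[population_mask, 2] = _YELLOW[2]
    out[population_mask, 3] = 255

    # red gradient scaled by the original (red-channel) marker intensity
    intensity = marker_img[..., 0].astype(float) / 255.0
    red = (_RED_LO + (_RED_HI - _RED_LO) * intensity).astype(np.uint8)
    out[marker_mask, 0] = red[marker_mask]
    out[marker_mask, 1] = 0
    out[marker_mask, 2] = 0
    out[marker_mask, 3] = 255

    overlap = int((marker_mask & population_mask).sum())
    n_marker = int(marker_mask.sum())
    result = ColocResult(
        marker_pixels=n_marker,
        population_pixels=int(population_mask.sum()),
        overlap_pixels=overlap,
        overlap_fraction_of_marker=overlap / n_marker if n_marker else 0.0,
    )
    return out, result
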