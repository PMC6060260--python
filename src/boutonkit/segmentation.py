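"""Punctum detection and ROI trace extraction.

Boutons are detected on a temporally averaged (and ideally
background-subtracted) image: the image is transformed with the discrete
Laplace operator, and a multiple of the standard deviation of all
Laplacian pixel values serves as the detection threshold. Connected
components of supra-threshold pixels within an area window become
punctum ROIs, each centered at its pixel of maximum average intensity.
Fixed 3x3 ROIs circumscribe single boutons, and neighboring 3x3
background ROIs measure local background fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.ndimage import convolve
from skimage.measure import label, regionprops

from .core import ParameterError, Roi, ShapeError, Trace

__all__ = [
    "SegmentationParams",
    "temporal_average",
    "laplacian_response",
    "detect_puncta",
    "make_fixed_rois",
    "pick_background_rois",
    "extract_traces",
]

# negated 4-neighbour Laplacian: bright blobs -> positive response
_LAPLACE_KERNEL = -np.array([[0, 1, 0],
                             [1, -4, 1],
                             [0, 1, 0]], dtype=float)

_COMPASS = ((-1, 0), (-1, 1), (0, 1), (1, 1),
            (1, 0), (1, -1), (0, -1), (-1, -1))  # N, NE, E, SE, S, SW, W, NW


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold multiple, component-area window and connectivity."""

    k_sd: float = 3.0
    min_area_px: int = 2
    max_area_px: int = 100
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ParameterError("k_sd must be > 0")
        if not 1 <= self.min_area_px <= self.max_area_px:
            raise ParameterError("need 1 <= min_area_px <= max_area_px")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")


def temporal_average(stack: np.ndarray,
                     frame_range: Tuple[int, int] = None) -> np.ndarray:
    """Pixelwise mean over an inclusive frame index interval."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ShapeError("stack must be (T, H, W)")
    if frame_range is None:
        frame_range = (0, stack.shape[0] - 1)
    lo, hi = frame_range
    if not (0 <= lo <= hi < stack.shape[0]):
        raise ParameterError(f"frame range {frame_range} invalid for "
                             f"{stack.shape[0]} frames")
    return stack[lo:hi + 1].mean(axis=0)


def laplacian_response(image: np.ndarray) -> np.ndarray:
    """Negated discrete Laplacian (3x3 cross kernel, reflect boundary)."""
    return convolve(np.asarray(image, dtype=float), _LAPLACE_KERNEL,
                    mode="reflect")


def detect_puncta(avg_image: np.ndarray,
                  params: SegmentationParams = SegmentationParams()
                  ) -> List[Roi]:
    """Detect punctate boutons by Laplacian SD-thresholding.

    Pipeline: negated Laplacian -> threshold at ``k_sd`` x SD of all
    Laplacian pixels -> connected components -> area filter -> one
    punctum ROI per component, centered at the component's brightest
    pixel of ``avg_image`` (row-major first on ties). Output is sorted
    by center coordinates. A constant image (zero SD) yields no ROIs.
    """
    avg_image = np.asarray(avg_image, dtype=float)
    if avg_image.ndim != 2 or min(avg_image.shape) < 5:
        raise ShapeError("image must be 2-D and at least 5x5")
    if not np.all(np.isfinite(avg_image)):
        raise ParameterError("image must be finite")
    lap = laplacian_response(avg_image)
    sd = lap.std()
    if sd == 0:
        return []
    mask = lap > params.k_sd * sd
    labels = label(mask, connectivity=1 if params.connectivity == 4 else 2)
    rois: List[Roi] = []
    for region in regionprops(labels):
        if not params.min_area_px <= region.area <= params.max_area_px:
            continue
        coords = region.coords  # already row-major sorted
        intens = avg_image[coords[:, 0], coords[:, 1]]
        center = tuple(coords[int(np.argmax(intens))])  # first max wins
        rois.append(Roi(id="", pixels=frozenset(map(tuple, coords)),
                        center=center, kind="punctum"))
    rois.sort(key=lambda r: r.center)
    return [Roi(id=f"p{i:03d}", pixels=r.pixels, center=r.center,
                kind="punctum") for i, r in enumerate(rois)]


def _window3x3(center: Tuple[int, int],
               image_shape: Tuple[int, int]) -> frozenset:
    H, W = image_shape
    cr, cc = center
    return frozenset((r, c)
                     for r in range(max(0, cr - 1), min(H, cr + 2))
                     for c in range(max(0, cc - 1), min(W, cc + 2)))


def make_fixed_rois(centers: Sequence[Tuple[int, int]],
                    image_shape: Tuple[int, int]) -> List[Roi]:
    """3x3 ROIs just circumscribing single boutons, cropped at borders."""
    H, W = image_shape
    rois = []
    for i, (cr, cc) in enumerate(centers):
        if not (0 <= cr < H and 0 <= cc < W):
            raise ParameterError(f"center ({cr}, {cc}) outside image")
        rois.append(Roi(id=f"f{i:03d}",
                        pixels=_window3x3((cr, cc), image_shape),
                        center=(cr, cc), kind="fixed3x3"))
    return rois


def pick_background_rois(puncta: Sequence[Roi],
                         image_shape: Tuple[int, int],
                         offset_px: int = 5,
                         seed: int = 0
                         ) -> Tuple[List[Roi], List[str]]:
    """One neighboring 3x3 background ROI per punctum.

    Candidate centers sit at ``offset_px`` from the punctum center in
    the 8 compass directions; the direction order is shuffled per
    punctum by the seed and the first candidate whose 3x3 window lies
    fully in-image and overlaps no punctum ROI wins. Puncta with no
    valid direction are skipped and their ids returned.
    """
    if offset_px < 3:
        raise ParameterError("offset_px must be >= 3")
    H, W = image_shape
    occupied = set()
    for roi in puncta:
        occupied |= roi.pixels
    rng = np.random.default_rng(seed)
    rois: List[Roi] = []
    skipped: List[str] = []
    for roi in puncta:
        cr, cc = roi.center
        directions = list(_COMPASS)
        rng.shuffle(directions)
        placed = False
        for dr, dc in directions:
            br, bc = cr + dr * offset_px, cc + dc * offset_px
            if not (1 <= br < H - 1 and 1 <= bc < W - 1):
                continue
            window = _window3x3((br, bc), image_shape)
            if window & occupied:
                continue
            rois.append(Roi(id=f"bg_{roi.id}", pixels=window,
                            center=(br, bc), kind="background"))
            placed = True
            break
        if not placed:
            skipped.append(roi.id)
    return rois, skipped


def extract_traces(stack: np.ndarray, rois: Sequence[Roi],
                   frame_interval_s: float = 1.0) -> List[Trace]:
    """Mean ROI intensity per frame, one raw trace per ROI (input order)."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ShapeError("stack must be (T, H, W)")
    T, H, W = stack.shape
    times = np.arange(T) * frame_interval_s
    traces = []
    for roi in rois:
        rows, cols = roi.rows_cols()
        if rows.max() >= H or cols.max() >= W or rows.min() < 0 or cols.min() < 0:
            raise ShapeError(f"ROI {roi.id} outside frame geometry")
        traces.append(Trace(times_s=times,
                            values=stack[:, rows, cols].mean(axis=1),
                            stage="raw", roi_id=roi.id))
    return traces
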