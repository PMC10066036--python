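"""Cell segmentation and single-cell geometry from phase-contrast images.

Produces integer label masks from phase contrast (cells darker than the
background) by classical thresholding, or ingests externally produced masks
(e.g. from a learned segmenter), and reduces each labelled cell to a
:class:`CellOutline`: a sub-pixel closed boundary polyline, a pole-to-pole
midline, and the derived circumference, length and width.

The boundary comes from marching squares on the binary cell at level 0.5;
the midline is the skeleton pruned to its longest path, extended to the two
pole points on the boundary.  Width is the median midline-perpendicular
extent (twice the Euclidean distance transform along the midline), excluding
the rounded cap regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation as sk_seg

from .geometry import polyline_length

__all__ = [
    "CellOutline",
    "segment_phase",
    "extract_outline",
    "cell_length",
    "read_label_mask",
    "write_label_mask",
]


@dataclass
class CellOutline:
    """Geometry of one segmented cell.

    ``boundary`` and ``midline`` are polylines in continuous ``(x=col,
    y=row)`` pixel coordinates; the boundary is closed (first point repeated
    last).  ``length`` and ``width`` are in micrometres when ``pixel_size``
    (um/px) is known, else in pixels.
    """

    cell_id: int
    boundary: np.ndarray          # (N, 2) closed polyline
    midline: np.ndarray           # (M, 2) pole-to-pole polyline
    circumference_px: float
    length_px: float
    width_px: float
    centroid: tuple[float, float]
    pole_points: np.ndarray       # (2, 2) boundary coords
    pixel_size: float | None = None

    @property
    def circumference(self) -> float:
        return self._scaled(self.circumference_px)

    @property
    def length(self) -> float:
        return self._scaled(self.length_px)

    @property
    def width(self) -> float:
        return self._scaled(self.width_px)

    def _scaled(self, v: float) -> float:
        return v * self.pixel_size if self.pixel_size is not None else v


def _smooth_closed(poly: np.ndarray, window: int = 9) -> np.ndarray:
    """Circular moving average of a closed polyline (deduplicated, re-closed).

    Removes the staircase jaggedness of marching-squares contours, whose raw
    length overestimates a smooth perimeter by several percent.
    """
    pts = poly[:-1]
    n = len(pts)
    if n < window:
        return poly
    kernel = np.ones(window) / window
    pad = window // 2
    ext = np.vstack([pts[-pad:], pts, pts[:pad]])
    sm = np.column_stack([np.convolve(ext[:, 0], kernel, mode="valid"),
                          np.convolve(ext[:, 1], kernel, mode="valid")])
    return np.vstack([sm, sm[:1]])


def _smooth_open(path: np.ndarray, window: int = 7) -> np.ndarray:
    """Edge-padded moving average of an open polyline (skeleton de-zigzag)."""
    n = len(path)
    if n < 3:
        return path.astype(float)
    window = min(window, n if n % 2 else n - 1)
    kernel = np.ones(window) / window
    pad = window // 2
    ext = np.vstack([np.repeat(path[:1], pad, axis=0), path,
                     np.repeat(path[-1:], pad, axis=0)]).astype(float)
    return np.column_stack([np.convolve(ext[:, 0], kernel, mode="valid"),
                            np.convolve(ext[:, 1], kernel, mode="valid")])


def segment_phase(phase_image: np.ndarray, smooth_sigma: float = 1.0,
                  min_area: int = 50, split_touching: bool = False) -> np.ndarray:
    """Label mask from a phase-contrast image (cells darker than background).

    Pipeline: Gaussian smooth, Otsu threshold on the inverted image, hole
    fill, area filter, and optionally a distance-transform watershed to split
    touching cells.  Returns an empty (all-zero) mask when no foreground is
    found.
    """
    img = np.asarray(phase_image, float)
    if img.ndim != 2:
        raise ValueError("phase image must be 2-D")
    sm = ndi.gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 else img
    inv = sm.max() - sm
    if inv.max() <= inv.min():
        return np.zeros(img.shape, dtype=np.int32)
    thr = filters.threshold_otsu(inv)
    fg = inv > thr
    # Otsu on a (near-)uniform image can mark half the field; reject such fits
    if fg.mean() > 0.9:
        return np.zeros(img.shape, dtype=np.int32)
    fg = ndi.binary_fill_holes(fg)
    if split_touching:
        dist = ndi.distance_transform_edt(fg)
        coords = morphology.local_maxima(ndi.gaussian_filter(dist, 1.0))
        markers, _ = ndi.label(coords & fg)
        lab = sk_seg.watershed(-dist, markers, mask=fg)
    else:
        lab, _ = ndi.label(fg)
    # area filter with sequential relabelling
    ids, counts = np.unique(lab[lab > 0], return_counts=True)
    keep = ids[counts >= min_area]
    out = np.zeros(img.shape, dtype=np.int32)
    for new_id, old_id in enumerate(keep, start=1):
        out[lab == old_id] = new_id
    return out


def _longest_skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Ordered (row, col) pixels of the longest path through a skeleton.

    Two passes of BFS (graph diameter heuristic on trees) over 8-connected
    skeleton pixels.
    """
    pix = np.argwhere(skel)
    if len(pix) == 0:
        return pix
    index = {tuple(p): i for i, p in enumerate(pix)}
    nbrs: list[list[int]] = [[] for _ in pix]
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for i, (r, c) in enumerate(pix):
        for dr, dc in offs:
            j = index.get((r + dr, c + dc))
            if j is not None:
                nbrs[i].append(j)

    def bfs(src: int):
        dist = np.full(len(pix), -1)
        parent = np.full(len(pix), -1)
        dist[src] = 0
        queue = [src]
        for u in queue:
            for v in nbrs[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    parent[v] = u
                    queue.append(v)
        far = int(np.argmax(dist))
        return far, parent

    a, _ = bfs(0)
    b, parent = bfs(a)
    path = [b]
    while parent[path[-1]] >= 0:
        path.append(int(parent[path[-1]]))
    return pix[path[::-1]]


def extract_outline(mask: np.ndarray, cell_id: int,
                    pixel_size: float | None = None) -> CellOutline:
    """Sub-pixel outline, midline and size metrics for one labelled cell."""
    binary = np.asarray(mask) == cell_id
    if not binary.any():
        raise ValueError(f"cell_id {cell_id} not present in mask")
    if binary.sum() < 3:
        raise ValueError(f"cell_id {cell_id} region is degenerate")
    contours = measure.find_contours(binary.astype(float), 0.5)
    contour = max(contours, key=len)          # (row, col)
    boundary = contour[:, ::-1].copy()        # -> (x, y)
    if not np.allclose(boundary[0], boundary[-1]):
        boundary = np.vstack([boundary, boundary[:1]])
    boundary = _smooth_closed(boundary)
    circumference = polyline_length(boundary)

    skel = morphology.skeletonize(binary)
    path = _longest_skeleton_path(skel)       # (row, col)
    rows, cols = np.nonzero(binary)
    centroid = (float(cols.mean()), float(rows.mean()))

    if len(path) >= 2:
        midline = _smooth_open(path[:, ::-1].astype(float))   # (x, y)
        # outward tangents at the two midline ends (averaged over a few px)
        k = min(5, len(midline) - 1)
        t0 = midline[0] - midline[k]
        t1 = midline[-1] - midline[-1 - k]
        poles = []
        for end, tang in ((midline[0], t0), (midline[-1], t1)):
            tang = tang / (np.hypot(*tang) + 1e-12)
            proj = (boundary[:-1] - end) @ tang
            poles.append(boundary[:-1][int(np.argmax(proj))])
        pole_points = np.array(poles)
        length_px = (polyline_length(midline)
                     + np.hypot(*(pole_points[0] - midline[0]))
                     + np.hypot(*(pole_points[1] - midline[-1])))
    else:
        # near-round region: midline degenerates to the centroid; length is
        # the boundary diameter
        pts = boundary[:-1]
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmax(d2), d2.shape)
        pole_points = np.array([pts[i], pts[j]])
        midline = np.array([np.asarray(centroid, float)])
        length_px = float(np.sqrt(d2[i, j]))

    edt = ndi.distance_transform_edt(binary)
    if len(path) >= 2:
        widths = 2.0 * edt[path[:, 0], path[:, 1]]
        w_est = float(np.median(widths))
        # drop midline points within half a width of either end (cap regions)
        seg = np.hypot(*np.diff(midline, axis=0).T)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        interior = (cum > w_est / 2) & (cum < cum[-1] - w_est / 2)
        width_px = float(np.median(widths[interior])) if interior.any() else w_est
    else:
        width_px = float(2.0 * edt.max())
    width_px = min(width_px, length_px)

    return CellOutline(cell_id=int(cell_id), boundary=boundary, midline=midline,
                       circumference_px=float(circumference),
                       length_px=float(length_px), width_px=width_px,
                       centroid=centroid, pole_points=pole_points,
                       pixel_size=pixel_size)


def cell_length(outline: CellOutline) -> float:
    """Pole-to-pole cell length in micrometres.

    Arclength of the midline plus the two cap extensions to the pole points.
    Requires ``pixel_size`` on the outline.
    """
    if outline.pixel_size is None:
        raise ValueError("outline has no pixel_size; cannot report micrometres")
    return outline.length_px * outline.pixel_size


def read_label_mask(path) -> np.ndarray:
    """Read an externally produced integer label mask from TIFF."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError("label mask must be a single 2-D image")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("label mask must contain integer labels")
        arr = np.round(arr)
    return arr.astype(np.int32)


def write_label_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask).astype(np.int32))
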