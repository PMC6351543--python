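"""Polygon export of segmented tumor regions for computer-aided annotation.

The dense heatmap is binarized at 0.5 and each 8-connected tumor
component is traced into one closed external polygon (holes are not
exported) by Moore boundary following through pixel centers, the
classic contour-retrieval behavior: the polygon's vertices are the
ordered boundary pixel coordinates, so a 3x3 component whose pixels
span columns/rows 1..3 yields a contour with bounding box (1,1)-(3,3)
at mask scale. Vertices are scaled by the mask's level scale (x8 for
the dense heatmap) into level-0 pixel units and written as
ASAP-compatible XML so pathologists can inspect and edit them in the
ASAP slide viewer.
"""

from __future__ import annotations

import os

import numpy as np
from lxml import etree
from skimage.measure import label as cc_label

from .pyramid_io import Heatmap, MaskRaster

__all__ = [
    "binarize",
    "trace_boundary",
    "extract_polygons",
    "write_asap_xml",
    "read_asap_xml",
]

DEFAULT_MIN_AREA = 4  # heatmap pixels; suppresses single-pixel noise

# Moore neighborhood in clockwise order starting from west, as
# (dx, dy) offsets; image y grows downward.
_MOORE = [(-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1)]


def binarize(hm: Heatmap, thr: float = 0.5) -> MaskRaster:
    """Binary tumor mask from a heatmap: 1 where p > thr (strict)."""
    if not 0.0 <= thr <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return MaskRaster(data=(hm.data > thr).astype(np.uint8), level_scale=hm.level_scale)


def trace_boundary(component: np.ndarray) -> list[tuple[int, int]]:
    """Outer boundary of a single 8-connected component, as ordered
    (x, y) pixel-center coordinates.

    Moore boundary following, clockwise, starting at the topmost-then-
    leftmost pixel (whose west neighbor is background by construction).
    The walk stops when a pixel-to-pixel transition repeats, which
    closes the cycle exactly even for pinched components whose
    boundary revisits a pixel.
    """
    ys, xs = np.nonzero(component)
    if len(ys) == 0:
        return []
    i = np.lexsort((xs, ys))[0]
    start = (int(xs[i]), int(ys[i]))
    h, w = component.shape

    def filled(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and bool(component[y, x])

    contour = [start]
    cur = start
    back = 0  # scan starts after the known-background west neighbor
    seen: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    while True:
        nxt = None
        for step in range(1, 9):
            k = (back + step) % 8
            nb = (cur[0] + _MOORE[k][0], cur[1] + _MOORE[k][1])
            if filled(*nb):
                nxt = nb
                # next scan resumes after the last background neighbor
                # checked, re-expressed relative to the new pixel
                prev_bg = (cur[0] + _MOORE[(k - 1) % 8][0], cur[1] + _MOORE[(k - 1) % 8][1])
                back = _MOORE.index((prev_bg[0] - nb[0], prev_bg[1] - nb[1]))
                break
        if nxt is None:
            break  # isolated pixel
        move = (cur, nxt)
        if move in seen:
            break
        seen.add(move)
        contour.append(nxt)
        cur = nxt
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return contour


def extract_polygons(
    mask: MaskRaster,
    min_area: int = DEFAULT_MIN_AREA,
) -> list[np.ndarray]:
    """External polygons of all mask components, in level-0 coordinates.

    Components are 8-connected; those smaller than ``min_area`` mask
    pixels are dropped. Each polygon is a closed (first != last;
    implicit closure) float array of (x, y) vertices, at least 3 of
    them, scaled by the mask's level scale into level-0 pixel units.
    Holes are ignored: only the outer contour is traced.
    """
    labels, n = cc_label(mask.data > 0, connectivity=2, return_num=True)
    polys: list[np.ndarray] = []
    scale = float(mask.level_scale)
    for k in range(1, n + 1):
        comp = labels == k
        if np.count_nonzero(comp) < min_area:
            continue
        contour = trace_boundary(comp)
        if len(contour) < 3:
            # pad degenerate (line/point) contours by repeating vertices
            while len(contour) < 3 and contour:
                contour.append(contour[-1])
        if not contour:
            continue
        polys.append(np.asarray(contour, dtype=np.float64) * scale)
    return polys


# ---------------------------------------------------------------------------
# ASAP XML
# ---------------------------------------------------------------------------

def write_asap_xml(polygons: list[np.ndarray], path: str | os.PathLike) -> None:
    """Write polygons as ASAP annotation XML (level-0 pixel units)."""
    root = etree.Element("ASAP_Annotations")
    anns = etree.SubElement(root, "Annotations")
    for i, poly in enumerate(polygons):
        ann = etree.SubElement(
            anns,
            "Annotation",
            Name=f"Annotation {i}",
            Type="Polygon",
            PartOfGroup="None",
            Color="#F4FA58",
        )
        coords = etree.SubElement(ann, "Coordinates")
        for order, (x, y) in enumerate(np.asarray(poly, dtype=np.float64)):
            etree.SubElement(
                coords,
                "Coordinate",
                Order=str(order),
                X=repr(float(x)),
                Y=repr(float(y)),
            )
    etree.SubElement(root, "AnnotationGroups")
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )


def read_asap_xml(path: str | os.PathLike) -> list[np.ndarray]:
    """Read ASAP polygon annotations back as (x, y) vertex arrays."""
    tree = etree.parse(str(path))
    polys = []
    for ann in tree.findall(".//Annotation"):
        if ann.get("Type") != "Polygon":
            continue
        coords = sorted(
            ann.findall(".//Coordinate"), key=lambda c: int(c.get("Order"))
        )
        polys.append(
            np.asarray(
                [(float(c.get("X")), float(c.get("Y"))) for c in coords],
                dtype=np.float64,
            )
        )
    return polys
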