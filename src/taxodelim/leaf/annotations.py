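"""Leaf contour/midvein annotations and CVAT image-XML IO.

A leaf is a closed simple polygon (the silhouette contour) plus an open
polyline (the midvein) running base to tip, both in pixel coordinates
with the y axis pointing down, as produced by manual annotation of
digitized herbarium specimens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lxml import etree
from shapely.geometry import LineString, Point, Polygon


@dataclass
class LeafAnnotation:
    """Contour polygon + midvein polyline of one leaf."""

    contour: np.ndarray  # (n, 2) closed ring, last vertex != first
    midvein: np.ndarray  # (m, 2) open polyline, base -> tip
    specimen_id: str = ""
    taxon: str = ""

    def __post_init__(self) -> None:
        self.contour = np.asarray(self.contour, dtype=float)
        self.midvein = np.asarray(self.midvein, dtype=float)
        if self.contour.ndim != 2 or self.contour.shape[1] != 2:
            raise ValueError("contour must be (n, 2)")
        if self.midvein.ndim != 2 or self.midvein.shape[1] != 2:
            raise ValueError("midvein must be (m, 2)")
        if len(self.midvein) < 2:
            raise ValueError("midvein needs at least two vertices")

    def polygon(self) -> Polygon:
        return Polygon(self.contour)

    def validate(self, strict: bool = True) -> None:
        poly = self.polygon()
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(
                f"leaf {self.specimen_id!r}: contour is self-intersecting or "
                "degenerate"
            )
        if strict:
            buffered = poly.buffer(1e-6 * np.sqrt(poly.area))
            if not buffered.contains(LineString(self.midvein)):
                raise ValueError(
                    f"leaf {self.specimen_id!r}: midvein leaves the contour"
                )

    def midvein_arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.midvein, axis=0), axis=1).sum())


def _local_width(poly: Polygon, point: np.ndarray, direction: np.ndarray) -> float:
    """Length of the contour chord through ``point`` perpendicular to
    ``direction`` (used to find the basal, i.e. wider, end of a midvein)."""
    d = direction / (np.linalg.norm(direction) + 1e-12)
    normal = np.array([-d[1], d[0]])
    span = 4.0 * np.sqrt(poly.area) + poly.length
    probe = LineString([point - span * normal, point + span * normal])
    cut = probe.intersection(poly)
    if cut.is_empty:
        return 0.0
    if cut.geom_type == "LineString":
        return float(cut.length)
    # take the piece containing the probe point
    pieces = getattr(cut, "geoms", [cut])
    pt = Point(point)
    best = min(pieces, key=lambda g: g.distance(pt))
    return float(best.length)


def orient_midvein(contour: np.ndarray, midvein: np.ndarray) -> np.ndarray:
    """Return the midvein ordered base -> tip.

    The basal end is the endpoint with the greater local contour width
    (leaves taper toward the tip).
    """
    poly = Polygon(contour)
    t0 = midvein[1] - midvein[0]
    t1 = midvein[-1] - midvein[-2]
    w_first = _local_width(poly, midvein[0], t0)
    w_last = _local_width(poly, midvein[-1], t1)
    return midvein if w_first >= w_last else midvein[::-1]


# ---------------------------------------------------------------------------
# CVAT image XML


def write_cvat(leaves: list[LeafAnnotation], path, image_size=(2000, 3000)) -> None:
    """Write annotations in the CVAT image-XML dialect.

    One ``<image>`` per leaf with a polygon (label ``leaf``) and a
    polyline (label ``midvein``).
    """
    root = etree.Element("annotations")
    etree.SubElement(root, "version").text = "1.1"
    for i, leaf in enumerate(leaves):
        img = etree.SubElement(
            root,
            "image",
            id=str(i),
            name=leaf.specimen_id or f"leaf_{i}.jpg",
            width=str(image_size[0]),
            height=str(image_size[1]),
        )
        etree.SubElement(
            img,
            "polygon",
            label="leaf",
            points=_fmt_points(leaf.contour),
            occluded="0",
        ).set("z_order", "0")
        etree.SubElement(
            img,
            "polyline",
            label="midvein",
            points=_fmt_points(leaf.midvein),
            occluded="0",
        ).set("z_order", "0")
        if leaf.taxon:
            attr = etree.SubElement(img[-2], "attribute", name="taxon")
            attr.text = leaf.taxon
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )


def _fmt_points(arr: np.ndarray) -> str:
    return ";".join(f"{x:.2f},{y:.2f}" for x, y in arr)


def _parse_points(text: str) -> np.ndarray:
    return np.array(
        [[float(v) for v in pair.split(",")] for pair in text.split(";")]
    )


def read_cvat(path) -> list[LeafAnnotation]:
    """Read CVAT image XML, pairing polygons with polylines per image.

    Pairing is by spatial containment: each polyline is matched to the
    polygon of the same image that contains (most of) it.  Unpaired
    shapes and self-intersecting polygons raise with the offending image
    named.  Midveins are re-oriented base -> tip.
    """
    tree = etree.parse(str(path))
    leaves: list[LeafAnnotation] = []
    for img in tree.getroot().iter("image"):
        name = img.get("name", "?")
        polygons, polylines, taxa = [], [], []
        for shape in img:
            if shape.tag == "polygon":
                pts = _parse_points(shape.get("points"))
                if not Polygon(pts).is_valid:
                    raise ValueError(
                        f"image {name!r}: polygon {shape.get('label')!r} "
                        "self-intersects"
                    )
                polygons.append(pts)
                taxon = ""
                for attr in shape.iter("attribute"):
                    if attr.get("name") == "taxon":
                        taxon = attr.text or ""
                taxa.append(taxon)
            elif shape.tag == "polyline":
                polylines.append(_parse_points(shape.get("points")))
        if len(polygons) != len(polylines):
            raise ValueError(
                f"image {name!r}: {len(polygons)} polygon(s) but "
                f"{len(polylines)} polyline(s); shapes must pair up"
            )
        used = [False] * len(polylines)
        for poly_pts, taxon in zip(polygons, taxa):
            poly = Polygon(poly_pts).buffer(1e-6)
            match = None
            for j, line in enumerate(polylines):
                if used[j]:
                    continue
                inside = np.mean([poly.contains(Point(p)) for p in line])
                if inside > 0.5:
                    match = j
                    break
            if match is None:
                raise ValueError(
                    f"image {name!r}: polygon has no contained polyline"
                )
            used[match] = True
            midvein = orient_midvein(poly_pts, polylines[match])
            leaves.append(
                LeafAnnotation(poly_pts, midvein, specimen_id=name, taxon=taxon)
            )
    return leaves
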