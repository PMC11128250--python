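"""Rasterized 2D target geometries and peripheral rind regions.

Targets are the in-silico planning shapes: circles of 3/5/8 cm diameter and
two kidney-bean crescents (a concave archetype from treatment-planning QA
practice).  A rind is the annular normal-tissue region of fixed width (10 or
30 mm) surrounding a target, used to quantify the sparing achieved by
collimation.  Masks live on a node-centered grid at 0.5 mm analysis
resolution by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "TargetGeometry",
    "RindRegion",
    "SHAPE_LABELS",
    "make_circle_target",
    "make_kidney_bean_target",
    "make_target",
    "make_rind",
    "mask_to_pgm",
    "mask_to_rle",
    "mask_from_rle",
]

SHAPE_LABELS = ("circle3", "circle5", "circle8", "kidney_small", "kidney_large")

# Kidney-bean parameterization (mm): outer ellipse semi-axes minus an inner
# ellipse displaced along the minor axis, giving a concave crescent; the
# small variant is the large one scaled by 0.4.
_KIDNEY_OUTER = (45.0, 25.0)
_KIDNEY_INNER = (40.0, 22.0)
_KIDNEY_INNER_SHIFT = 15.0
_KIDNEY_SMALL_SCALE = 0.4


@dataclass
class TargetGeometry:
    """Boolean target mask on a node-centered 2D lattice.

    ``mask`` is indexed [iy, ix]; ``origin`` is the (x, y) coordinate of
    node [0, 0] in mm; ``spacing`` is isotropic.
    """

    mask: np.ndarray
    spacing: float
    origin: tuple[float, float]
    shape_label: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("target mask must be a nonempty 2D boolean grid")
        border = np.concatenate(
            [self.mask[0], self.mask[-1], self.mask[:, 0], self.mask[:, -1]]
        )
        if border.any():
            raise ValueError("target mask touches the grid boundary; enlarge the grid")

    @property
    def area(self) -> float:
        """Target area in mm² (spacing² per true node)."""
        return float(self.mask.sum()) * self.spacing**2

    @property
    def x_coords(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.mask.shape[1]) * self.spacing

    @property
    def y_coords(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.mask.shape[0]) * self.spacing

    def centroid(self) -> tuple[float, float]:
        iy, ix = np.nonzero(self.mask)
        return (
            float(self.origin[0] + ix.mean() * self.spacing),
            float(self.origin[1] + iy.mean() * self.spacing),
        )

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of true nodes, mm."""
        iy, ix = np.nonzero(self.mask)
        x, y = self.x_coords, self.y_coords
        return float(x[ix.min()]), float(x[ix.max()]), float(y[iy.min()]), float(y[iy.max()])


@dataclass
class RindRegion:
    """Annular region of given width (mm) surrounding a parent target."""

    mask: np.ndarray
    width: float
    parent: TargetGeometry

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if (self.mask & self.parent.mask).any():
            raise ValueError("rind mask overlaps its parent target")

    @property
    def area(self) -> float:
        return float(self.mask.sum()) * self.parent.spacing**2


def _symmetric_grid(half_x: float, half_y: float, spacing: float):
    """Node-centered coordinates symmetric about (0, 0)."""
    nx = 2 * int(np.ceil(half_x / spacing)) + 1
    ny = 2 * int(np.ceil(half_y / spacing)) + 1
    x = (np.arange(nx) - (nx - 1) / 2) * spacing
    y = (np.arange(ny) - (ny - 1) / 2) * spacing
    return x, y


def make_circle_target(
    diameter: float, spacing: float = 0.5, padding: float = 40.0
) -> TargetGeometry:
    """Circular target: a node is included iff its center lies within
    diameter/2 of the target center."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    r = diameter / 2.0
    x, y = _symmetric_grid(r + padding, r + padding, spacing)
    xx, yy = np.meshgrid(x, y)
    mask = xx**2 + yy**2 <= r**2
    label = {30.0: "circle3", 50.0: "circle5", 80.0: "circle8"}.get(
        float(diameter), f"circle_d{diameter:g}"
    )
    return TargetGeometry(mask=mask, spacing=spacing, origin=(x[0], y[0]), shape_label=label)


def make_kidney_bean_target(
    size: str, spacing: float = 0.5, padding: float = 40.0
) -> TargetGeometry:
    """Kidney-bean (concave crescent) target, as an outer ellipse minus an
    inner ellipse displaced along the minor axis."""
    if size not in ("small", "large"):
        raise ValueError("size must be 'small' or 'large'")
    scale = 1.0 if size == "large" else _KIDNEY_SMALL_SCALE
    ao, bo = (scale * v for v in _KIDNEY_OUTER)
    ai, bi = (scale * v for v in _KIDNEY_INNER)
    dy = scale * _KIDNEY_INNER_SHIFT
    x, y = _symmetric_grid(ao + padding, bo + padding, spacing)
    xx, yy = np.meshgrid(x, y)
    outer = (xx / ao) ** 2 + (yy / bo) ** 2 <= 1.0
    inner = (xx / ai) ** 2 + ((yy - dy) / bi) ** 2 <= 1.0
    mask = outer & ~inner
    return TargetGeometry(
        mask=mask, spacing=spacing, origin=(x[0], y[0]), shape_label=f"kidney_{size}"
    )


def make_target(shape_label: str, spacing: float = 0.5, padding: float = 40.0) -> TargetGeometry:
    """Build any of the named study shapes."""
    if shape_label == "circle3":
        return make_circle_target(30.0, spacing, padding)
    if shape_label == "circle5":
        return make_circle_target(50.0, spacing, padding)
    if shape_label == "circle8":
        return make_circle_target(80.0, spacing, padding)
    if shape_label == "kidney_small":
        return make_kidney_bean_target("small", spacing, padding)
    if shape_label == "kidney_large":
        return make_kidney_bean_target("large", spacing, padding)
    raise ValueError(f"unknown shape label {shape_label!r}; valid: {SHAPE_LABELS}")


def make_rind(target: TargetGeometry, width: float) -> RindRegion:
    """Peripheral rind: Euclidean dilation of the target by ``width`` minus
    the target itself.

    Raises if the dilated region reaches the grid boundary (the rind would
    be clipped); regenerate the target with a larger padding in that case.
    """
    if width <= 0:
        raise ValueError("rind width must be positive")
    dist = ndimage.distance_transform_edt(~target.mask, sampling=target.spacing)
    rind = (dist > 0) & (dist <= width)
    border = np.concatenate([rind[0], rind[-1], rind[:, 0], rind[:, -1]])
    if border.any():
        raise ValueError(
            f"a {width} mm rind reaches the grid boundary; rebuild the target "
            f"with padding > {width} mm"
        )
    return RindRegion(mask=rind, width=width, parent=target)


# --------------------------------------------------------------------------
# plain-text / image export


def mask_to_pgm(mask: np.ndarray, path) -> None:
    """Write a boolean mask as a plain-ASCII PGM (P2) grayscale image."""
    mask = np.asarray(mask, dtype=bool)
    ny, nx = mask.shape
    with open(path, "w") as f:
        f.write(f"P2\n{nx} {ny}\n255\n")
        for row in mask:
            f.write(" ".join("255" if v else "0" for v in row) + "\n")


def mask_to_rle(mask: np.ndarray) -> str:
    """Row-major run-length encoding: 'ny nx' header then alternating run
    lengths starting with the False run."""
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel()
    runs: list[int] = []
    current, count = False, 0
    for v in flat:
        if v == current:
            count += 1
        else:
            runs.append(count)
            current, count = v, 1
    runs.append(count)
    return f"{mask.shape[0]} {mask.shape[1]} " + " ".join(map(str, runs))


def mask_from_rle(text: str) -> np.ndarray:
    parts = text.split()
    ny, nx = int(parts[0]), int(parts[1])
    runs = list(map(int, parts[2:]))
    flat = np.zeros(ny * nx, dtype=bool)
    pos, value = 0, False
    for run in runs:
        flat[pos : pos + run] = value
        pos += run
        value = not value
    if pos != ny * nx:
        raise ValueError("run-length data does not match the stated shape")
    return flat.reshape(ny, nx)
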