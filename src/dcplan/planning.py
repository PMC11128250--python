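"""Spot placement, dose-ratio beamlet selection and collimation assignment.

The planning chain places a rectangular spot lattice over the target, scores
every candidate beamlet with the conformity dose ratio

    DR = 100% * Din / Dout,

the integrated beamlet dose inside over outside the target, keeps spots with
DR at or above a selection threshold (DRthresh), and then assigns trimmer
collimation to edge spots according to a collimation-level threshold Tcoll:
a kept spot whose open-field DR falls below Tcoll receives the library
configuration that maximizes its DR.  Physical trimmer coordinates follow
from the spot position, the configured offsets and a 1 mm minimum offset
from the beamlet axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .beamlets import (
    BeamletKernel,
    BeamSpec,
    KernelLibrary,
    OPEN_CONFIG,
    TrimmerConfig,
)
from .targets import TargetGeometry

__all__ = [
    "SpotMap",
    "CandidateSpot",
    "Plan",
    "MIN_TRIMMER_OFFSET",
    "place_spots",
    "dose_ratio",
    "select_spots",
    "assign_collimation",
    "trimmer_positions_for_spot",
    "KernelSampler",
    "plan_to_table",
    "plan_from_table",
]

MIN_TRIMMER_OFFSET = 1.0  # mm, delivery-robustness floor on engaged offsets


@dataclass
class SpotMap:
    """Rectangular lattice of candidate spot positions (mm)."""

    positions: np.ndarray  # (n, 2) of (x, y)
    spacing: float
    energy: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if len(np.unique(self.positions, axis=0)) != len(self.positions):
            raise ValueError("spot positions must be unique")


@dataclass
class CandidateSpot:
    """One selected spot with its configuration and conformity score."""

    position: tuple[float, float]
    config: TrimmerConfig
    dr: float  # percent; math.inf when no dose falls outside the target
    trimmer_positions: tuple[float | None, float | None, float | None, float | None] = (
        None,
        None,
        None,
        None,
    )  # (X1, X2, Y1, Y2) edge coordinates, None = Out


@dataclass
class Plan:
    """A single-energy-layer plan: spots, per-spot weights in protons, and
    the planning parameters that produced it."""

    spots: list[CandidateSpot]
    beam: BeamSpec
    tsd: float
    weights: np.ndarray | None = None
    t_coll: float = 0.0
    dr_thresh: float = 0.0
    prescription: float = 5.0

    def __post_init__(self) -> None:
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.spots),):
                raise ValueError("one weight per spot required")
            if np.any(self.weights < 0):
                raise ValueError("weights must be nonnegative")

    @property
    def n_collimated(self) -> int:
        return sum(s.config.engaged > 0 for s in self.spots)


def place_spots(
    target: TargetGeometry, spacing: float, margin: float = 10.0, energy: float = 0.0
) -> SpotMap:
    """Rectangular spot lattice covering the target bounding box expanded by
    ``margin``, aligned so that one lattice node falls on the target
    centroid."""
    if spacing <= 0:
        raise ValueError("spot spacing must be positive")
    cx, cy = target.centroid()
    xmin, xmax, ymin, ymax = target.bounding_box()
    xmin -= margin
    xmax += margin
    ymin -= margin
    ymax += margin
    kx = np.arange(math.ceil((xmin - cx) / spacing), math.floor((xmax - cx) / spacing) + 1)
    ky = np.arange(math.ceil((ymin - cy) / spacing), math.floor((ymax - cy) / spacing) + 1)
    xs = cx + kx * spacing
    ys = cy + ky * spacing
    xx, yy = np.meshgrid(xs, ys)
    positions = np.column_stack([xx.ravel(), yy.ravel()])
    return SpotMap(positions=positions, spacing=spacing, energy=energy)


class KernelSampler:
    """Resamples library kernels onto a target's evaluation lattice.

    Kernels live on a 1 mm lattice centered on the beamlet axis; evaluation
    grids are finer (0.5 mm analysis resolution).  For a fixed fractional
    offset between a spot position and the evaluation lattice the resampled
    kernel array is shared by every spot on the same spot lattice, so it is
    interpolated once and afterwards applied by pure integer-window
    arithmetic.
    """

    def __init__(self, library: KernelLibrary, target: TargetGeometry):
        self.library = library
        self.target = target
        self.spacing = target.spacing
        self.origin = target.origin
        self.shape = target.mask.shape
        self._cache: dict = {}

    def _resampled(self, config: TrimmerConfig, frac: tuple[float, float]):
        key = (config, frac)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        kernel = self.library.kernel_for(config)
        h = self.spacing
        half = (kernel.grid.shape[1] - 1) / 2 * kernel.spacing
        # relative sample coordinates that land on the evaluation lattice
        rx = np.arange(math.ceil((-half - frac[0]) / h), math.floor((half - frac[0]) / h) + 1)
        ry = np.arange(math.ceil((-half - frac[1]) / h), math.floor((half - frac[1]) / h) + 1)
        dx = frac[0] + rx * h
        dy = frac[1] + ry * h
        interp = kernel.interpolator()
        vals = interp((dy[:, None], dx[None, :]))
        vals = np.maximum(vals, 0.0)
        out = (vals, dx[0], dy[0])
        self._cache[key] = out
        return out

    def window(self, config: TrimmerConfig, position):
        """Kernel values of ``config`` for a spot at ``position``, clipped
        to the evaluation grid.

        Returns ``(values, iy0, ix0)``: a 2D array and the grid indices of
        its [0, 0] node, or ``None`` if there is no overlap.
        """
        px, py = float(position[0]), float(position[1])
        h = self.spacing
        fx = round((px - self.origin[0]) / h, 9)
        fy = round((py - self.origin[1]) / h, 9)
        frac = (round((fx - math.floor(fx)) * -h, 6), round((fy - math.floor(fy)) * -h, 6))
        # frac is the offset from the spot to the nearest lattice node at or
        # below it, expressed as a relative sample coordinate in [-h, 0]
        vals, dx0, dy0 = self._resampled(config, frac)
        ix0 = int(round((px + dx0 - self.origin[0]) / h))
        iy0 = int(round((py + dy0 - self.origin[1]) / h))
        ny, nx = self.shape
        ky, kx = vals.shape
        sy0, sx0 = max(0, -iy0), max(0, -ix0)
        ey, ex = min(ky, ny - iy0), min(kx, nx - ix0)
        if sy0 >= ey or sx0 >= ex:
            return None
        return vals[sy0:ey, sx0:ex], iy0 + sy0, ix0 + sx0

    def dose_ratio(self, config: TrimmerConfig, position) -> float:
        win = self.window(config, position)
        if win is None:
            return 0.0
        vals, iy0, ix0 = win
        sub = self.target.mask[iy0 : iy0 + vals.shape[0], ix0 : ix0 + vals.shape[1]]
        din = float(vals[sub].sum())
        dout = float(vals.sum()) - din
        if dout <= 0.0:
            return math.inf
        return 100.0 * din / dout

    def accumulate(self, out: np.ndarray, config: TrimmerConfig, position, weight: float) -> None:
        win = self.window(config, position)
        if win is None:
            return
        vals, iy0, ix0 = win
        out[iy0 : iy0 + vals.shape[0], ix0 : ix0 + vals.shape[1]] += weight * vals


def dose_ratio(kernel: BeamletKernel, position, target: TargetGeometry) -> float:
    """Conformity dose ratio of a beamlet shifted to ``position`` over the
    target's evaluation grid: 100 * Din / Dout (percent), where Din and
    Dout integrate the shifted kernel inside and outside the target mask.
    Returns ``math.inf`` when no dose falls outside the target."""
    interp = kernel.interpolator()
    x = target.x_coords - float(position[0])
    y = target.y_coords - float(position[1])
    vals = interp((y[:, None], x[None, :]))
    vals = np.maximum(vals, 0.0)
    din = float(vals[target.mask].sum())
    dout = float(vals.sum()) - din
    if dout <= 0.0:
        return math.inf
    return 100.0 * din / dout


def select_spots(
    spot_map: SpotMap,
    library: KernelLibrary,
    target: TargetGeometry,
    dr_thresh: float,
    sampler: KernelSampler | None = None,
) -> list[CandidateSpot]:
    """Keep every spot whose open-field dose ratio reaches ``dr_thresh``.

    The kept spot stores its DR; collimation is assigned in a second pass
    (:func:`assign_collimation`).
    """
    if dr_thresh < 0:
        raise ValueError("dr_thresh must be nonnegative")
    sampler = sampler or KernelSampler(library, target)
    kept: list[CandidateSpot] = []
    for pos in spot_map.positions:
        dr = sampler.dose_ratio(OPEN_CONFIG, pos)
        if dr >= dr_thresh:
            spot = CandidateSpot(position=(float(pos[0]), float(pos[1])), config=OPEN_CONFIG, dr=dr)
            spot.trimmer_positions = trimmer_positions_for_spot(spot)
            kept.append(spot)
    return kept


def assign_collimation(
    candidates: list[CandidateSpot],
    library: KernelLibrary,
    target: TargetGeometry,
    t_coll: float,
    sampler: KernelSampler | None = None,
) -> list[CandidateSpot]:
    """Assign trimmer configurations at collimation level ``t_coll``.

    A spot is collimated iff its open-field DR is finite and below
    ``t_coll`` (percent); larger Tcoll therefore collimates more spots.
    The assigned configuration is the library entry maximizing the spot's
    DR, ties broken by fewer engaged blades, then smaller offsets.
    """
    if not 0.0 <= t_coll <= 100.0:
        raise ValueError("t_coll must be in [0, 100]")
    sampler = sampler or KernelSampler(library, target)
    configs = library.configs()
    out: list[CandidateSpot] = []
    for spot in candidates:
        open_dr = spot.dr if spot.config.engaged == 0 else sampler.dose_ratio(OPEN_CONFIG, spot.position)
        if not (math.isfinite(open_dr) and open_dr < t_coll):
            new = replace(spot, config=OPEN_CONFIG, dr=open_dr)
            new.trimmer_positions = trimmer_positions_for_spot(new)
            out.append(new)
            continue
        best = None
        for config in configs:
            dr = sampler.dose_ratio(config, spot.position)
            rank = (-dr, config.engaged, config.offset_sum, config.label)
            if best is None or rank < best[0]:
                best = (rank, config, dr)
        new = replace(spot, config=best[1], dr=best[2])
        new.trimmer_positions = trimmer_positions_for_spot(new)
        out.append(new)
    return out


def trimmer_positions_for_spot(
    spot: CandidateSpot, min_offset: float = MIN_TRIMMER_OFFSET
):
    """Physical blade-edge coordinates (X1, X2, Y1, Y2) in mm for one spot.

    The '2' blade edge sits at the spot coordinate plus its offset, the '1'
    blade at the coordinate minus its offset; disengaged blades are
    ``None`` (parked out of field).  Engaged offsets below ``min_offset``
    are rejected.
    """
    config = spot.config
    px, py = spot.position
    for off in (config.x_offset, config.y_offset):
        if off is not None and off < min_offset:
            raise ValueError(f"engaged trimmer offset {off} mm is below the {min_offset} mm minimum")
    x1 = px - config.x_offset if config.x_trimmer == "X1" else None
    x2 = px + config.x_offset if config.x_trimmer == "X2" else None
    y1 = py - config.y_offset if config.y_trimmer == "Y1" else None
    y2 = py + config.y_offset if config.y_trimmer == "Y2" else None
    return (x1, x2, y1, y2)


# --------------------------------------------------------------------------
# plain-text plan table


def _fmt_trimmer(v: float | None) -> str:
    return "Out" if v is None else f"{v:.3f}"


def plan_to_table(plan: Plan) -> str:
    """Serialize a plan as a documented plain-text table."""
    lines = [
        "# dcplan plan table",
        f"# energy_mev={plan.beam.energy} range_shifted={plan.beam.range_shifted} "
        f"depth_cm={plan.beam.depth} sigma_air_mm={plan.beam.sigma_air} "
        f"measurement_depth_cm={plan.beam.measurement_depth}",
        f"# tsd_cm={plan.tsd} t_coll={plan.t_coll} dr_thresh={plan.dr_thresh} "
        f"prescription_gy={plan.prescription}",
        "# x_mm y_mm config t_x1 t_x2 t_y1 t_y2 weight_protons",
    ]
    weights = plan.weights if plan.weights is not None else np.zeros(len(plan.spots))
    for spot, w in zip(plan.spots, weights):
        t = spot.trimmer_positions
        lines.append(
            f"{spot.position[0]:.3f} {spot.position[1]:.3f} {spot.config.label} "
            f"{_fmt_trimmer(t[0])} {_fmt_trimmer(t[1])} {_fmt_trimmer(t[2])} "
            f"{_fmt_trimmer(t[3])} {w:.6e}"
        )
    return "\n".join(lines) + "\n"


def plan_from_table(text: str) -> Plan:
    header: dict[str, str] = {}
    spots: list[CandidateSpot] = []
    weights: list[float] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for token in line[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    header[k] = v
            continue
        fields = line.split()
        if len(fields) != 8:
            raise ValueError(f"malformed plan row: {line!r}")
        x, y = float(fields[0]), float(fields[1])
        config = TrimmerConfig.from_label(fields[2])
        trimmers = tuple(None if f == "Out" else float(f) for f in fields[3:7])
        spots.append(
            CandidateSpot(position=(x, y), config=config, dr=math.nan, trimmer_positions=trimmers)
        )
        weights.append(float(fields[7]))
    beam = BeamSpec(
        energy=float(header["energy_mev"]),
        sigma_air=float(header["sigma_air_mm"]),
        depth=float(header["depth_cm"]),
        range_shifted=header["range_shifted"] == "True",
        measurement_depth=float(header["measurement_depth_cm"]),
    )
    return Plan(
        spots=spots,
        beam=beam,
        tsd=float(header["tsd_cm"]),
        weights=np.array(weights),
        t_coll=float(header["t_coll"]),
        dr_thresh=float(header["dr_thresh"]),
        prescription=float(header["prescription_gy"]),
    )
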