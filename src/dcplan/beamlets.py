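"""Synthetic pencil-beamlet kernel library for a sliding-bar dynamic collimator.

A beamlet is the 2D lateral dose distribution (Gy/proton) of one scanned
proton pencil beam at its treatment depth, on a 1 mm isotropic lattice.
Uncollimated beamlets are modelled as a radially symmetric double Gaussian
(core + light halo).  Collimation by up to two orthogonal nickel trimmer
blades (X1/X2/Y1/Y2) is modelled by multiplying the kernel with an erf-shaped
transmission edge whose spread grows with the trimmer-to-surface distance
(TSD) and with depth in water.

The per-energy library holds the trimmer configurations of the machine's
offset table (1 and 2 mm offsets), expanded by mirror symmetry to all four
blades: 32 trimmed entries plus one open (uncollimated) entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erfc

__all__ = [
    "BeamSpec",
    "TrimmerConfig",
    "BeamletKernel",
    "KernelLibrary",
    "KernelModel",
    "LibraryEntry",
    "BEAM_TABLE",
    "BASE_CONFIGS",
    "OPEN_CONFIG",
    "FLIPS",
    "beam_from_table",
    "effective_sigma",
    "edge_spread_sigma",
    "make_uncollimated_kernel",
    "collimate_kernel",
    "flip_kernel",
    "expand_library",
    "build_library",
    "library_to_hdf5",
    "library_from_hdf5",
    "export_profiles",
]


# --------------------------------------------------------------------------
# beam table: (depth cm, range_shifted, energy MeV, sigma_air mm)
# Machine beam data for each single-energy treatment depth: spot sigma at
# isocenter in air, with and without the upstream polyethylene range shifter.
_BEAM_ROWS = [
    (2.0, True, 86.9, 7.6),
    (3.0, True, 94.8, 7.0),
    (5.0, True, 109.3, 6.2),
    (5.0, False, 78.3, 6.6),
    (10.0, True, 140.5, 4.9),
    (10.0, False, 116.0, 5.0),
    (13.5, True, 159.7, 4.3),
    (15.0, False, 146.1, 4.2),
    (17.5, False, 159.7, 3.8),
    (22.5, False, 184.6, 3.4),
]

BEAM_TABLE = {(energy, rs): (depth, sigma) for depth, rs, energy, sigma in _BEAM_ROWS}


@dataclass(frozen=True)
class BeamSpec:
    """One monoenergetic scanned beam.

    Parameters
    ----------
    energy : float
        Nominal beam energy in MeV.
    sigma_air : float
        Spot sigma at isocenter in air, mm.
    depth : float
        Treatment (Bragg) depth in water, cm.
    range_shifted : bool
        Whether the upstream range shifter is in the beam path.
    measurement_depth : float
        Depth of the evaluation plane in water, cm (defaults to ``depth``).
    """

    energy: float
    sigma_air: float
    depth: float
    range_shifted: bool = False
    measurement_depth: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sigma_air <= 0:
            raise ValueError("sigma_air must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.measurement_depth is None:
            object.__setattr__(self, "measurement_depth", self.depth)


def beam_from_table(energy: float, range_shifted: bool) -> BeamSpec:
    """Look up a machine beam by (energy, range-shifter flag).

    Raises
    ------
    KeyError
        If the combination is not a row of the beam table; the message lists
        the valid rows.
    """
    key = (float(energy), bool(range_shifted))
    if key not in BEAM_TABLE:
        rows = ", ".join(
            f"({e} MeV, {'RS' if rs else 'NRS'})" for e, rs in sorted(BEAM_TABLE)
        )
        raise KeyError(
            f"no beam with energy {energy} MeV and "
            f"{'RS' if range_shifted else 'NRS'}; valid rows: {rows}"
        )
    depth, sigma = BEAM_TABLE[key]
    return BeamSpec(
        energy=key[0], sigma_air=sigma, depth=depth, range_shifted=key[1]
    )


# --------------------------------------------------------------------------
# trimmer configurations

_X_NAMES = ("X1", "X2", "Out")
_Y_NAMES = ("Y1", "Y2", "Out")


@dataclass(frozen=True)
class TrimmerConfig:
    """Engagement state of the four trimmer blades for one beamlet.

    At most one X blade and one Y blade may be engaged (never X1+X2 or
    Y1+Y2); the offset is the lateral distance, mm, from the beamlet axis
    to the engaged blade edge and is present iff the blade is engaged.
    """

    x_trimmer: str = "Out"
    y_trimmer: str = "Out"
    x_offset: float | None = None
    y_offset: float | None = None

    def __post_init__(self) -> None:
        if self.x_trimmer not in _X_NAMES:
            raise ValueError(f"x_trimmer must be one of {_X_NAMES}")
        if self.y_trimmer not in _Y_NAMES:
            raise ValueError(f"y_trimmer must be one of {_Y_NAMES}")
        if (self.x_trimmer == "Out") != (self.x_offset is None):
            raise ValueError("x_offset must be present iff an X trimmer is engaged")
        if (self.y_trimmer == "Out") != (self.y_offset is None):
            raise ValueError("y_offset must be present iff a Y trimmer is engaged")
        for off in (self.x_offset, self.y_offset):
            if off is not None and off <= 0:
                raise ValueError("trimmer offsets must be positive")

    @property
    def engaged(self) -> int:
        """Number of engaged blades (0, 1 or 2)."""
        return (self.x_trimmer != "Out") + (self.y_trimmer != "Out")

    @property
    def offset_sum(self) -> float:
        return (self.x_offset or 0.0) + (self.y_offset or 0.0)

    @property
    def label(self) -> str:
        if self.engaged == 0:
            return "Open"
        parts = []
        if self.x_trimmer != "Out":
            parts.append(f"{self.x_trimmer}@{self.x_offset:g}")
        if self.y_trimmer != "Out":
            parts.append(f"{self.y_trimmer}@{self.y_offset:g}")
        return "+".join(parts)

    @classmethod
    def from_label(cls, label: str) -> "TrimmerConfig":
        if label == "Open":
            return cls()
        kw: dict = {}
        for part in label.split("+"):
            name, off = part.split("@")
            axis = "x" if name.startswith("X") else "y"
            kw[f"{axis}_trimmer"] = name
            kw[f"{axis}_offset"] = float(off)
        return cls(**kw)


OPEN_CONFIG = TrimmerConfig()

# The machine offset table: nine unique base states in the X2/Y2 convention —
# the four two-blade offset combinations, two single-Y, two single-X, and
# the open state.
BASE_CONFIGS: tuple[TrimmerConfig, ...] = tuple(
    [
        TrimmerConfig("X2", "Y2", 1.0, 1.0),
        TrimmerConfig("X2", "Y2", 1.0, 2.0),
        TrimmerConfig("X2", "Y2", 2.0, 1.0),
        TrimmerConfig("X2", "Y2", 2.0, 2.0),
        TrimmerConfig("Out", "Y2", None, 1.0),
        TrimmerConfig("Out", "Y2", None, 2.0),
        TrimmerConfig("X2", "Out", 1.0, None),
        TrimmerConfig("X2", "Out", 2.0, None),
        TrimmerConfig(),
    ]
)


# --------------------------------------------------------------------------
# kernel model parameters


@dataclass(frozen=True)
class KernelModel:
    """Tunable parameters of the analytic beamlet model.

    core_weight / halo_sigma_ratio / halo weight (the complement) shape the
    double-Gaussian lateral profile; ``broadening_k`` (mm per cm of water)
    grows the in-water spot sigma with depth; ``theta_nrs`` / ``theta_rs``
    (mrad) are the effective angular spreads that drive the collimated
    edge-spread dependence on TSD without and with the range shifter;
    ``peak_dose`` is the Gy/proton calibration at the beamlet axis.
    """

    core_weight: float = 0.95
    halo_sigma_ratio: float = 3.0
    broadening_k: float = 0.35  # mm of sigma per cm of water depth
    theta_nrs: float = 2.0  # mrad
    theta_rs: float = 12.0  # mrad
    peak_dose: float = 1e-9  # Gy/proton at the beamlet axis


DEFAULT_MODEL = KernelModel()


def effective_sigma(beam: BeamSpec, model: KernelModel = DEFAULT_MODEL) -> float:
    """In-water core sigma (mm) at the beam's measurement depth."""
    d = beam.measurement_depth
    return float(np.hypot(beam.sigma_air, model.broadening_k * d))


def mixture_sigma(beam: BeamSpec, model: KernelModel = DEFAULT_MODEL) -> float:
    """Per-axis RMS sigma (mm) of the full double-Gaussian mixture."""
    sc = effective_sigma(beam, model)
    w = model.core_weight
    return sc * float(np.sqrt(w + (1.0 - w) * model.halo_sigma_ratio**2))


def edge_spread_sigma(
    beam: BeamSpec, tsd: float, model: KernelModel = DEFAULT_MODEL
) -> float:
    """Gaussian sigma (mm) of the collimated field edge.

    Combines the geometric penumbra of the angular spread over the air gap
    plus depth (theta_eff * (TSD + d_w)) with in-water scatter (k * d_w).
    """
    if tsd < 0:
        raise ValueError("tsd must be nonnegative")
    theta = model.theta_rs if beam.range_shifted else model.theta_nrs
    d = beam.measurement_depth
    geometric = theta * 1e-3 * (tsd + d) * 10.0  # cm -> mm
    scatter = model.broadening_k * d
    return float(np.hypot(geometric, scatter))


# --------------------------------------------------------------------------
# kernels


@dataclass
class BeamletKernel:
    """2D dose-per-proton lattice for one beamlet at the evaluation plane.

    ``grid`` is indexed [iy, ix] on a node-centered 1 mm isotropic lattice
    whose central node is the beamlet axis (coordinate origin).
    """

    grid: np.ndarray
    beam: BeamSpec
    config: TrimmerConfig = OPEN_CONFIG
    tsd: float = 5.0
    spacing: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("kernel grid must be 2D")
        if np.any(self.grid < 0):
            raise ValueError("kernel values must be nonnegative")
        if not np.isfinite(self.grid).all():
            raise ValueError("kernel values must be finite")

    @property
    def x_coords(self) -> np.ndarray:
        nx = self.grid.shape[1]
        return self.origin[0] + (np.arange(nx) - (nx - 1) / 2) * self.spacing

    @property
    def y_coords(self) -> np.ndarray:
        ny = self.grid.shape[0]
        return self.origin[1] + (np.arange(ny) - (ny - 1) / 2) * self.spacing

    @property
    def integral(self) -> float:
        """Integrated dose, Gy·mm²/proton."""
        return float(self.grid.sum() * self.spacing**2)

    def interpolator(self):
        from scipy.interpolate import RegularGridInterpolator

        return RegularGridInterpolator(
            (self.y_coords, self.x_coords),
            self.grid,
            bounds_error=False,
            fill_value=0.0,
        )


def make_uncollimated_kernel(
    beam: BeamSpec,
    grid_half_width: float | None = None,
    model: KernelModel = DEFAULT_MODEL,
) -> BeamletKernel:
    """Build the open-field double-Gaussian beamlet kernel.

    The lateral profile is ``w·G(sigma_core) + (1-w)·G(sigma_halo)`` with
    the in-water core sigma of :func:`effective_sigma`, normalized so the
    central-axis node equals the model's Gy/proton peak calibration.

    ``grid_half_width`` (mm) defaults to five mixture sigmas and must be at
    least that large so the kernel support is contained.
    """
    sig_mix = mixture_sigma(beam, model)
    min_half = 5.0 * sig_mix
    if grid_half_width is None:
        grid_half_width = min_half
    if grid_half_width < min_half - 1e-9:
        raise ValueError(
            f"grid_half_width {grid_half_width:.1f} mm is below the required "
            f"5 effective sigma = {min_half:.1f} mm"
        )
    half_nodes = int(np.ceil(grid_half_width / 1.0))
    x = (np.arange(2 * half_nodes + 1) - half_nodes) * 1.0
    xx, yy = np.meshgrid(x, x)
    r2 = xx**2 + yy**2
    sc = effective_sigma(beam, model)
    sh = model.halo_sigma_ratio * sc
    w = model.core_weight
    # normalized 2D Gaussians (each integrates to one over the plane)
    core = np.exp(-r2 / (2 * sc**2)) / (2 * np.pi * sc**2)
    halo = np.exp(-r2 / (2 * sh**2)) / (2 * np.pi * sh**2)
    profile = w * core + (1.0 - w) * halo
    grid = model.peak_dose * profile / profile[half_nodes, half_nodes]
    return BeamletKernel(grid=grid, beam=beam, config=OPEN_CONFIG)


def _transmission(coords: np.ndarray, name: str, offset: float, sigma: float) -> np.ndarray:
    """Blade transmission along one axis: erf edge at ±offset.

    The '2' blade collimates from the positive-coordinate side (edge at
    +offset), the '1' blade from the negative side (edge at -offset); the
    offset is measured from the beamlet axis toward the field interior.
    """
    if name.endswith("2"):
        u = coords - offset
    else:
        u = -coords - offset
    return 0.5 * erfc(u / (np.sqrt(2.0) * sigma))


def collimate_kernel(
    kernel: BeamletKernel,
    config: TrimmerConfig,
    tsd: float,
    model: KernelModel = DEFAULT_MODEL,
) -> BeamletKernel:
    """Apply trimmer collimation to an open kernel.

    The open-field dose is multiplied by the product of the engaged blades'
    erf transmission edges (a unit step blurred by the edge-spread sigma of
    :func:`edge_spread_sigma`).  The both-Out configuration returns the
    kernel unchanged apart from its config/tsd metadata.
    """
    if config.engaged == 0:
        return replace(kernel, grid=kernel.grid.copy(), config=config, tsd=tsd)
    sigma_e = edge_spread_sigma(kernel.beam, tsd, model)
    grid = kernel.grid.copy()
    if config.x_trimmer != "Out":
        tx = _transmission(kernel.x_coords, config.x_trimmer, config.x_offset, sigma_e)
        grid *= tx[np.newaxis, :]
    if config.y_trimmer != "Out":
        ty = _transmission(kernel.y_coords, config.y_trimmer, config.y_offset, sigma_e)
        grid *= ty[:, np.newaxis]
    return replace(kernel, grid=grid, config=config, tsd=tsd)


# --------------------------------------------------------------------------
# symmetry expansion

FLIPS = ("identity", "mirror_x", "mirror_y", "mirror_xy")

_X_SWAP = {"X1": "X2", "X2": "X1", "Out": "Out"}
_Y_SWAP = {"Y1": "Y2", "Y2": "Y1", "Out": "Out"}


def _flip_config(config: TrimmerConfig, flip: str) -> TrimmerConfig:
    x_name, y_name = config.x_trimmer, config.y_trimmer
    if flip in ("mirror_x", "mirror_xy"):
        x_name = _X_SWAP[x_name]
    if flip in ("mirror_y", "mirror_xy"):
        y_name = _Y_SWAP[y_name]
    return TrimmerConfig(x_name, y_name, config.x_offset, config.y_offset)


def flip_kernel(kernel: BeamletKernel, flip: str) -> BeamletKernel:
    """Mirror a kernel about the x and/or y axis, relabelling its blades."""
    if flip not in FLIPS:
        raise ValueError(f"flip must be one of {FLIPS}")
    grid = kernel.grid
    if flip in ("mirror_x", "mirror_xy"):
        grid = grid[:, ::-1]
    if flip in ("mirror_y", "mirror_xy"):
        grid = grid[::-1, :]
    return replace(kernel, grid=grid.copy(), config=_flip_config(kernel.config, flip))


@dataclass
class LibraryEntry:
    config: TrimmerConfig
    flip: str
    kernel: BeamletKernel


@dataclass
class KernelLibrary:
    """The 32+1 per-energy beamlet library.

    ``entries`` are the 32 trimmed kernels obtained by applying the four
    axis-flip transforms to each of the 8 collimated base configurations
    (single-blade entries are pairwise mirror-degenerate; the duplicate
    count is the machine convention and is kept).  ``uncollimated`` is the
    open-field kernel.
    """

    beam: BeamSpec
    uncollimated: BeamletKernel
    entries: list[LibraryEntry]
    tsd: float = 5.0

    @property
    def n_trimmed(self) -> int:
        return len(self.entries)

    def configs(self) -> list[TrimmerConfig]:
        """Distinct trimmed configurations (duplicates collapsed)."""
        seen: dict[TrimmerConfig, None] = {}
        for e in self.entries:
            seen.setdefault(e.config, None)
        return list(seen)

    def kernel_for(self, config: TrimmerConfig) -> BeamletKernel:
        if config.engaged == 0:
            return self.uncollimated
        for e in self.entries:
            if e.config == config:
                return e.kernel
        raise KeyError(f"configuration {config.label} not in library")


def expand_library(
    base_kernels: dict[TrimmerConfig, BeamletKernel], beam: BeamSpec
) -> KernelLibrary:
    """Expand the base-configuration kernels into the full 32+1 library.

    ``base_kernels`` must cover the 8 collimated base configurations (X2/Y2
    convention) and the open configuration; each collimated kernel is
    mirrored by the four axis flips to populate all four blades.
    """
    required = set(BASE_CONFIGS)
    missing = required - set(base_kernels)
    if missing:
        labels = ", ".join(sorted(c.label for c in missing))
        raise ValueError(f"missing base configurations: {labels}")
    entries: list[LibraryEntry] = []
    tsd = None
    for config in BASE_CONFIGS:
        if config.engaged == 0:
            continue
        kernel = base_kernels[config]
        tsd = kernel.tsd
        for flip in FLIPS:
            entries.append(LibraryEntry(_flip_config(config, flip), flip, flip_kernel(kernel, flip)))
    assert len(entries) == 32
    return KernelLibrary(
        beam=beam,
        uncollimated=base_kernels[OPEN_CONFIG],
        entries=entries,
        tsd=tsd if tsd is not None else 5.0,
    )


def build_library(
    beam: BeamSpec,
    tsd: float = 5.0,
    model: KernelModel = DEFAULT_MODEL,
    grid_half_width: float | None = None,
) -> KernelLibrary:
    """Generate and expand the full beamlet library for one beam."""
    open_kernel = make_uncollimated_kernel(beam, grid_half_width, model)
    base = {OPEN_CONFIG: replace(open_kernel, grid=open_kernel.grid.copy(), tsd=tsd)}
    for config in BASE_CONFIGS:
        if config.engaged:
            base[config] = collimate_kernel(open_kernel, config, tsd, model)
    return expand_library(base, beam)


# --------------------------------------------------------------------------
# persistence and export


def library_to_hdf5(library: KernelLibrary, path) -> None:
    """Persist one beam's library as a hierarchical binary container."""
    import h5py

    with h5py.File(path, "w") as f:
        b = library.beam
        f.attrs.update(
            energy=b.energy,
            sigma_air=b.sigma_air,
            depth=b.depth,
            range_shifted=b.range_shifted,
            measurement_depth=b.measurement_depth,
            tsd=library.tsd,
        )
        f.create_dataset("uncollimated", data=library.uncollimated.grid)
        g = f.create_group("trimmed")
        for i, e in enumerate(library.entries):
            d = g.create_dataset(f"entry_{i:02d}", data=e.kernel.grid)
            d.attrs["config"] = e.config.label
            d.attrs["flip"] = e.flip


def library_from_hdf5(path) -> KernelLibrary:
    import h5py

    with h5py.File(path, "r") as f:
        beam = BeamSpec(
            energy=float(f.attrs["energy"]),
            sigma_air=float(f.attrs["sigma_air"]),
            depth=float(f.attrs["depth"]),
            range_shifted=bool(f.attrs["range_shifted"]),
            measurement_depth=float(f.attrs["measurement_depth"]),
        )
        tsd = float(f.attrs["tsd"])
        uncoll = BeamletKernel(
            grid=f["uncollimated"][()], beam=beam, config=OPEN_CONFIG, tsd=tsd
        )
        entries = []
        for name in sorted(f["trimmed"]):
            d = f["trimmed"][name]
            config = TrimmerConfig.from_label(d.attrs["config"])
            entries.append(
                LibraryEntry(
                    config,
                    d.attrs["flip"],
                    BeamletKernel(grid=d[()], beam=beam, config=config, tsd=tsd),
                )
            )
    return KernelLibrary(beam=beam, uncollimated=uncoll, entries=entries, tsd=tsd)


def export_profiles(kernel: BeamletKernel, path) -> None:
    """Write the central x and y 1D profiles as plain text columns."""
    ny, nx = kernel.grid.shape
    xprof = kernel.grid[(ny - 1) // 2, :]
    yprof = kernel.grid[:, (nx - 1) // 2]
    with open(path, "w") as f:
        f.write("# axis coordinate_mm dose_gy_per_proton\n")
        for x, v in zip(kernel.x_coords, xprof):
            f.write(f"x {x:.1f} {v:.6e}\n")
        for y, v in zip(kernel.y_coords, yprof):
            f.write(f"y {y:.1f} {v:.6e}\n")
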