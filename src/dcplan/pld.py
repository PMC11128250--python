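"""Extended PLD (pencil layer definition) delivery-file I/O.

A PLD file describes one deliverable field as layer blocks of spot elements
(position and meterset in MU).  This dialect appends the four trimmer-blade
coordinates to the end of every element line so a dynamic collimation
system can position its blades per spot.  Optimized weights in protons are
converted to MU through a per-energy protons/MU calibration factor.

Dialect (comma separated, one file per field)::

    # dcplan PLD 1.0; coordinates mm at isocenter plane; X = trimmer-X travel axis
    beam,<energy MeV>,<NRS|RS>,<tsd cm>,<calibration label>
    conversion,<protons per MU>
    layer,<energy MeV>,<n elements>
    spot,<x>,<y>,<MU>,<T_X1>,<T_X2>,<T_Y1>,<T_Y2>

Coordinates carry 3 decimals, MU 6 significant digits, and parked blades
the token ``Out``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .beamlets import BeamSpec, TrimmerConfig
from .planning import CandidateSpot, Plan

__all__ = [
    "ConversionFactor",
    "PLDElement",
    "PLDLayer",
    "PLDFile",
    "protons_per_mu",
    "plan_to_pld",
    "write_pld",
    "write_pld_file",
    "read_pld",
    "pld_to_plan",
    "save_conversion_table",
    "load_conversion_table",
]

_MAGIC = "# dcplan PLD 1.0; coordinates mm at isocenter plane; X = trimmer-X travel axis"


@dataclass(frozen=True)
class ConversionFactor:
    """Per-energy protons/MU calibration under reference conditions."""

    protons_per_mu: float
    energy: float = 0.0
    reference_conditions: str = "synthetic"

    def __post_init__(self) -> None:
        if self.protons_per_mu <= 0:
            raise ValueError("protons_per_mu must be positive")


def protons_per_mu(
    dose_per_proton: float,
    dose_per_mu: float,
    energy: float = 0.0,
    reference_conditions: str = "synthetic",
) -> ConversionFactor:
    """Calibration factor relating optimizer protons to machine MU:
    (Gy/MU) / (Gy/proton) = protons/MU."""
    if dose_per_proton <= 0 or dose_per_mu <= 0:
        raise ValueError("doses must be positive")
    return ConversionFactor(
        protons_per_mu=dose_per_mu / dose_per_proton,
        energy=energy,
        reference_conditions=reference_conditions,
    )


@dataclass
class PLDElement:
    x: float
    y: float
    mu: float
    trimmers: tuple[float | None, float | None, float | None, float | None]

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("element MU must be nonnegative")


@dataclass
class PLDLayer:
    energy: float
    elements: list[PLDElement] = field(default_factory=list)


@dataclass
class PLDFile:
    energy: float
    range_shifted: bool
    tsd: float
    calibration: str
    conversion: ConversionFactor
    layers: list[PLDLayer] = field(default_factory=list)


def plan_to_pld(plan: Plan, conversion: ConversionFactor) -> PLDFile:
    """Convert an optimized plan (weights in protons) to a one-layer PLD."""
    if plan.weights is None:
        raise ValueError("plan has no weights; optimize before export")
    if np.any(plan.weights < 0):
        raise ValueError("negative weight in plan")
    elements = [
        PLDElement(
            x=spot.position[0],
            y=spot.position[1],
            mu=float(w) / conversion.protons_per_mu,
            trimmers=spot.trimmer_positions,
        )
        for spot, w in zip(plan.spots, plan.weights)
    ]
    return PLDFile(
        energy=plan.beam.energy,
        range_shifted=plan.beam.range_shifted,
        tsd=plan.tsd,
        calibration=conversion.reference_conditions,
        conversion=conversion,
        layers=[PLDLayer(energy=plan.beam.energy, elements=elements)],
    )


def _fmt_trimmer(v: float | None) -> str:
    return "Out" if v is None else f"{v:.3f}"


def write_pld_file(pld: PLDFile, path) -> None:
    lines = [_MAGIC]
    lines.append(
        f"beam,{pld.energy:.3f},{'RS' if pld.range_shifted else 'NRS'},"
        f"{pld.tsd:.3f},{pld.calibration}"
    )
    lines.append(f"conversion,{pld.conversion.protons_per_mu:.6e}")
    for layer in pld.layers:
        lines.append(f"layer,{layer.energy:.3f},{len(layer.elements)}")
        for el in layer.elements:
            t = ",".join(_fmt_trimmer(v) for v in el.trimmers)
            lines.append(f"spot,{el.x:.3f},{el.y:.3f},{el.mu:.6g},{t}")
    with open(path, "w", newline="\n") as f:
        f.write("\n".join(lines) + "\n")


def write_pld(plan: Plan, conversion: ConversionFactor, path) -> PLDFile:
    """Write an optimized plan as an extended PLD file; returns the PLD
    structure that was serialized."""
    pld = plan_to_pld(plan, conversion)
    write_pld_file(pld, path)
    return pld


class PLDParseError(ValueError):
    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _parse_trimmer(token: str, lineno: int) -> float | None:
    if token == "Out":
        return None
    try:
        return float(token)
    except ValueError:
        raise PLDParseError(lineno, f"bad trimmer coordinate {token!r}") from None


def read_pld(path) -> PLDFile:
    """Parse an extended PLD file, strictly.

    Legacy element lines without the four trimmer fields are a dialect
    error, not silently accepted; negative MU is a validation error.
    """
    with open(path) as f:
        raw = f.read().splitlines()
    header: dict = {}
    conversion: ConversionFactor | None = None
    layers: list[PLDLayer] = []
    for lineno, line in enumerate(raw, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split(",")
        kind = fields[0]
        if kind == "beam":
            if len(fields) != 5:
                raise PLDParseError(lineno, "beam line needs 5 fields")
            header = {
                "energy": float(fields[1]),
                "range_shifted": fields[2] == "RS",
                "tsd": float(fields[3]),
                "calibration": fields[4],
            }
        elif kind == "conversion":
            if len(fields) != 2:
                raise PLDParseError(lineno, "conversion line needs 2 fields")
            conversion = ConversionFactor(
                protons_per_mu=float(fields[1]),
                energy=header.get("energy", 0.0),
                reference_conditions=header.get("calibration", "synthetic"),
            )
        elif kind == "layer":
            if len(fields) != 3:
                raise PLDParseError(lineno, "layer line needs 3 fields")
            layers.append(PLDLayer(energy=float(fields[1])))
        elif kind == "spot":
            if not layers:
                raise PLDParseError(lineno, "spot element before any layer block")
            if len(fields) != 8:
                raise PLDParseError(
                    lineno,
                    "element line must carry x, y, MU and four trimmer fields "
                    f"(got {len(fields) - 1} fields); legacy PLD lines without "
                    "trimmer coordinates are not accepted",
                )
            mu = float(fields[3])
            if mu < 0:
                raise PLDParseError(lineno, f"negative MU {mu}")
            trimmers = tuple(_parse_trimmer(t, lineno) for t in fields[4:8])
            layers[-1].elements.append(
                PLDElement(x=float(fields[1]), y=float(fields[2]), mu=mu, trimmers=trimmers)
            )
        else:
            raise PLDParseError(lineno, f"unknown record kind {kind!r}")
    if not header:
        raise ValueError("missing beam header line")
    if conversion is None:
        raise ValueError("missing conversion line")
    return PLDFile(
        energy=header["energy"],
        range_shifted=header["range_shifted"],
        tsd=header["tsd"],
        calibration=header["calibration"],
        conversion=conversion,
        layers=layers,
    )


def _config_from_trimmers(trimmers, x: float, y: float) -> TrimmerConfig:
    tx1, tx2, ty1, ty2 = trimmers
    if tx1 is not None and tx2 is not None:
        raise ValueError("X1 and X2 cannot both be engaged")
    if ty1 is not None and ty2 is not None:
        raise ValueError("Y1 and Y2 cannot both be engaged")
    x_name, x_off = "Out", None
    if tx1 is not None:
        x_name, x_off = "X1", x - tx1
    elif tx2 is not None:
        x_name, x_off = "X2", tx2 - x
    y_name, y_off = "Out", None
    if ty1 is not None:
        y_name, y_off = "Y1", y - ty1
    elif ty2 is not None:
        y_name, y_off = "Y2", ty2 - y
    return TrimmerConfig(x_name, y_name, x_off, y_off)


def pld_to_plan(pld: PLDFile, beam: BeamSpec | None = None) -> Plan:
    """Reconstruct a plan skeleton (weights in protons) from a PLD file."""
    if len(pld.layers) != 1:
        raise ValueError("single-energy plans carry exactly one layer block")
    layer = pld.layers[0]
    spots = []
    weights = []
    for el in layer.elements:
        config = _config_from_trimmers(el.trimmers, el.x, el.y)
        spots.append(
            CandidateSpot(
                position=(el.x, el.y),
                config=config,
                dr=math.nan,
                trimmer_positions=el.trimmers,
            )
        )
        weights.append(el.mu * pld.conversion.protons_per_mu)
    if beam is None:
        beam = BeamSpec(
            energy=pld.energy, sigma_air=1.0, depth=1.0, range_shifted=pld.range_shifted
        )
    return Plan(spots=spots, beam=beam, tsd=pld.tsd, weights=np.array(weights))


def save_conversion_table(factors: list[ConversionFactor], path) -> None:
    """Persist per-energy protons/MU calibrations as a small text table."""
    lines = ["# energy_mev protons_per_mu reference_conditions"]
    for f in sorted(factors, key=lambda f: f.energy):
        lines.append(f"{f.energy:.3f} {f.protons_per_mu:.6e} {f.reference_conditions}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_conversion_table(path) -> dict[float, ConversionFactor]:
    """Load a per-energy calibration table keyed by energy (MeV)."""
    table: dict[float, ConversionFactor] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            energy, factor, label = line.split(maxsplit=2)
            table[float(energy)] = ConversionFactor(
                protons_per_mu=float(factor),
                energy=float(energy),
                reference_conditions=label,
            )
    return table
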