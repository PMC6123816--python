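"""Charge accounting, apparent impedance, and transmembrane potential.

The dose-like quantity of electrolytic ablation is the delivered charge
Q = ∫ I dt (trapezoid rule over the 10 s-sampled current trace).  The
transmembrane potential (TMP) a cell experiences in a quasi-static field is
estimated as the local field-gradient magnitude times the cell diameter
(default 14.2 µm); irreversible electroporation requires TMP of order 1 V,
so the threshold report distinguishes electroporation from electrolytic
mechanisms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .fields import RasterField

__all__ = [
    "CurrentTrace",
    "TMPField",
    "ElectroporationReport",
    "total_charge",
    "mean_impedance",
    "transmembrane_field",
    "electroporation_report",
]

#: average cell diameter used to scale gradients into transmembrane volts, µm
DEFAULT_CELL_DIAMETER_UM = 14.2

#: transmembrane potential needed for irreversible electroporation, volts
ELECTROPORATION_THRESHOLD_V = 1.0


@dataclass(frozen=True)
class CurrentTrace:
    """Time-stamped current samples from one ablation (times s, currents A)."""

    times: np.ndarray
    currents: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.currents, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "currents", i)
        if t.ndim != 1 or t.shape != i.shape:
            raise ValidationError("times and currents must be equal-length 1D arrays")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(i)):
            raise ValidationError("currents must be finite")

    def __len__(self) -> int:
        return self.times.size


def total_charge(trace: CurrentTrace) -> float:
    """Delivered charge in coulombs: trapezoidal integral of I(t)."""
    if len(trace) < 2:
        raise ValidationError("charge integration needs at least 2 samples")
    return float(np.trapezoid(trace.currents, trace.times))


def mean_impedance(trace: CurrentTrace, applied_voltage: float) -> float:
    """Quasi-static apparent impedance: applied voltage / time-averaged current."""
    q = total_charge(trace)
    span = trace.times[-1] - trace.times[0]
    mean_i = q / span
    if mean_i <= 0:
        raise ValidationError("mean current must be positive to define impedance")
    return float(applied_voltage / mean_i)


@dataclass
class TMPField:
    """Transmembrane-potential magnitude raster (volts, >= 0 on valid cells)."""

    raster: RasterField
    cell_diameter_um: float = DEFAULT_CELL_DIAMETER_UM


def _masked_gradient(values: np.ndarray, mask: np.ndarray, spacing: float):
    """Finite-difference gradient honouring a validity mask.

    Central differences where both neighbours are valid, one-sided at mask
    edges, NaN where no valid neighbour exists along the axis.
    """
    v = np.where(mask, values, np.nan)
    grads = []
    for axis in (0, 1):
        pad = [(0, 0), (0, 0)]
        pad[axis] = (1, 1)
        vp = np.pad(v, pad, constant_values=np.nan)
        sl_prev = [slice(None)] * 2
        sl_next = [slice(None)] * 2
        sl_prev[axis] = slice(0, -2)
        sl_next[axis] = slice(2, None)
        prev = vp[tuple(sl_prev)]
        nxt = vp[tuple(sl_next)]
        ok_p = np.isfinite(prev)
        ok_n = np.isfinite(nxt)
        g = np.full_like(v, np.nan)
        both = ok_p & ok_n
        g[both] = (nxt[both] - prev[both]) / (2.0 * spacing)
        fwd = ~ok_p & ok_n
        g[fwd] = (nxt[fwd] - v[fwd]) / spacing
        bwd = ok_p & ~ok_n
        g[bwd] = (v[bwd] - prev[bwd]) / spacing
        g[~mask] = np.nan
        grads.append(g)
    return grads[0], grads[1]  # d/drow (y), d/dcol (x)


def transmembrane_field(
    voltage_raster: RasterField,
    cell_diameter_um: float = DEFAULT_CELL_DIAMETER_UM,
) -> TMPField:
    """TMP = |∇V| × cell diameter, from the signed re-centered voltage raster.

    Gradients are taken at raster resolution (central differences, one-sided
    at valid-mask edges); the magnitude in V/mm is multiplied by the cell
    diameter converted to mm.  A spacing finer than the cell diameter merely
    warns — the linear interpolant's gradient is scale-free within triangles.
    """
    if cell_diameter_um <= 0:
        raise ValidationError("cell diameter must be positive")
    if voltage_raster.spacing * 1000.0 < cell_diameter_um:
        warnings.warn(
            "raster spacing is below the cell diameter; TMP is still the "
            "gradient-times-diameter estimate",
            stacklevel=2,
        )
    gy, gx = _masked_gradient(
        voltage_raster.values, voltage_raster.valid_mask, voltage_raster.spacing
    )
    grad_mag = np.hypot(gx, gy)  # V/mm
    tmp = grad_mag * (cell_diameter_um * 1e-3)  # V
    mask = voltage_raster.valid_mask & np.isfinite(tmp)
    tmp = np.where(mask, tmp, 0.0)
    raster = RasterField(
        origin=voltage_raster.origin,
        spacing=voltage_raster.spacing,
        values=tmp,
        valid_mask=mask,
        quantity="tmp_volts",
    )
    return TMPField(raster=raster, cell_diameter_um=cell_diameter_um)


@dataclass(frozen=True)
class ElectroporationReport:
    max_tmp_V: float
    argmax_mm: tuple
    exceeded: bool
    exceed_mask: np.ndarray
    threshold_V: float


def electroporation_report(
    tmp: TMPField, threshold: float = ELECTROPORATION_THRESHOLD_V
) -> ElectroporationReport:
    """Maximum TMP, its location, and the electroporation threshold test."""
    raster = tmp.raster
    if not raster.valid_mask.any():
        raise ValidationError("TMP field has an empty valid mask")
    masked = raster.masked()
    flat = np.nanargmax(masked)
    row, col = np.unravel_index(flat, masked.shape)
    max_v = float(masked[row, col])
    loc = (
        float(raster.origin[0] + col * raster.spacing),
        float(raster.origin[1] + row * raster.spacing),
    )
    exceed = np.zeros_like(raster.valid_mask)
    exceed[raster.valid_mask] = raster.values[raster.valid_mask] > threshold
    return ElectroporationReport(
        max_tmp_V=max_v,
        argmax_mm=loc,
        exceeded=bool(max_v > threshold),
        exceed_mask=exceed,
        threshold_V=float(threshold),
    )
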