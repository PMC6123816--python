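"""Physics-based synthetic experiments ("phantoms") for electrolytic ablation.

A phantom emulates one ablation in a buffered cell-encapsulation dish:

* a constant applied potential drives a current set by a buffer-dependent
  resistance; the charge delivered over 90 s at 10 V in the 10 mM baseline
  integrates to 0.726 C (the calibration anchor);
* electrolysis converts that charge stoichiometrically into hydroxide at the
  cathode (2H₂O + 2e⁻ → H₂ + 2OH⁻) and hydronium at the anode
  (6H₂O → 4H₃O⁺ + O₂ + 4e⁻) — one mole of acid or base per mole of
  electrons at unit Faradaic efficiency;
* the electrogenerated species spread as Gaussian areal deposits around each
  electrode and are titrated against a monoprotic HEPES-like buffer to give
  a pH field;
* a two-electrode logarithmic line-source potential gives the voltage field
  (only a small fraction of the applied 10 V drops across the gel);
* cells die where pH exceeds the viability window, rendered as a two-channel
  live/dead (green/red) image with seeded noise.

Everything is a pure function of (config, seed), so every downstream stage
of the analysis can be tested without any experimental download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .electro import CurrentTrace, total_charge
from .errors import ConfigurationError, DomainError, NumericsError, ValidationError
from .fields import FieldSamples, MeasurementGrid
from .viability import ViabilityImage

__all__ = [
    "Electrode",
    "ResistanceModel",
    "PhantomConfig",
    "ScalarField2D",
    "default_config",
    "generate_current_trace",
    "electrolysis_moles",
    "buffer_ph",
    "generate_ph_field",
    "generate_voltage_field",
    "generate_temperature_field",
    "default_measurement_grid",
    "sample_field",
    "render_viability_image",
]

FARADAY_C_PER_MOL = 96485.0

#: intensity levels (16-bit scale) of the bright vs dim reporter channel
CHANNEL_HIGH = 45000.0
CHANNEL_LOW = 5000.0
INTENSITY_MAX = 65535.0


@dataclass(frozen=True)
class Electrode:
    """A needle electrode: position (mm), polarity, and radius (mm)."""

    x: float
    y: float
    polarity: str
    radius: float = 0.25

    def __post_init__(self):
        object.__setattr__(self, "x", float(self.x))
        object.__setattr__(self, "y", float(self.y))
        object.__setattr__(self, "radius", float(self.radius))
        if self.polarity not in ("anode", "cathode"):
            raise ConfigurationError(f"unknown polarity {self.polarity!r}")
        if self.radius <= 0:
            raise ConfigurationError("electrode radius must be positive")

    @property
    def position(self):
        return (self.x, self.y)


@dataclass(frozen=True)
class ResistanceModel:
    """Apparent dish resistance as a function of buffer concentration.

    R(B) = r_ref * (1 + k * (B - b_ref)) ohms.  The reference resistance is
    calibrated so the baseline trace (10 V, 90 s, 10 mM) integrates to
    0.726 C; the slope makes charge decrease as buffering increases while
    every standard HEPES condition keeps a measurable ablation zone.
    """

    r_ref: float = 900.0 / 0.726  # ohms at b_ref; 10 V * 90 s / 0.726 C
    b_ref: float = 0.010  # mol/L
    k: float = 3.0  # L/mol

    def ohms(self, buffer_total: float) -> float:
        r = self.r_ref * (1.0 + self.k * (buffer_total - self.b_ref))
        if r <= 0:
            raise ConfigurationError(
                f"resistance model yields non-positive R={r:.3g} ohm "
                f"at buffer_total={buffer_total}"
            )
        return r


def _default_electrodes():
    # cathode left, anode right, 1.5 cm apart, centered in the dish
    return (
        Electrode(-7.5, 0.0, "cathode"),
        Electrode(7.5, 0.0, "anode"),
    )


@dataclass(frozen=True)
class PhantomConfig:
    """Full generative description of one synthetic ablation experiment."""

    electrodes: tuple = field(default_factory=_default_electrodes)
    applied_voltage: float = 10.0  # V
    duration: float = 90.0  # s
    sample_interval: float = 10.0  # s
    dish_radius: float = 30.0  # mm (6 cm dish)
    gel_thickness: float = 1.5  # mm (4 mL in a 6 cm dish)
    buffer_total: float = 0.010  # mol/L HEPES
    buffer_pKa: float = 7.48
    initial_pH: float = 7.4
    Kw: float = 1e-14  # mol^2/L^2
    faraday: float = FARADAY_C_PER_MOL  # C/mol
    spread_sigma: float = 2.0  # mm, Gaussian spread of electrogenerated species
    diffusivity: float = 0.3  # mm^2/min, effective post-ablation spreading
    post_diffusion_min: float = 0.0  # minutes
    death_pH_low: float = 4.8
    death_pH_high: float = 10.6
    resistance_model: ResistanceModel = field(default_factory=ResistanceModel)
    gel_voltage_fraction: float = 0.02  # fraction of applied V across the gel
    noise_sd_pH: float = 0.1
    noise_sd_volt: float = 0.001  # V
    noise_sd_current: float = 0.0002  # A, per-sample meter noise
    resistance_noise_frac: float = 0.05  # between-assay resistance variability
    image_noise_sd: float = 0.02  # fraction of the 16-bit intensity range
    pixel_size: float = 50.0  # µm
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "electrodes", tuple(self.electrodes))
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.buffer_total < 0:
            raise ConfigurationError("buffer_total must be non-negative")
        if not (self.death_pH_low < self.initial_pH < self.death_pH_high):
            raise ConfigurationError(
                "death thresholds must bracket the initial pH"
            )
        pol = [e.polarity for e in self.electrodes]
        if pol.count("anode") < 1 or pol.count("cathode") < 1:
            raise ConfigurationError("need at least one anode and one cathode")
        for e in self.electrodes:
            if math.hypot(e.x, e.y) + e.radius > self.dish_radius:
                raise ConfigurationError(
                    f"electrode at ({e.x}, {e.y}) lies outside the dish"
                )
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")

    def without_noise(self) -> "PhantomConfig":
        """Copy of the config with every noise scale set to zero."""
        return replace(
            self, noise_sd_pH=0.0, noise_sd_volt=0.0, noise_sd_current=0.0,
            resistance_noise_frac=0.0, image_noise_sd=0.0,
        )

    def anodes(self):
        return tuple(e for e in self.electrodes if e.polarity == "anode")

    def cathodes(self):
        return tuple(e for e in self.electrodes if e.polarity == "cathode")

    def electrode_midpoint(self):
        """Midpoint between the mean anode and mean cathode positions."""
        a = np.mean([[e.x, e.y] for e in self.anodes()], axis=0)
        c = np.mean([[e.x, e.y] for e in self.cathodes()], axis=0)
        return tuple(0.5 * (a + c))


def default_config(**overrides) -> PhantomConfig:
    """The baseline condition: 10 V, 90 s, 10 mM HEPES, 1.5 cm spacing."""
    return PhantomConfig(**overrides)


@dataclass(frozen=True)
class ScalarField2D:
    """Continuous ground-truth field: (x, y) in mm -> scalar value."""

    func: Callable
    quantity: str

    def __call__(self, x, y):
        return self.func(np.asarray(x, dtype=float), np.asarray(y, dtype=float))


# ---------------------------------------------------------------------------
# current and electrolysis


def generate_current_trace(
    config: PhantomConfig, seed: Optional[int] = None
) -> CurrentTrace:
    """Constant-resistance current trace sampled every ``sample_interval`` s.

    I(t) = V / R(buffer_total), with two seeded noise sources: a per-assay
    multiplicative resistance factor (``resistance_noise_frac``, emulating
    the dish-to-dish scatter of delivered charge) and per-sample additive
    meter noise (``noise_sd_current``).  With noise off, the default
    resistance model makes the baseline trace integrate to exactly 0.726 C.
    """
    n_steps = config.duration / config.sample_interval
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ConfigurationError("duration must be divisible by sample_interval")
    r = config.resistance_model.ohms(config.buffer_total)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if config.resistance_noise_frac > 0:
        r = r * max(1.0 + rng.normal(0.0, config.resistance_noise_frac), 0.1)
    times = config.sample_interval * np.arange(int(round(n_steps)) + 1)
    currents = np.full_like(times, config.applied_voltage / r, dtype=float)
    if config.noise_sd_current > 0:
        currents = currents + rng.normal(0.0, config.noise_sd_current, currents.shape)
    return CurrentTrace(times=times, currents=currents)


def electrolysis_moles(charge: float, faraday: float = FARADAY_C_PER_MOL) -> tuple:
    """Moles of OH⁻ (cathode) and H₃O⁺ (anode) produced by ``charge`` coulombs.

    Both half-reactions yield one mole of hydroxide/hydronium per mole of
    electrons, so each equals Q / F (unit Faradaic efficiency).
    """
    if charge < 0:
        raise DomainError("charge must be non-negative")
    n = charge / faraday
    return (n, n)


# ---------------------------------------------------------------------------
# buffer titration


def buffer_ph(
    net_strong_acid,
    buffer_total: float = 0.010,
    pKa: float = 7.48,
    initial_pH: float = 7.4,
    Kw: float = 1e-14,
    tol: float = 1e-6,
):
    """pH of a monoprotic buffer after adding net strong acid (mol/L, signed).

    Positive values add hydronium, negative add hydroxide.  The buffer is
    initialized at ``initial_pH`` (its counter-ion content is whatever makes
    that so); the perturbed pH solves the electroneutrality condition

        [H+] + b0 - n = Kw/[H+] + B*Ka/(Ka + [H+])

    by bisection on pH in [0, 14] to ``tol``.  Monotone non-increasing in the
    net strong acid.  Accepts scalars or arrays.
    """
    n = np.asarray(net_strong_acid, dtype=float)
    scalar = n.ndim == 0
    n = np.atleast_1d(n)
    if buffer_total < 0:
        raise DomainError("buffer_total must be non-negative")
    if np.any(np.abs(n) >= 10.0):
        raise DomainError("|net_strong_acid| must be below 10 mol/L")
    Ka = 10.0 ** (-pKa)
    h0 = 10.0 ** (-initial_pH)
    b0 = Kw / h0 + buffer_total * Ka / (Ka + h0) - h0

    def residual(ph):
        h = 10.0 ** (-ph)
        return h + b0 - n - Kw / h - buffer_total * Ka / (Ka + h)

    lo = np.zeros_like(n)
    hi = np.full_like(n, 14.0)
    r_lo = residual(lo)
    r_hi = residual(hi)
    # residual decreases with pH: need r(0) >= 0 >= r(14)
    if np.any(r_lo < 0) or np.any(r_hi > 0):
        bad = n[(r_lo < 0) | (r_hi > 0)]
        raise NumericsError(
            f"bisection bracket failure on pH in [0, 14] for net strong acid "
            f"loads like {bad.ravel()[:3]} (buffer_total={buffer_total}, "
            f"pKa={pKa}, initial_pH={initial_pH})"
        )
    n_iter = int(np.ceil(np.log2(14.0 / tol))) + 1
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        r_mid = residual(mid)
        take_hi = r_mid >= 0  # root is at higher pH
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    out = 0.5 * (lo + hi)
    return float(out[0]) if scalar else out.reshape(np.shape(net_strong_acid))


# ---------------------------------------------------------------------------
# ground-truth fields


def _effective_sigma2(config: PhantomConfig) -> float:
    """Gaussian variance after optional post-ablation diffusion, mm²."""
    return config.spread_sigma**2 + 2.0 * config.diffusivity * config.post_diffusion_min


def generate_ph_field(config: PhantomConfig, trace: CurrentTrace) -> ScalarField2D:
    """Buffered pH field from Gaussian acid/base deposits at the electrodes.

    The trace's total charge is converted to moles via Faraday's law, split
    evenly among same-polarity electrodes, spread as a 2D Gaussian areal
    deposit (sigma from config, widened by 2*D*t if post-ablation diffusion
    is requested), converted to a volume concentration through the gel
    thickness, summed with sign (anode acid positive, cathode base negative)
    and titrated against the buffer.
    """
    q = total_charge(trace)
    if q < 0:
        raise DomainError("trace integrates to negative charge")
    oh_mol, h3o_mol = electrolysis_moles(q, config.faraday)
    sigma2 = _effective_sigma2(config)
    sources = []  # (x, y, signed moles)
    anodes, cathodes = config.anodes(), config.cathodes()
    for e in anodes:
        sources.append((e.x, e.y, +h3o_mol / len(anodes)))
    for e in cathodes:
        sources.append((e.x, e.y, -oh_mol / len(cathodes)))

    def net_strong_acid(x, y):
        net = np.zeros(np.broadcast(x, y).shape, dtype=float)
        for ex, ey, moles in sources:
            r2 = (x - ex) ** 2 + (y - ey) ** 2
            areal = moles / (2.0 * np.pi * sigma2) * np.exp(-r2 / (2.0 * sigma2))
            # mol/mm^2 -> mol/mm^3 -> mol/L  (1 L = 1e6 mm^3)
            net = net + areal / config.gel_thickness * 1e6
        return net

    def ph(x, y):
        return buffer_ph(
            net_strong_acid(x, y),
            buffer_total=config.buffer_total,
            pKa=config.buffer_pKa,
            initial_pH=config.initial_pH,
            Kw=config.Kw,
        )

    return ScalarField2D(func=ph, quantity="pH")


def generate_voltage_field(config: PhantomConfig) -> ScalarField2D:
    """Two-electrode logarithmic line-source potential in the gel.

    Each electrode contributes a signed -ln(r) term (clamped to its surface
    radius); the superposition is scaled so the anode-surface minus
    cathode-surface difference equals applied_voltage × gel_voltage_fraction
    (most of the applied potential drops at the electrode interfaces), then
    shifted so the field is zero at the anode–cathode midpoint.
    """
    electrodes = config.electrodes

    def raw(x, y):
        out = np.zeros(np.broadcast(x, y).shape, dtype=float)
        for e in electrodes:
            r = np.hypot(x - e.x, y - e.y)
            r = np.maximum(r, e.radius)  # clamp inside the electrode disk
            sign = 1.0 if e.polarity == "anode" else -1.0
            out = out - sign * np.log(r)
        return out

    def surface_value(e: Electrode) -> float:
        # value on the electrode's own surface, towards the dish center
        d = math.hypot(e.x, e.y)
        if d > 0:
            px, py = e.x * (1 - e.radius / d), e.y * (1 - e.radius / d)
        else:
            px, py = e.x + e.radius, e.y
        return float(raw(np.asarray(px), np.asarray(py)))

    v_an = float(np.mean([surface_value(e) for e in config.anodes()]))
    v_ca = float(np.mean([surface_value(e) for e in config.cathodes()]))
    span = v_an - v_ca
    if span <= 0:
        raise ConfigurationError("degenerate electrode layout: zero potential span")
    scale = config.applied_voltage * config.gel_voltage_fraction / span
    mx, my = config.electrode_midpoint()
    offset = float(raw(np.asarray(mx), np.asarray(my))) * scale

    def volts(x, y):
        return raw(x, y) * scale - offset

    return ScalarField2D(func=volts, quantity="volts")


def generate_temperature_field(config: PhantomConfig, celsius: float = 22.0) -> ScalarField2D:
    """Constant room-temperature field — electrolytic ablation is non-thermal."""
    return ScalarField2D(
        func=lambda x, y: np.full(np.broadcast(x, y).shape, celsius, dtype=float),
        quantity="temperature",
    )


# ---------------------------------------------------------------------------
# measurement template and sampling


def default_measurement_grid(config: PhantomConfig) -> MeasurementGrid:
    """The standard 85-site probe template around a two-electrode layout.

    Per electrode, a polar grid of 8 angles × 5 radii (2, 4, 6, 8, 10 mm);
    plus 5 sites along the perpendicular bisector of the electrode pair at
    -10, -5, 0, 5, 10 mm.  The exact paper coordinates are not published;
    this symmetric layout is the package's deterministic stand-in.
    """
    anodes, cathodes = config.anodes(), config.cathodes()
    if len(anodes) != 1 or len(cathodes) != 1:
        raise ConfigurationError(
            "the default measurement grid requires exactly one anode and one cathode"
        )
    cathode, anode = cathodes[0], anodes[0]
    radii = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    angles = np.pi / 4.0 * np.arange(8)
    ids, pts = [], []
    for prefix, e in (("cat", cathode), ("ano", anode)):
        k = 0
        for r in radii:
            for th in angles:
                ids.append(f"{prefix}-{k:02d}")
                pts.append((e.x + r * math.cos(th), e.y + r * math.sin(th)))
                k += 1
    # perpendicular bisector of the electrode axis
    mx, my = config.electrode_midpoint()
    ax = np.array([anode.x - cathode.x, anode.y - cathode.y])
    perp = np.array([-ax[1], ax[0]]) / np.linalg.norm(ax)
    for k, s in enumerate((-10.0, -5.0, 0.0, 5.0, 10.0)):
        ids.append(f"mid-{k:02d}")
        pts.append((mx + s * perp[0], my + s * perp[1]))
    pts = np.array(pts)
    outside = np.hypot(pts[:, 0], pts[:, 1]) > config.dish_radius
    if outside.any():
        raise ConfigurationError(
            f"{int(outside.sum())} measurement sites fall outside the dish"
        )
    return MeasurementGrid(site_ids=tuple(ids), xy=pts)


def sample_field(
    field2d: ScalarField2D,
    grid: MeasurementGrid,
    noise_sd: float,
    replicates: int,
    seed: int,
) -> FieldSamples:
    """Simulated probe measurements: field value plus Gaussian noise per replicate."""
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    truth = np.asarray(field2d(grid.xy[:, 0], grid.xy[:, 1]), dtype=float)
    rows = []
    for rep in range(replicates):
        noise = rng.normal(0.0, noise_sd, truth.shape) if noise_sd > 0 else 0.0
        values = truth + noise
        if field2d.quantity == "pH":
            values = np.clip(values, 0.0, 14.0)
        for sid, v in zip(grid.site_ids, values):
            rows.append((sid, rep, float(v)))
    data = pd.DataFrame(rows, columns=["site_id", "replicate", "value"])
    return FieldSamples(grid=grid, quantity=field2d.quantity, data=data)


# ---------------------------------------------------------------------------
# viability rendering


def render_viability_image(
    ph_field: ScalarField2D, config: PhantomConfig, seed: Optional[int] = None
) -> ViabilityImage:
    """Render a two-channel live/dead image of the dish from a pH field.

    Dead pixels (pH outside [death_pH_low, death_pH_high]) are red-high /
    green-low, live pixels the opposite, with seeded Gaussian channel noise.
    Pixel (0, 0) is the top-left corner of the dish bounding box; the world
    transform maps pixel centers so x = x_min + (col + 0.5) * pixel size.
    """
    px_mm = config.pixel_size * 1e-3
    r = config.dish_radius
    n = int(math.ceil(2.0 * r / px_mm))
    corner = (-r, -r)
    cols = corner[0] + (np.arange(n) + 0.5) * px_mm
    rows = corner[1] + (np.arange(n) + 0.5) * px_mm
    X, Y = np.meshgrid(cols, rows)
    ph = np.asarray(ph_field(X, Y), dtype=float)
    dead = (ph < config.death_pH_low) | (ph > config.death_pH_high)
    green = np.where(dead, CHANNEL_LOW, CHANNEL_HIGH)
    red = np.where(dead, CHANNEL_HIGH, CHANNEL_LOW)
    if config.image_noise_sd > 0:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        sd = config.image_noise_sd * INTENSITY_MAX
        green = green + rng.normal(0.0, sd, green.shape)
        red = red + rng.normal(0.0, sd, red.shape)
    green = np.clip(green, 0.0, INTENSITY_MAX)
    red = np.clip(red, 0.0, INTENSITY_MAX)
    return ViabilityImage(
        green=green,
        red=red,
        pixel_size_um=config.pixel_size,
        origin_mm=(corner[0] + 0.5 * px_mm, corner[1] + 0.5 * px_mm),
    )
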