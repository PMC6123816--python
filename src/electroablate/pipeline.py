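"""End-to-end orchestration: phantom -> fields -> electro -> viability -> stats.

`analyze_phantom` runs the whole analysis in memory and returns both the
intermediate objects and a JSON-ready summary; `run_pipeline` is the
file-based variant with re-runnable stages and a manifest; `run_study` runs
several buffering conditions with replicates and applies the statistics
(ANOVA across conditions, pairwise Welch tests with Bonferroni adjustment,
and the threshold table pooling the per-condition viability-boundary pHs).
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as eio
from .electro import (
    electroporation_report,
    mean_impedance,
    total_charge,
    transmembrane_field,
)
from .errors import ValidationError
from .fields import (
    aggregate_replicates,
    extract_contours,
    interpolate_scattered,
    rasterize,
    recenter_voltage,
)
from .phantom import (
    Electrode,
    PhantomConfig,
    default_config,
    default_measurement_grid,
    generate_current_trace,
    generate_ph_field,
    generate_voltage_field,
    render_viability_image,
    sample_field,
)
from .stats import bonferroni, one_way_anova, summarize, welch_t
from .viability import boundary_ph, boundary_points, fit_ellipse, segment_dead

__all__ = [
    "SCENARIOS",
    "scenario_config",
    "AnalysisResult",
    "analyze_phantom",
    "RunManifest",
    "run_pipeline",
    "run_study",
    "STAGES",
]

__version__ = "0.1.0"

#: number of probe replicates per site (pH sampled at least twice,
#: voltage at least four times)
PH_REPLICATES = 2
VOLT_REPLICATES = 4

#: raster cell sizes, mm: the reconstruction raster and the fine raster of
#: the phantom's generative pH field used for boundary-pH extraction
RASTER_SPACING = 0.1
TRUTH_SPACING = 0.02


def _multicathode_electrodes():
    ring = [
        Electrode(10.0 * np.cos(t), 10.0 * np.sin(t), "cathode")
        for t in 2.0 * np.pi * np.arange(8) / 8.0
    ]
    return tuple([Electrode(0.0, 0.0, "anode")] + ring)


SCENARIOS = {
    "baseline": {},
    "hepes50": {"buffer_total": 0.050},
    "hepes200": {"buffer_total": 0.200},
    "diffusion60": {"post_diffusion_min": 60.0},
    "multicathode": {"electrodes": _multicathode_electrodes(), "duration": 10.0},
}


def scenario_config(name: str, seed: int = 0, noise: bool = True) -> PhantomConfig:
    if name not in SCENARIOS:
        raise ValidationError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        )
    cfg = default_config(seed=seed, **SCENARIOS[name])
    return cfg if noise else cfg.without_noise()


def _stage_seeds(config: PhantomConfig) -> dict:
    """Deterministic per-stage substream seeds derived from the config seed."""
    state = np.random.SeedSequence(int(config.seed)).generate_state(4)
    return {
        "trace": int(state[0]),
        "ph": int(state[1]),
        "volt": int(state[2]),
        "image": int(state[3]),
    }


@dataclass
class AnalysisResult:
    """All intermediates of one phantom analysis plus the JSON-ready summary."""

    config: PhantomConfig
    trace: object
    ph_field: object
    voltage_field: object
    image: object
    zones: list
    summary: dict
    ph_raster: object = None
    voltage_raster: object = None
    tmp: object = None
    report: object = None
    contours: dict = field(default_factory=dict)


def _zone_summary(zone, ell, bph_field, bph_measured) -> dict:
    out = {
        "electrode_label": zone.electrode_label,
        "electrode_index": zone.electrode_index,
        "area_mm2": zone.area_mm2,
        "centroid_mm": list(zone.centroid_mm),
        "ellipse": {
            "center_mm": list(ell.center),
            "semi_major_mm": ell.semi_major,
            "semi_minor_mm": ell.semi_minor,
            "rotation_rad": ell.rotation,
        },
        "boundary_ph_field": None,
        "boundary_ph_measured": None,
    }
    if bph_field is not None:
        out["boundary_ph_field"] = {
            "mean": bph_field.mean, "sd": bph_field.sd, "n_valid": bph_field.n_valid,
        }
    if bph_measured is not None:
        out["boundary_ph_measured"] = {
            "mean": bph_measured.mean, "sd": bph_measured.sd,
            "n_valid": bph_measured.n_valid,
        }
    return out


def analyze_phantom(
    config: PhantomConfig,
    raster_spacing: float = RASTER_SPACING,
    truth_spacing: float = TRUTH_SPACING,
) -> AnalysisResult:
    """Generate a phantom and run every analysis stage on it in memory.

    The scattered-measurement reconstruction (and hence the TMP report and
    the measured boundary pH) requires the standard two-electrode layout;
    for other layouts those entries are None.  Each dead zone's boundary pH
    is reported twice: sampled on a fine raster of the generative pH field
    (``boundary_ph_field``) and on the 85-site reconstruction
    (``boundary_ph_measured``).
    """
    seeds = _stage_seeds(config)
    trace = generate_current_trace(config, seed=seeds["trace"])
    charge = total_charge(trace)
    impedance = mean_impedance(trace, config.applied_voltage)
    ph_field = generate_ph_field(config, trace)
    volt_field = generate_voltage_field(config)

    ph_raster = volt_raster = tmp = report = None
    contours = {}
    two_electrode = len(config.anodes()) == 1 and len(config.cathodes()) == 1
    if two_electrode:
        grid = default_measurement_grid(config)
        ph_samples = sample_field(
            ph_field, grid, config.noise_sd_pH, PH_REPLICATES, seeds["ph"]
        )
        volt_samples = sample_field(
            volt_field, grid, config.noise_sd_volt, VOLT_REPLICATES, seeds["volt"]
        )
        ph_mean = aggregate_replicates(ph_samples, PH_REPLICATES)
        volt_mean = aggregate_replicates(volt_samples, VOLT_REPLICATES)
        signed, _magnitude = recenter_voltage(volt_mean, config.electrode_midpoint())
        ph_raster = interpolate_scattered(ph_mean, spacing=raster_spacing)
        volt_raster = interpolate_scattered(signed, spacing=raster_spacing)
        tmp = transmembrane_field(volt_raster)
        report = electroporation_report(tmp)
        contours = extract_contours(
            ph_raster, [config.death_pH_low, config.death_pH_high]
        )

    image = render_viability_image(ph_field, config, seed=seeds["image"])
    zones = segment_dead(image, config.electrodes)
    zone_summaries = []
    for zone in zones:
        pts = boundary_points(zone)
        ell = fit_ellipse(pts)
        pad = 3.0
        bounds = (
            ell.center[0] - ell.semi_major - pad,
            ell.center[0] + ell.semi_major + pad,
            ell.center[1] - ell.semi_major - pad,
            ell.center[1] + ell.semi_major + pad,
        )
        truth = rasterize(ph_field, bounds, spacing=truth_spacing, quantity="pH")
        bph_field = boundary_ph(ell, truth)
        bph_measured = None
        if ph_raster is not None:
            try:
                bph_measured = boundary_ph(ell, ph_raster)
            except ValidationError:
                bph_measured = None
        zone_summaries.append(_zone_summary(zone, ell, bph_field, bph_measured))

    summary = {
        "charge_C": charge,
        "impedance_ohm": impedance,
        "buffer_total_M": config.buffer_total,
        "tmp_max_V": None if report is None else report.max_tmp_V,
        "tmp_argmax_mm": None if report is None else list(report.argmax_mm),
        "threshold_exceeded": None if report is None else report.exceeded,
        "dead_area_total_mm2": float(sum(z.area_mm2 for z in zones)),
        "dead_area_by_electrode": {
            label: float(
                sum(z.area_mm2 for z in zones if z.electrode_label == label)
            )
            for label in ("cathode", "anode")
        },
        "zones": zone_summaries,
        "seed": int(config.seed),
    }
    return AnalysisResult(
        config=config, trace=trace, ph_field=ph_field, voltage_field=volt_field,
        image=image, zones=zones, summary=summary, ph_raster=ph_raster,
        voltage_raster=volt_raster, tmp=tmp, report=report, contours=contours,
    )


# ---------------------------------------------------------------------------
# file-based staged pipeline

STAGES = ("phantom", "fields", "electro", "viability", "stats")


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    version: str
    stages: dict
    created: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _require(out: Path, names: Sequence[str], stage: str) -> None:
    missing = [str(out / n) for n in names if not (out / n).exists()]
    if missing:
        raise ValidationError(
            f"stage '{stage}' is missing required inputs: {missing}"
        )


def run_pipeline(
    out_dir,
    seed: int = 0,
    config: Optional[PhantomConfig] = None,
    scenario: str = "baseline",
    stages: Sequence[str] = STAGES,
    noise: bool = True,
) -> RunManifest:
    """Run the staged pipeline, writing per-stage artifacts into ``out_dir``.

    Stages not listed are skipped; later stages read the earlier stages'
    files from ``out_dir`` and fail with a ValidationError naming any
    missing input.  Rerunning with the same config and seed reproduces
    byte-identical summary JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in stages:
        if s not in STAGES:
            raise ValidationError(f"unknown stage {s!r}; valid stages: {STAGES}")
    if config is None:
        config = scenario_config(scenario, seed=seed, noise=noise)
    else:
        config = dataclasses.replace(config, seed=seed)
        if not noise:
            config = config.without_noise()
    manifest_stages = {}

    if "phantom" in stages:
        res = analyze_phantom(config)
        eio.write_config(config, out / "config.yaml")
        eio.write_trace(res.trace, out / "trace.csv")
        if res.ph_raster is not None:
            grid = default_measurement_grid(config)
            seeds = _stage_seeds(config)
            ph_samples = sample_field(
                res.ph_field, grid, config.noise_sd_pH, PH_REPLICATES, seeds["ph"]
            )
            volt_samples = sample_field(
                res.voltage_field, grid, config.noise_sd_volt, VOLT_REPLICATES,
                seeds["volt"],
            )
            eio.write_measurements([ph_samples, volt_samples], out / "measurements.csv")
        eio.write_viability_image(
            res.image, out / "viability.tif", out / "viability.json"
        )
        ex = [e.x for e in config.electrodes]
        ey = [e.y for e in config.electrodes]
        pad = 12.0
        truth = rasterize(
            res.ph_field,
            (min(ex) - pad, max(ex) + pad, min(ey) - pad, max(ey) + pad),
            spacing=TRUTH_SPACING,
            quantity="pH",
        )
        eio.write_raster(truth, out / "ph_truth.csv", out / "ph_truth.meta.json")
        manifest_stages["phantom"] = {
            "outputs": [
                "config.yaml", "trace.csv", "measurements.csv",
                "viability.tif", "viability.json", "ph_truth.csv",
                "ph_truth.meta.json",
            ]
        }

    if "fields" in stages:
        _require(out, ["config.yaml", "measurements.csv"], "fields")
        config = eio.read_config(out / "config.yaml")
        samples = eio.read_measurements(out / "measurements.csv")
        ph_mean = aggregate_replicates(samples["pH"], 1)
        volt_mean = aggregate_replicates(samples["volts"], 1)
        signed, _mag = recenter_voltage(volt_mean, config.electrode_midpoint())
        ph_raster = interpolate_scattered(ph_mean, spacing=RASTER_SPACING)
        volt_raster = interpolate_scattered(signed, spacing=RASTER_SPACING)
        eio.write_raster(ph_raster, out / "ph_raster.csv", out / "ph_raster.meta.json")
        eio.write_raster(
            volt_raster, out / "voltage_raster.csv", out / "voltage_raster.meta.json"
        )
        contours = extract_contours(
            ph_raster, [config.death_pH_low, config.death_pH_high]
        )
        eio.write_json(
            {
                str(level): [line.tolist() for line in lines]
                for level, lines in contours.items()
            },
            out / "contours.json",
        )
        manifest_stages["fields"] = {
            "inputs": ["config.yaml", "measurements.csv"],
            "outputs": [
                "ph_raster.csv", "ph_raster.meta.json", "voltage_raster.csv",
                "voltage_raster.meta.json", "contours.json",
            ],
        }

    if "electro" in stages:
        _require(
            out,
            ["config.yaml", "trace.csv", "voltage_raster.csv", "voltage_raster.meta.json"],
            "electro",
        )
        config = eio.read_config(out / "config.yaml")
        trace = eio.read_trace(out / "trace.csv")
        volt_raster = eio.read_raster(
            out / "voltage_raster.csv", out / "voltage_raster.meta.json"
        )
        tmp = transmembrane_field(volt_raster)
        report = electroporation_report(tmp)
        eio.write_json(
            {
                "charge_C": total_charge(trace),
                "impedance_ohm": mean_impedance(trace, config.applied_voltage),
                "tmp_max_V": report.max_tmp_V,
                "tmp_argmax_mm": list(report.argmax_mm),
                "threshold_exceeded": report.exceeded,
                "threshold_V": report.threshold_V,
            },
            out / "electro.json",
        )
        manifest_stages["electro"] = {
            "inputs": ["config.yaml", "trace.csv", "voltage_raster.csv"],
            "outputs": ["electro.json"],
        }

    if "viability" in stages:
        _require(
            out,
            ["config.yaml", "viability.tif", "viability.json", "ph_truth.csv",
             "ph_truth.meta.json"],
            "viability",
        )
        config = eio.read_config(out / "config.yaml")
        image = eio.read_viability_image(out / "viability.tif", out / "viability.json")
        truth = eio.read_raster(out / "ph_truth.csv", out / "ph_truth.meta.json")
        ph_raster = None
        if (out / "ph_raster.csv").exists():
            ph_raster = eio.read_raster(
                out / "ph_raster.csv", out / "ph_raster.meta.json"
            )
        zones = segment_dead(image, config.electrodes)
        zone_summaries = []
        for zone in zones:
            ell = fit_ellipse(boundary_points(zone))
            bph_field = boundary_ph(ell, truth)
            bph_measured = None
            if ph_raster is not None:
                try:
                    bph_measured = boundary_ph(ell, ph_raster)
                except ValidationError:
                    bph_measured = None
            zone_summaries.append(_zone_summary(zone, ell, bph_field, bph_measured))
        eio.write_json(
            {
                "zones": zone_summaries,
                "dead_area_total_mm2": float(sum(z.area_mm2 for z in zones)),
            },
            out / "viability_zones.json",
        )
        manifest_stages["viability"] = {
            "inputs": ["config.yaml", "viability.tif", "ph_truth.csv"],
            "outputs": ["viability_zones.json"],
        }

    if "stats" in stages:
        _require(out, ["viability_zones.json", "electro.json"], "stats")
        zinfo = eio.read_json(out / "viability_zones.json")
        einfo = eio.read_json(out / "electro.json")
        by_label = {"cathode": [], "anode": []}
        for z in zinfo["zones"]:
            if z["boundary_ph_field"] is not None:
                by_label[z["electrode_label"]].append(z["boundary_ph_field"]["mean"])
        summary = {
            "charge_C": einfo["charge_C"],
            "impedance_ohm": einfo["impedance_ohm"],
            "tmp_max_V": einfo["tmp_max_V"],
            "threshold_exceeded": einfo["threshold_exceeded"],
            "dead_area_total_mm2": zinfo["dead_area_total_mm2"],
            "zones": zinfo["zones"],
            "boundary_ph": {
                label: (summarize(vals).mean if vals else None)
                for label, vals in by_label.items()
            },
        }
        eio.write_json(summary, out / "summary.json")
        manifest_stages["stats"] = {
            "inputs": ["viability_zones.json", "electro.json"],
            "outputs": ["summary.json"],
        }

    manifest = RunManifest(
        seed=int(seed),
        config_hash=eio.config_hash(config),
        version=__version__,
        stages=manifest_stages,
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    eio.write_json(manifest.to_dict(), out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# multi-condition study


def run_study(
    scenarios: Sequence[str] = ("baseline", "hepes50", "hepes200"),
    out_dir=None,
    seed: int = 0,
    replicates: int = 4,
    noise: bool = True,
) -> dict:
    """Run several conditions with replicates and apply the statistics.

    Per condition: mean charge, mean total dead area, and the per-electrode
    viability-boundary pH (averaged over replicates).  Across conditions:
    one-way ANOVA on dead areas, pairwise Welch t-tests with Bonferroni
    adjustment, and the pooled threshold table (mean and SD across the
    per-condition boundary pHs, printed at one decimal).
    """
    conditions = {}
    for i, name in enumerate(scenarios):
        reps = []
        for r in range(replicates):
            sub = int(
                np.random.SeedSequence(entropy=int(seed), spawn_key=(i, r))
                .generate_state(1)[0]
            )
            cfg = scenario_config(name, seed=sub, noise=noise)
            reps.append(analyze_phantom(cfg).summary)
        cathode_ph = [
            z["boundary_ph_field"]["mean"]
            for s in reps for z in s["zones"]
            if z["electrode_label"] == "cathode" and z["boundary_ph_field"]
        ]
        anode_ph = [
            z["boundary_ph_field"]["mean"]
            for s in reps for z in s["zones"]
            if z["electrode_label"] == "anode" and z["boundary_ph_field"]
        ]
        conditions[name] = {
            "replicates": reps,
            "charge_C": [s["charge_C"] for s in reps],
            "dead_area_mm2": [s["dead_area_total_mm2"] for s in reps],
            "cathode_boundary_ph": (
                summarize(cathode_ph).mean if cathode_ph else None
            ),
            "anode_boundary_ph": summarize(anode_ph).mean if anode_ph else None,
        }

    study = {"seed": int(seed), "conditions": conditions}
    names = list(scenarios)
    areas = [conditions[n]["dead_area_mm2"] for n in names]
    if len(names) >= 2 and replicates >= 2:
        anova = one_way_anova(areas)
        pairs, raw_p = [], []
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                t = welch_t(areas[a], areas[b])
                pairs.append(
                    {
                        "pair": [names[a], names[b]],
                        "t": t.statistic,
                        "df": t.df,
                        "p": t.p_value,
                    }
                )
                raw_p.append(t.p_value)
        adj = bonferroni(raw_p)
        for pr, ap in zip(pairs, adj):
            pr["p_bonferroni"] = ap
        study["dead_area_stats"] = {
            "anova": {"F": anova.statistic, "df": list(anova.df), "p": anova.p_value},
            "pairwise_welch": pairs,
        }
    cat = [c["cathode_boundary_ph"] for c in conditions.values()
           if c["cathode_boundary_ph"] is not None]
    ano = [c["anode_boundary_ph"] for c in conditions.values()
           if c["anode_boundary_ph"] is not None]
    study["threshold_table"] = {
        "cathode": dataclasses.asdict(summarize(cat, decimals=1)) if cat else None,
        "anode": dataclasses.asdict(summarize(ano, decimals=1)) if ano else None,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        eio.write_json(study, out / "study.json")
    return study
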