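"""Synthetic-experiment generator: electrochemistry, fields, sampling, rendering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist

from electroablate import (
    ConfigurationError,
    DomainError,
    Electrode,
    PhantomConfig,
    ResistanceModel,
    ScalarField2D,
    buffer_ph,
    default_config,
    default_measurement_grid,
    electrolysis_moles,
    generate_current_trace,
    generate_ph_field,
    generate_voltage_field,
    render_viability_image,
    sample_field,
    segment_dead,
    total_charge,
)

FARADAY = 96485.0


# ---------------------------------------------------------------------------
# current trace


def test_baseline_trace_integrates_to_calibration_charge():
    """10 V / 90 s / 10 mM with the default resistance model delivers 0.726 C."""
    trace = generate_current_trace(default_config().without_noise())
    assert trace.times[0] == 0.0 and trace.times[-1] == 90.0
    assert np.allclose(np.diff(trace.times), 10.0)
    assert total_charge(trace) == pytest.approx(0.726, abs=1e-9)


def test_zero_voltage_trace_has_zero_charge():
    cfg = default_config(applied_voltage=0.0).without_noise()
    trace = generate_current_trace(cfg)
    assert np.all(trace.currents == 0.0)
    assert total_charge(trace) == 0.0


def test_constant_resistance_closed_form_charge():
    """Q = V t / R for a constant 1250-ohm load: 10 V x 90 s -> 0.720 C."""
    cfg = default_config(resistance_model=ResistanceModel(r_ref=1250.0, k=0.0))
    trace = generate_current_trace(cfg.without_noise())
    assert total_charge(trace) == pytest.approx(0.720, abs=1e-12)


def test_trace_requires_divisible_duration():
    with pytest.raises(ConfigurationError):
        generate_current_trace(default_config(duration=85.0))


def test_nonpositive_resistance_is_a_configuration_error():
    cfg = default_config(resistance_model=ResistanceModel(r_ref=100.0, k=-600.0),
                         buffer_total=0.2)
    with pytest.raises(ConfigurationError):
        generate_current_trace(cfg)


def test_total_charge_decreases_with_buffer_concentration():
    charges = []
    for b in (0.010, 0.050, 0.200):
        cfg = default_config(buffer_total=b).without_noise()
        charges.append(total_charge(generate_current_trace(cfg)))
    assert charges[0] > charges[1] > charges[2]


# ---------------------------------------------------------------------------
# electrolysis stoichiometry


@pytest.mark.parametrize(
    "charge, expected",
    [(0.726, 0.726 / FARADAY), (0.0, 0.0), (FARADAY, 1.0)],
)
def test_electrolysis_moles_faraday_law(charge, expected):
    oh, h3o = electrolysis_moles(charge)
    assert oh == pytest.approx(expected, abs=1e-15)
    assert h3o == pytest.approx(expected, abs=1e-15)


def test_electrolysis_rejects_negative_charge():
    with pytest.raises(DomainError):
        electrolysis_moles(-1.0)


# ---------------------------------------------------------------------------
# buffer titration


def test_buffer_ph_no_addition_returns_initial_ph():
    assert buffer_ph(0.0) == pytest.approx(7.4, abs=1e-4)


def test_buffer_ph_matches_henderson_hasselbalch_for_small_base_addition():
    """Adding 2 mM OH- to 10 mM buffer: HH predicts ~7.76."""
    f0 = 1.0 / (1.0 + 10 ** (7.4 - 7.48))  # protonated fraction at pH 7.4
    prot, deprot = 0.010 * f0, 0.010 * (1 - f0)
    hh = 7.48 + math.log10((deprot + 0.002) / (prot - 0.002))
    assert buffer_ph(-0.002) == pytest.approx(hh, abs=0.01)
    assert hh == pytest.approx(7.76, abs=0.01)


def test_buffer_ph_strong_base_excess_limit():
    """OH- beyond the protonated pool by 1 mM leaves pOH ~ 3, pH ~ 11."""
    f0 = 1.0 / (1.0 + 10 ** (7.4 - 7.48))
    load = -(0.010 * f0 + 0.001)
    assert buffer_ph(load) == pytest.approx(11.0, abs=0.05)


def test_buffer_ph_rejects_extreme_loads():
    with pytest.raises(DomainError):
        buffer_ph(10.0)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    b=st.floats(0.0, 0.5),
    pka=st.floats(6.0, 9.0),
    n1=st.floats(-0.5, 0.5),
    n2=st.floats(-0.5, 0.5),
)
def test_buffer_ph_monotone_nonincreasing_in_acid_load(b, pka, n1, n2):
    lo, hi = min(n1, n2), max(n1, n2)
    assert buffer_ph(lo, buffer_total=b, pKa=pka) >= buffer_ph(
        hi, buffer_total=b, pKa=pka
    ) - 1e-6


@pytest.mark.parametrize("load", [0.005, -0.005])
def test_ph_excursion_shrinks_with_buffer_capacity(load):
    excursions = [
        abs(buffer_ph(load, buffer_total=b) - 7.4)
        for b in (0.001, 0.010, 0.050, 0.200)
    ]
    assert all(a >= b - 1e-9 for a, b in zip(excursions, excursions[1:]))


# ---------------------------------------------------------------------------
# ground-truth fields


def _threshold_area(field, cfg, spacing=0.2):
    xs = np.arange(-cfg.dish_radius, cfg.dish_radius, spacing)
    X, Y = np.meshgrid(xs, xs)
    ph = field(X, Y)
    dead = (ph < cfg.death_pH_low) | (ph > cfg.death_pH_high)
    return dead.sum() * spacing**2


def test_ph_field_is_flat_without_charge():
    cfg = default_config(applied_voltage=0.0).without_noise()
    field = generate_ph_field(cfg, generate_current_trace(cfg))
    pts = field(np.array([-7.5, 0.0, 7.5]), np.array([0.0, 3.0, 0.0]))
    assert np.allclose(pts, 7.4, atol=1e-4)


def test_ph_field_exceeds_death_thresholds_at_electrodes():
    cfg = default_config().without_noise()
    field = generate_ph_field(cfg, generate_current_trace(cfg))
    assert field(-7.5, 0.0) > cfg.death_pH_high  # cathode: basic
    assert field(7.5, 0.0) < cfg.death_pH_low  # anode: acidic


def test_post_diffusion_expands_lethal_area():
    cfg0 = default_config().without_noise()
    cfg60 = default_config(post_diffusion_min=60.0).without_noise()
    f0 = generate_ph_field(cfg0, generate_current_trace(cfg0))
    f60 = generate_ph_field(cfg60, generate_current_trace(cfg60))
    assert _threshold_area(f60, cfg60) > _threshold_area(f0, cfg0)


def test_voltage_field_zero_at_midpoint_and_antisymmetric():
    field = generate_voltage_field(default_config())
    assert field(0.0, 0.0) == pytest.approx(0.0, abs=1e-12)
    x = np.array([1.0, 3.0, 5.5, -2.0])
    y = np.array([0.0, 2.0, -4.0, 7.0])
    assert np.allclose(field(x, y), -field(-x, y), atol=1e-12)


def test_voltage_field_gradients_stay_far_below_electroporation():
    """|grad V| x 14.2 um never approaches the 1 V electroporation threshold."""
    cfg = default_config()
    field = generate_voltage_field(cfg)
    xs = np.arange(-20.0, 20.0, 0.05)
    X, Y = np.meshgrid(xs, xs)
    v = field(X, Y)
    gy, gx = np.gradient(v, 0.05)
    tmp = np.hypot(gx, gy) * 14.2e-3  # V/mm * mm
    assert tmp.max() < 1.0


# ---------------------------------------------------------------------------
# measurement template and sampling


def test_default_grid_has_85_sites_including_the_midpoint():
    grid = default_measurement_grid(default_config())
    assert len(grid) == 85
    assert any(np.allclose(p, (0.0, 0.0), atol=1e-12) for p in grid.xy)


def test_default_grid_sites_are_separated():
    grid = default_measurement_grid(default_config())
    assert pdist(grid.xy).min() >= 0.5 - 1e-9


def test_default_grid_requires_two_electrode_layout():
    cfg = default_config(
        electrodes=(
            Electrode(-7.5, 0.0, "cathode"),
            Electrode(0.0, 5.0, "cathode"),
            Electrode(7.5, 0.0, "anode"),
        )
    )
    with pytest.raises(ConfigurationError):
        default_measurement_grid(cfg)


def test_sample_field_noiseless_equals_truth_and_is_deterministic():
    cfg = default_config()
    grid = default_measurement_grid(cfg)
    field = generate_voltage_field(cfg)
    exact = sample_field(field, grid, noise_sd=0.0, replicates=2, seed=5)
    truth = field(grid.xy[:, 0], grid.xy[:, 1])
    assert np.allclose(exact.data["value"].to_numpy().reshape(2, -1)[0], truth)
    a = sample_field(field, grid, noise_sd=0.05, replicates=3, seed=9)
    b = sample_field(field, grid, noise_sd=0.05, replicates=3, seed=9)
    pd.testing.assert_frame_equal(a.data, b.data, check_exact=True)


def test_sample_field_noise_scale_is_calibrated():
    cfg = default_config()
    grid = default_measurement_grid(cfg)
    field = generate_voltage_field(cfg)
    samples = sample_field(field, grid, noise_sd=0.1, replicates=1000, seed=2)
    one_site = samples.data[samples.data["site_id"] == grid.site_ids[0]]["value"]
    sd = one_site.std(ddof=1)
    assert abs(sd - 0.1) < 0.01  # chi-square bound at n=1000


# ---------------------------------------------------------------------------
# viability rendering


def _uniform_field(value):
    return ScalarField2D(
        func=lambda x, y: np.full(np.broadcast(x, y).shape, float(value)), quantity="pH"
    )


def test_uniform_physiologic_ph_renders_no_dead_pixels():
    cfg = default_config(dish_radius=10.0, electrodes=(
        Electrode(-4.0, 0.0, "cathode"), Electrode(4.0, 0.0, "anode"))).without_noise()
    img = render_viability_image(_uniform_field(7.4), cfg)
    zones = segment_dead(img, cfg.electrodes, red_thresh=20000, green_thresh=20000)
    assert zones == []


def test_uniform_lethal_ph_renders_all_dead():
    cfg = default_config(dish_radius=10.0, electrodes=(
        Electrode(-4.0, 0.0, "cathode"), Electrode(4.0, 0.0, "anode"))).without_noise()
    img = render_viability_image(_uniform_field(12.0), cfg)
    zones = segment_dead(img, cfg.electrodes, red_thresh=20000, green_thresh=20000,
                         split_merged=False)
    assert len(zones) == 1
    assert zones[0].mask.sum() == img.green.size


def test_default_phantom_renders_one_dead_zone_per_electrode(preset_analyses):
    zones = preset_analyses["baseline"].zones
    assert len(zones) == 2
    assert sorted(z.electrode_label for z in zones) == ["anode", "cathode"]


def test_generation_is_a_pure_function_of_config_and_seed():
    cfg = PhantomConfig(
        electrodes=(Electrode(-4.0, 0.0, "cathode"), Electrode(4.0, 0.0, "anode")),
        dish_radius=12.0,
        seed=21,
    )
    t1 = generate_current_trace(cfg)
    t2 = generate_current_trace(cfg)
    assert np.array_equal(t1.currents, t2.currents)
    field = generate_ph_field(cfg, t1)
    i1 = render_viability_image(field, cfg)
    i2 = render_viability_image(field, cfg)
    assert np.array_equal(i1.green, i2.green) and np.array_equal(i1.red, i2.red)
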