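import numpy as np
import pytest

from electroablate.pipeline import analyze_phantom, scenario_config

PRESETS = ("baseline", "hepes50", "hepes200")


@pytest.fixture(scope="session")
def preset_analyses():
    """Noise-free end-to-end analyses of the three buffering presets."""
    return {name: analyze_phantom(scenario_config(name, noise=False)) for name in PRESETS}


@pytest.fixture(scope="session")
def noisy_preset_analyses():
    """Default-noise analyses of the three presets under a fixed seed."""
    return {name: analyze_phantom(scenario_config(name, seed=11)) for name in PRESETS}


def zones_by_label(result):
    out = {}
    for z in result.summary["zones"]:
        out.setdefault(z["electrode_label"], []).append(z)
    return out
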