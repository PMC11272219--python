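import numpy as np
import pytest

import bootsfx as bx
from bootsfx.synthetic import make_two_state_models

D_MIN = 2.5
F_TRUE = 0.27


@pytest.fixture(scope="session")
def toy_models():
    """Matched dark/light toy models (no transient water)."""
    return make_two_state_models(seed=7, transient_water=False)


@pytest.fixture(scope="session")
def toy_sf(toy_models):
    """Ground-truth structure factors: dark, light, coherent mix at f_true."""
    dark, light = toy_models
    F_dark = bx.structure_factors(dark, D_MIN, role="reference")
    F_light = bx.structure_factors(light, D_MIN, role="activated")
    F_mix = bx.mix_states(F_dark, F_light, F_TRUE)
    return F_dark, F_light, F_mix


@pytest.fixture(scope="session")
def toy_obs(toy_models, toy_sf):
    """Amplitude-only observation sets (mix as 'light data', dark reference)."""
    dark, _ = toy_models
    F_dark, _, F_mix = toy_sf
    obs = bx.ReflectionSet(
        hkl=F_mix.hkl, amplitude=F_mix.amplitude, cell=dark.cell, d_min=D_MIN,
        role="activated",
    )
    ref = bx.ReflectionSet(
        hkl=F_dark.hkl, amplitude=F_dark.amplitude, cell=dark.cell, d_min=D_MIN,
        role="reference",
    )
    return obs, ref


def random_reflections(rng, n=40, with_sigma=True, cell=None):
    """Small random amplitude table on a fixed hkl grid."""
    hkl = []
    for h in range(1, 5):
        for k in range(-3, 4):
            for l in range(-3, 4):
                hkl.append((h, k, l))
    hkl = np.array(hkl[:n])
    amp = rng.uniform(1.0, 100.0, size=len(hkl))
    sig = rng.uniform(0.1, 5.0, size=len(hkl)) if with_sigma else None
    return bx.ReflectionSet(hkl=hkl, amplitude=amp, sigma=sig, cell=cell)
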