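import numpy as np
import pytest

import ribbonphys as rp
from ribbonphys import vclamp

WT = {"v_half": -29.4, "k": 6.92}
KO = {"v_half": -26.6, "k": 6.98}


@pytest.fixture(scope="session")
def wt_model():
    """WT-like channel scaled so the closed-form peak inward current is 210 pA."""
    base = rp.ChannelModel(g_max=1.0, **WT).with_peak_current(210.0)
    return rp.ChannelModel(g_max=base.g_max, g_leak=2.0, **WT)


@pytest.fixture(scope="session")
def step_protocols():
    return rp.synth.make_step_protocol()


@pytest.fixture(scope="session")
def noiseless_iv(wt_model, step_protocols):
    """Leak-corrected IV of the noiseless WT step family (LJP exercised)."""
    sweeps = [
        vclamp.p4_leak_correct(rp.synth.simulate_current(p, wt_model, 0.0, 0, ljp=17.0))
        for p in step_protocols
    ]
    return vclamp.extract_iv(sweeps, ljp=17.0)


@pytest.fixture(scope="session")
def ramp_pair():
    return rp.synth.make_ramp_pair()


@pytest.fixture(scope="session")
def noiseless_movie(ramp_pair):
    model = rp.ChannelModel(g_max=4.0, v_half=-30.0, k=5.79)
    return rp.synth.simulate_hotspot_movie(ramp_pair, model, noise_sd=0.0, seed=2)


def run_iv_pipeline(model, protocols, noise_sd, rng, ljp=17.0):
    """Simulate -> p/4 -> LJP -> IV -> Boltzmann fit for one cell."""
    sweeps = [
        vclamp.p4_leak_correct(rp.synth.simulate_current(p, model, noise_sd, rng, ljp=ljp))
        for p in protocols
    ]
    return vclamp.fit_activation(vclamp.extract_iv(sweeps, ljp=ljp))


def run_fv_pipeline(movie):
    """dF image -> hotspot -> traces -> merged FV -> staged fit for one AZ."""
    from ribbonphys import imaging

    img = imaging.delta_f_image(movie)
    _, center = imaging.select_hotspot([img])
    trace_a = imaging.extract_trace(movie, center, which="a")
    trace_b = imaging.extract_trace(movie, center, which="b")
    fv = imaging.build_fv(trace_a, trace_b, (movie.ramp_a, movie.ramp_b))
    return imaging.fit_fv(fv), fv
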