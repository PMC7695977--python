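import numpy as np
import pytest

from streamspa import synthetic


@pytest.fixture(scope="session")
def small_movie():
    """8-frame 512^2 movie with planted drift only, SNR 1."""
    truth = synthetic.random_motion_truth(n_frames=8, total_drift=5.0,
                                          seed=11, with_local=False)
    stack = synthetic.make_movie(truth, dims=(512, 512), snr=1.0, seed=11)
    return stack, truth


@pytest.fixture(scope="session")
def noiseless_movie():
    truth = synthetic.random_motion_truth(n_frames=8, total_drift=5.0,
                                          seed=13, with_local=False)
    stack = synthetic.make_movie(truth, dims=(512, 512), snr=None, seed=13)
    return stack, truth


@pytest.fixture(scope="session")
def ctf_fixture():
    """Noiseless 2048^2 Thon-ring micrograph with known astigmatic CTF."""
    from streamspa import ctf
    base = ctf.CtfParams(dfx=1.9, dfy=1.7, ang_ast=30.0, pixel_size=1.0)
    truth = synthetic.CtfGroundTruth(base=base)
    mic = synthetic.make_ctf_micrograph(truth, dims=(2048, 2048), snr=None,
                                        seed=21)
    spectrum = ctf.compute_spectrum(mic, 1.0)
    return mic, spectrum, base


@pytest.fixture(scope="session")
def picking_fixture():
    mic, coords, ref = synthetic.make_picking_micrograph(
        n_particles=30, dims=(1024, 1024), snr=0.3, seed=31, box=48)
    return mic, coords, ref
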