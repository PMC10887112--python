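import numpy as np
import pytest

import spheroxi as sx
from spheroxi.presets import untreated_reference_device


@pytest.fixture(scope="session")
def calib():
    """Dye calibration from the 533/381 ns nitrogen/air references."""
    return sx.default_calibration()


def render_uniform_stack(tau_ns, n_steps=16, frequency=250e3, shape=(4, 4)):
    """Noise-free single-timepoint stack of a uniform-lifetime field."""
    acq = sx.AcquisitionConfig(
        modulation_frequency=frequency,
        n_phase_steps=n_steps,
        photon_budget=np.inf,
        read_noise_sd=0.0,
    )
    planes = sx.render_phase_stack(np.full(shape, float(tau_ns)), acq)
    return sx.PhaseStackSeries(
        intensities=planes[None],
        phase_angles=acq.phase_angles,
        modulation_frequency=frequency,
        timepoints=[0.0],
    )


@pytest.fixture(scope="session")
def untreated_device():
    """Simulated six-chamber untreated device (photon budget 1e4, seed 7)."""
    scene, acq, kinetics = untreated_reference_device(seed=7)
    return sx.simulate_device(scene, acq, kinetics, seed=7)


@pytest.fixture(scope="session")
def untreated_chamber_map(untreated_device):
    """Chamber map detected from the device's DC image, occupancy from config."""
    from spheroxi.chambers import detect_chambers

    scene = untreated_device.scene
    dc = untreated_device.stack.intensities[0].mean(axis=0)
    cmap = detect_chambers(dc, scene.chamber_diameter, scene.pixel_size)
    centers = np.asarray(scene.chamber_centers, dtype=float)
    for ch in cmap.chambers:
        dist = np.hypot(*(centers - np.asarray(ch.center)).T)
        ch.occupancy = scene.occupancy[int(np.argmin(dist))]
    cmap.label_image = cmap._render_labels()
    return cmap
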