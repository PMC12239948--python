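"""Shared synthetic fixtures; everything is generated at test time."""
import numpy as np
import pytest

from sarcotrace import metrics, synthdata, zdisc


@pytest.fixture(scope="session")
def small_stack():
    """Noiseless 2-myofibril × 6-sarcomere stack with ground truth."""
    return synthdata.make_flight_stack(
        n_myofibrils=2, n_sarcomeres=6, sarcomere_length=2.0,
        noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_stack():
    """3 myofibrils × 30 sarcomeres at peak SNR ≈ 18 (noise sd 0.02)."""
    return synthdata.make_flight_stack(
        n_myofibrils=3, n_sarcomeres=30, sarcomere_length=2.0,
        noise_sd=0.02, seed=1)


@pytest.fixture(scope="session")
def noisy_detection(noisy_stack):
    """Z-discs detected on the noisy stack plus their ground-truth match."""
    stack, gt = noisy_stack
    discs = zdisc.detect_zdiscs(stack)
    detected = np.array([[d.x, d.y, d.z] for d in discs])
    match = metrics.match_points(detected, gt.all_zdiscs(), radius=0.5)
    return stack, gt, discs, match
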