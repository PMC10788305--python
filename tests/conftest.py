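import numpy as np
import pytest

from psgkit import (
    EventSpec, SubjectProfile, synthesize_record, epoch_record,
)
from psgkit.hypnogram import Hypnogram

FS = 200.0


def n2_hypnogram(n_epochs: int) -> Hypnogram:
    return Hypnogram(np.array(["N2"] * n_epochs, dtype=object))


@pytest.fixture(scope="session")
def spindle_record():
    """20 min of N2 with 2/min fast spindles on C3 (single channel)."""
    hyp = n2_hypnogram(40)
    spec = EventSpec("fast_spindle", density=2.0, amplitude=30.0,
                     duration=1.0, frequency=15.0, channels=("C3",))
    rec, gt = synthesize_record(SubjectProfile("s", 10.0), hyp, [spec],
                                fs=FS, seed=42, channels=["C3"])
    return rec, gt, hyp


@pytest.fixture(scope="session")
def so_record():
    """30 min of N2 with implanted SOs on C3 (single channel)."""
    hyp = n2_hypnogram(60)
    spec = EventSpec("so", density=6.0, amplitude=80.0, p2p=130.0,
                     duration=1.2, channels=("C3",))
    rec, gt = synthesize_record(SubjectProfile("s", 6.0), hyp, [spec],
                                fs=FS, seed=7, channels=["C3"])
    return rec, gt, hyp


@pytest.fixture(scope="session")
def coupled_record():
    """N2 with SOs and kappa=20-coupled fast spindles at 0 deg on C3."""
    hyp = n2_hypnogram(40)
    specs = [
        EventSpec("so", density=6.0, amplitude=80.0, p2p=130.0,
                  duration=1.2, channels=("C3",)),
        EventSpec("fast_spindle", density=2.0, amplitude=30.0, duration=1.0,
                  frequency=15.0, coupling_phase=0.0, coupling_kappa=20.0,
                  channels=("C3",)),
    ]
    rec, gt = synthesize_record(SubjectProfile("s", 8.0), hyp, specs,
                                fs=FS, seed=5, channels=["C3"])
    return rec, gt, hyp


@pytest.fixture(scope="session")
def full_record():
    """Short multichannel record with mastoids, spindles and SOs."""
    hyp = n2_hypnogram(20)
    specs = [
        EventSpec("so", density=5.0, amplitude=80.0, p2p=130.0, duration=1.2),
        EventSpec("fast_spindle", density=2.0),
        EventSpec("slow_spindle", density=2.0, frequency=11.0),
    ]
    rec, gt = synthesize_record(SubjectProfile("s", 9.0), hyp, specs,
                                fs=FS, seed=11)
    return rec, gt, hyp
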