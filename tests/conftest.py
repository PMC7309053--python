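import numpy as np
import pytest

from ecgid import ECGRecord, SegmentationConfig, SynthConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_record():
    return ECGRecord(np.arange(100, dtype=float), 100.0, subject_id="ramp")


@pytest.fixture(scope="session")
def clean_cohort():
    """Six noise-free subjects, 30 s at 360 Hz, with ground-truth R peaks."""
    cfg = SynthConfig(
        num_subjects=6, duration_s=30.0, sampling_rate_hz=360.0,
        noise_sd=0.0, baseline_wander_amp=0.0, seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Same cohort with realistic noise and baseline wander."""
    cfg = SynthConfig(
        num_subjects=6, duration_s=30.0, sampling_rate_hz=360.0,
        noise_sd=0.05, baseline_wander_amp=0.1, seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rpeak_config():
    return SegmentationConfig(mode="rpeak_grouped", group_n=3, beat_window_samples=180)


def match_peaks(detected, truth, tol):
    """Greedy nearest matching; returns (tp, fp, fn)."""
    truth = np.asarray(truth)
    used = set()
    tp = fp = 0
    for d in detected:
        j = int(np.argmin(np.abs(truth - d))) if truth.size else -1
        if j >= 0 and abs(int(truth[j]) - int(d)) <= tol and j not in used:
            tp += 1
            used.add(j)
        else:
            fp += 1
    return tp, fp, truth.size - len(used)
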