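import numpy as np
import pytest

import crosstask_erp as ce
from crosstask_erp.events import SequenceDesign
from crosstask_erp.simulate import default_config, noiseless_config


@pytest.fixture(scope="session")
def small_design() -> SequenceDesign:
    """Shortened sequences for fast tests (the study design itself — 20
    repetitions of 47-50 stimuli — is exercised where the checked quantity
    depends on it)."""
    return SequenceDesign(n_stimuli_range=(20, 24), target_count_range=(3, 6),
                          n_repetitions_per_condition=4)


@pytest.fixture(scope="session")
def small_cfg(small_design):
    return default_config(master_seed=11, sequence_design=small_design)


@pytest.fixture(scope="session")
def small_recording(small_cfg):
    return ce.simulate_recording(small_cfg, 0, "C")


@pytest.fixture(scope="session")
def small_epochs(small_recording):
    return ce.preprocess_recording(small_recording)


@pytest.fixture(scope="session")
def small_features(small_epochs):
    return ce.extract_features(small_epochs)


@pytest.fixture(scope="session")
def noiseless_cfg(small_design):
    return noiseless_config(master_seed=11, sequence_design=small_design)


@pytest.fixture(scope="session")
def noiseless_recording(noiseless_cfg):
    return ce.simulate_recording(noiseless_cfg, 0, "C")


def toy_recording(n_channels=4, n_samples=2000, sfreq=1000.0, seed=0,
                  channel_names=None, events=None):
    """Small random recording for oracle tests (includes mastoids + EOG by
    default so the full chain runs)."""
    rng = np.random.default_rng(seed)
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_channels - 3)] + ["M1", "M2", "EOG"]
    data = rng.normal(size=(len(channel_names), n_samples))
    return ce.ContinuousRecording(
        data=data, sampling_rate=sfreq, channel_names=channel_names,
        events=events or [], participant="T01", condition="C",
    )


def make_events(n, repetition_index=1, start_ms=500, condition="C", targets=()):
    return [
        ce.StimulusEvent(
            onset_ms=start_ms + i * 1000, color_index=0 if i in targets else 1,
            grid_row=1 + i % 5, grid_col=1 + (i * 2) % 5,
            is_target=i in targets, condition=condition,
            repetition_index=repetition_index, within_repetition_index=i + 1,
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def study_cohort():
    """Scaled-down replica of the full study: 13 participants x 3
    conditions, 12 repetitions of 40-44 stimuli (about half the epochs of
    the printed design), preprocessed to features plus Fisher-averaged
    signed-r2 maps per condition."""
    from crosstask_erp import discriminability as dm

    design = SequenceDesign(n_stimuli_range=(40, 44), target_count_range=(8, 13),
                            n_repetitions_per_condition=12)
    cfg = default_config(master_seed=42, sequence_design=design)
    cohort = {}
    maps = {}
    for p in range(13):
        label = f"P{p + 1:02d}"
        cohort[label] = {}
        for cond in ("A", "C", "M"):
            rec = ce.simulate_recording(cfg, p, cond)
            epochs = ce.preprocess_recording(rec)
            cohort[label][cond] = ce.extract_features(epochs)
            maps.setdefault(cond, []).append(dm.signed_r2(epochs))
            del rec, epochs
    avg_maps = {c: dm.fisher_average(m) for c, m in maps.items()}
    return cohort, avg_maps
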