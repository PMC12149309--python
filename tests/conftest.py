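"""Shared fixtures: the default synthetic study conditions, a tuned ESVT
operating point (grid search run once per session), per-seed gain tables
for the efficacy/benchmark assertions, and a synthetic dataset tree."""

from __future__ import annotations

import numpy as np
import pytest

from bcgdenoise import (
    ESVTParams,
    SyntheticSpec,
    esvt_denoise,
    generate_beat_train,
    grid_search,
    measure_snr,
    simulate,
    wavelet_denoise,
)
from bcgdenoise.beats import PeakAnnotations
from bcgdenoise.dataset import (
    SubjectRecord,
    format_record_name,
    write_peak_csv,
    write_signal_csv,
    write_subject_info,
)

EFFICACY_LEVELS = (0.0, 5.0, 10.0, 15.0)
EFFICACY_SEEDS = 10


@pytest.fixture(scope="session")
def paper_spec() -> SyntheticSpec:
    """The published synthetic-BCG conditions: six cardiac sinusoids,
    0.2 Hz respiration of amplitude 2, 30 s at 100 Hz."""
    return SyntheticSpec()


@pytest.fixture(scope="session")
def tuned(paper_spec) -> "tuple[ESVTParams, object]":
    """(tau_opt, i_opt) from the default grid search at nominal 0 dB."""
    result = grid_search(paper_spec, seed=1)
    return result.params(), result


@pytest.fixture(scope="session")
def gain_table(paper_spec, tuned):
    """Per-(level, seed) cardiac-referenced SNR gains for ESVT and the
    wavelet baseline at nominal SNR levels 0/5/10/15 dB, 10 pinned seeds."""
    params, _ = tuned
    esvt_gains = {}
    wave_gains = {}
    for li, level in enumerate(EFFICACY_LEVELS):
        spec = SyntheticSpec(nominal_snr_db=level, seed=1)
        eg, wg = [], []
        for r in range(EFFICACY_SEEDS):
            sig = simulate(spec, 500 + li, r)
            snr_in = measure_snr(sig.noisy, sig.clean_cardiac)
            den = esvt_denoise(sig.noisy, params).denoised
            eg.append(measure_snr(den, sig.clean_cardiac) - snr_in)
            wden = wavelet_denoise(sig.noisy)
            wg.append(measure_snr(wden, sig.clean_cardiac) - snr_in)
        esvt_gains[level] = np.array(eg)
        wave_gains[level] = np.array(wg)
    return esvt_gains, wave_gains


def make_recording_folder(root, subject_id, site, hr_bpm, seed, duration=60.0, fs=100.0):
    """Write one synthetic hdata<ID><site> folder in the published layout.

    BCG and ECG channels are beat trains at slightly offset rates drawn
    from ground-truth peak times; the 'denoised' column reuses the BCG
    train.  Synthetic stand-in for a real recording folder.
    """
    name = format_record_name(subject_id, site)
    folder = root / name
    folder.mkdir(parents=True)
    bcg, j_times = generate_beat_train(hr_bpm, duration, fs, jitter_sd=0.01, seed=seed)
    ecg, r_times = generate_beat_train(hr_bpm, duration, fs, jitter_sd=0.01, template="gaussian-bump", seed=seed + 1)
    write_signal_csv(folder / "signal.csv", bcg, ecg, bcg)
    j_idx = np.round(np.asarray(j_times) * fs).astype(np.int64)
    r_idx = np.round(np.asarray(r_times) * fs).astype(np.int64)
    write_peak_csv(folder / f"{name}_BCG.csv", PeakAnnotations(j_idx, j_idx / fs, fs))
    write_peak_csv(folder / f"{name}_ECG.csv", PeakAnnotations(r_idx, r_idx / fs, fs))
    (folder / f"{name}_UCG.AVI").write_text("synthetic placeholder, never decoded\n")
    (folder / "signal.pdf").write_text("synthetic placeholder\n")
    return folder


@pytest.fixture()
def dataset_root(tmp_path):
    """A small synthetic dataset tree: 7 recordings, 4 subjects, EF folder."""
    root = tmp_path / "Data"
    rng = np.random.default_rng(7)
    sites = ["mitral_valve", "left_ventricle", "aortic_valve"]
    k = 0
    for sid in (1, 2, 3, 36):
        for site in sites[: 1 + sid % 3]:
            hr = float(rng.uniform(55, 95))
            make_recording_folder(root, sid, site, hr, seed=100 + k)
            k += 1
    ef_dir = root / "EF_ALLsubject"
    ef_dir.mkdir()
    for sid in (1, 2, 3, 36):
        (ef_dir / f"hdata{sid}EF.JPG").write_text("synthetic placeholder\n")
    return root


@pytest.fixture()
def subject_records():
    return [
        SubjectRecord(id=1, sex="M", weight=70, height=175, age=30, heart_rate=62, ef=64, group="sinus"),
        SubjectRecord(id=2, sex="F", weight=58, height=160, age=45, heart_rate=71, ef=60, group="sinus"),
        SubjectRecord(id=3, sex="M", weight=80, height=180, age=63, heart_rate=85, ef=30, group="hf"),
        SubjectRecord(id=36, sex="M", weight=75, height=172, age=55, heart_rate=78, ef=40, group="hf"),
        SubjectRecord(id=5, sex="F", weight=62, height=165, age=68, heart_rate=69, ef=50, group="hf"),
    ]
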