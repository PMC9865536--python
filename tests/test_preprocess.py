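import numpy as np
import pytest

from doaeeg.preprocess import (
    FAST_CLEANING,
    CleaningConfig,
    Sample,
    Segment,
    bandpass_fir,
    ceemdan_decompose,
    classify_ics,
    filter_array,
    ica_decompose,
    ica_reconstruct,
    make_samples,
    mra_decompose,
    remove_eoa,
    segment_record,
    wt_decompose,
    wt_reconstruct,
)
from doaeeg.synth import EEGRecord

FS = 178.2


def _record(n_seconds=12.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(round(n_seconds * FS))
    return EEGRecord(data=rng.standard_normal((4, n)), fs=FS)


# --- segmentation ----------------------------------------------------------


def test_segment_length_and_count():
    rec = _record(60.0)
    segs = segment_record(rec)
    win, hop = 712, 356
    assert all(s.data.shape == (4, win) for s in segs)
    expected = (rec.n_samples - win) // hop + 1
    assert len(segs) == expected
    assert np.isclose(segs[1].start_time - segs[0].start_time, hop / FS)


def test_segment_record_too_short():
    with pytest.raises(ValueError):
        segment_record(_record(1.0))


def test_segment_validation():
    with pytest.raises(ValueError):
        Segment(data=np.zeros((3, 100)), fs=FS)
    bad = np.zeros((4, 100))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        Segment(data=bad, fs=FS)


def test_sample_validation():
    seg = Segment(data=np.zeros((4, 100)), fs=FS)
    with pytest.raises(ValueError):
        Sample(segment=seg, psi=101.0)
    with pytest.raises(ValueError):
        Sample(segment=seg, psi=-0.5)


# --- filtering -------------------------------------------------------------


def test_bandpass_passband_and_stopband():
    t = np.arange(4096) / FS
    inband = np.sin(2 * np.pi * 10.0 * t)
    slow = np.sin(2 * np.pi * 0.2 * t)
    fast = np.sin(2 * np.pi * 70.0 * t)
    y_in = filter_array(inband, FS)
    y_slow = filter_array(slow, FS)
    y_fast = filter_array(fast, FS)
    mid = slice(1000, 3000)  # away from edges
    assert np.std(y_in[mid]) > 0.9 * np.std(inband[mid])
    assert np.std(y_slow[mid]) < 0.05 * np.std(slow[mid])
    assert np.std(y_fast[mid]) < 0.05 * np.std(fast[mid])


def test_bandpass_zero_delay():
    t = np.arange(4096) / FS
    x = np.sin(2 * np.pi * 10.0 * t)
    y = filter_array(x, FS)
    mid = slice(1000, 3000)
    # in-phase: correlation with the input maximal at zero lag
    assert np.corrcoef(x[mid], y[mid])[0, 1] > 0.999


def test_bandpass_segment_shape():
    seg = Segment(data=np.random.default_rng(0).standard_normal((4, 712)), fs=FS)
    out = bandpass_fir(seg)
    assert out.data.shape == (4, 712)
    assert out.start_time == seg.start_time


def test_bandpass_fs_too_low():
    with pytest.raises(ValueError):
        filter_array(np.zeros(500), fs=80.0)


# --- wavelet ---------------------------------------------------------------


def test_wt_round_trip():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(712)
    coeffs = wt_decompose(x)
    y = wt_reconstruct(coeffs, length=x.size)
    assert np.allclose(x, y, atol=1e-10)


def test_wt_level_too_high():
    with pytest.raises(ValueError):
        wt_decompose(np.zeros(32), level=10)


def test_mra_additive():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(712)
    bands = mra_decompose(x)
    assert len(bands) == 5  # approximation + 4 details
    assert np.allclose(np.sum(bands, axis=0), x, atol=1e-10)


# --- CEEMDAN wrapper -------------------------------------------------------


def test_ceemdan_decompose_completeness():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(256)
    imfs, residue = ceemdan_decompose(x, FAST_CLEANING)
    assert np.allclose(imfs.sum(axis=0) + residue, x, atol=1e-10)


# --- ICA -------------------------------------------------------------------


def test_ica_full_keep_identity():
    rng = np.random.default_rng(4)
    sources = np.array(
        [np.sin(np.linspace(0, 20, 400)), rng.standard_normal(400), rng.laplace(size=400)]
    )
    mixed = np.array([[1.0, 0.5, 0.2], [0.3, 1.0, 0.4], [0.2, 0.3, 1.0]]) @ sources
    icset = ica_decompose(mixed, CleaningConfig())
    back = ica_reconstruct(icset, keep_mask=np.ones(3, dtype=bool))
    assert np.allclose(back, mixed, atol=1e-12)


def test_ica_drop_removes_contribution():
    rng = np.random.default_rng(5)
    mixed = rng.standard_normal((3, 300))
    icset = ica_decompose(mixed, CleaningConfig())
    keep = np.array([True, False, True])
    back = ica_reconstruct(icset, keep)
    expected = icset.original - np.outer(icset.mixing[:, 1], icset.sources[1])
    assert np.allclose(back, expected, atol=1e-12)


def test_ica_reconstruct_mask_length():
    icset = ica_decompose(np.random.default_rng(6).standard_normal((3, 200)), CleaningConfig())
    with pytest.raises(ValueError):
        ica_reconstruct(icset, np.ones(4, dtype=bool))


def test_ica_single_row_passthrough():
    x = np.random.default_rng(7).standard_normal((1, 100))
    icset = ica_decompose(x, CleaningConfig())
    assert np.allclose(icset.sources, x)
    assert np.allclose(ica_reconstruct(icset, np.array([True])), x)


def test_classify_ics():
    rng = np.random.default_rng(8)
    smooth = np.sin(np.linspace(0, 4 * np.pi, 400))
    noisy = rng.standard_normal(400)
    mask = classify_ics(np.array([smooth, noisy]), sampen_threshold=0.3)
    assert mask[0] and not mask[1]
    with pytest.raises(ValueError):
        classify_ics(np.empty((0, 100)), 0.3)


# --- cleaning config / orchestration --------------------------------------


def test_cleaning_config_validation():
    with pytest.raises(ValueError):
        CleaningConfig(wavelet_levels=0)
    with pytest.raises(ValueError):
        CleaningConfig(sampen_threshold=-0.1)


def test_remove_eoa_nothing_flagged_is_identity():
    rng = np.random.default_rng(9)
    seg = Segment(data=rng.standard_normal((4, 712)), fs=FS)
    cfg = CleaningConfig(sampen_threshold=0.0, ceemdan_ensemble_size=4, max_imfs=4)
    out, state = remove_eoa(seg, cfg, return_state=True)
    assert np.allclose(out.data, seg.data, atol=1e-9)
    assert all(not m.any() for m in state.artifact_mask)


def test_remove_eoa_preserves_shape_and_metadata(small_subjects):
    seg = segment_record(small_subjects[0].record)[0]
    seg = bandpass_fir(seg)
    out = remove_eoa(seg, FAST_CLEANING)
    assert out.data.shape == seg.data.shape
    assert out.fs == seg.fs and out.start_time == seg.start_time


def test_make_samples_labels(small_subjects):
    samples = make_samples(small_subjects[0], eoa_removal=False)
    segs = segment_record(small_subjects[0].record)
    assert len(samples) == len(segs)
    for s in samples:
        assert 0.0 <= s.psi <= 100.0
        assert s.segment.data.shape == (4, 712)
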