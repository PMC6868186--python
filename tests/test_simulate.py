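"""Simulator: spacing law, truth bookkeeping, sample cutting, determinism."""
import math

import numpy as np
import pytest

from pepfeat.isotopes import isotope_spacing
from pepfeat.map_io import FrameSpec, read_ms1
from pepfeat.simulate import (SimulationConfig, SyntheticFeatureSpec,
                              augment_rare_charges, make_detecting_samples,
                              make_grouping_samples, render_map,
                              sample_feature_specs, simulate_map,
                              simulate_to_files)


def test_sample_feature_specs_degenerate_cases():
    cfg = SimulationConfig(n_features=0)
    assert sample_feature_specs(cfg) == []
    cfg = SimulationConfig(n_features=100, charge_probs={2: 1.0}, rng_seed=5)
    specs = sample_feature_specs(cfg)
    assert len(specs) == 100
    assert all(s.charge == 2 for s in specs)


def test_generated_z2_spacing_is_half_c13_mass():
    cfg = SimulationConfig(n_features=50, charge_probs={2: 1.0}, rng_seed=6)
    for s in sample_feature_specs(cfg):
        assert s.isotope_mz(1) - s.isotope_mz(0) == pytest.approx(0.501675)


def test_printed_spacings_reproduced_for_low_charges():
    assert [round(isotope_spacing(z), 2) for z in (1, 2, 3, 4)] == \
        [1.00, 0.50, 0.33, 0.25]


def test_infeasible_extent_raises():
    cfg = SimulationConfig(mz_min=400.0, mz_max=402.0, n_features=10)
    with pytest.raises(ValueError, match="extent"):
        sample_feature_specs(cfg)


def test_render_map_paints_only_isotope_bins():
    cfg = SimulationConfig(n_features=1, noise_trace_density=0.0,
                           missing_scan_probability=0.0, mz_jitter_sigma=0.0,
                           rng_seed=3)
    specs = sample_feature_specs(cfg)
    lcms_map, truth = render_map(specs, cfg)
    nz_bins = set(np.unique(lcms_map.raw.tocoo().col))
    expect = {lcms_map.bin_of_mz(specs[0].isotope_mz(i))
              for i in range(specs[0].n_isotopes)}
    assert nz_bins == expect


def test_render_map_all_scans_dropped_keeps_truth():
    cfg = SimulationConfig(n_features=3, missing_scan_probability=1.0,
                           rng_seed=4)
    specs = sample_feature_specs(cfg)
    lcms_map, truth = render_map(specs, cfg)
    assert lcms_map.raw.nnz == 0
    assert len(truth) == 3


def test_truth_auc_matches_trapezoid_on_dense_grid():
    # single isotope, apex 1000, sigma 0.05 min: analytic integral vs a
    # dense numerical one on the rendered trace
    cfg = SimulationConfig(rt_span=2.0, scan_spacing=0.002, n_features=1,
                           noise_trace_density=0.0, missing_scan_probability=0.0,
                           mz_jitter_sigma=0.0, rng_seed=9)
    spec = SyntheticFeatureSpec(mono_mz=405.0, charge=2, n_isotopes=2,
                                rt_apex=1.0, rt_sigma=0.05,
                                apex_intensity=1000.0, envelope=[1.0, 0.5])
    lcms_map, truth = render_map([spec], cfg)
    analytic = 1000.0 * 0.05 * math.sqrt(2 * math.pi)
    assert truth.features[0].isotope_auc[0] == pytest.approx(analytic)
    b = lcms_map.bin_of_mz(405.0)
    trace = np.asarray(lcms_map.raw[:, b].todense()).ravel()
    numeric = np.trapezoid(trace, lcms_map.rt_of_scan)
    assert numeric == pytest.approx(analytic, rel=0.01)


def test_truth_total_is_exact_sum_of_isotope_aucs(small_sim):
    _, _, truth = small_sim
    for f in truth:
        assert f.total_intensity == float(f.isotope_auc.sum())


def test_spacing_law_within_half_bin(small_sim):
    cfg, lcms_map, truth = small_sim
    for f in truth:
        z = f.spec.charge
        for i in range(f.spec.n_isotopes):
            expect = f.spec.mono_mz + i * isotope_spacing(z)
            assert abs(f.spec.isotope_mz(i) - expect) < cfg.mz_bin_width / 2


def test_simulation_is_deterministic():
    a_map, a_truth = simulate_map(SimulationConfig(n_features=20, rng_seed=11))
    b_map, b_truth = simulate_map(SimulationConfig(n_features=20, rng_seed=11))
    assert (a_map.raw != b_map.raw).nnz == 0
    assert [f.spec.mono_mz for f in a_truth] == [f.spec.mono_mz for f in b_truth]


def test_detecting_sample_labels_follow_truth_ranges(small_sim, rng,
                                                     detect_frame):
    _, lcms_map, truth = small_sim
    samples = make_detecting_samples(lcms_map, truth, detect_frame,
                                     n_negative=10, rng=rng)
    pos = [s for s in samples if s.charge > 0]
    assert len(pos) == len(truth)
    for s, f in zip(pos, truth):
        inside = s.labels == s.charge
        assert inside.any()
        # labels are the charge exactly while the scan is inside the
        # feature's elution range, 0 outside
        run = np.nonzero(inside)[0]
        assert np.all(np.diff(run) == 1)
        assert set(np.unique(s.labels)) <= {0, s.charge}
    for s in samples:
        if s.charge == 0:
            assert not s.labels.any()


def test_grouping_sample_labels_cap_at_4(small_sim, rng):
    _, lcms_map, truth = small_sim
    samples = make_grouping_samples(lcms_map, truth, rng)
    pos = samples[:len(truth)]
    for s, f in zip(pos, truth):
        assert s.label == min(f.spec.n_isotopes - 1, 4)
        assert s.frames.shape == (5, 15, 10)
    # negatives (noise, shifted-start, blank) all labeled 0
    assert all(s.label == 0 for s in samples[len(truth):])


def test_augment_rare_charges_duplicates_and_keeps_labels(small_sim, rng,
                                                          detect_frame):
    _, lcms_map, truth = small_sim
    samples = make_detecting_samples(lcms_map, truth, detect_frame,
                                     n_negative=0, rng=rng)
    zs = {s.charge for s in samples}
    target = max(zs)
    n_target = sum(1 for s in samples if s.charge == target)
    out = augment_rare_charges(samples, {target}, duplication=10, rng=rng)
    n_out = sum(1 for s in out if s.charge == target)
    assert n_out >= 10 * n_target
    # copies keep the label sequence of their source
    copies = [s for s in out if s.charge == target][n_target:]
    originals = [s for s in samples if s.charge == target]
    for c in copies:
        assert any(np.array_equal(c.labels, o.labels) for o in originals)
    assert augment_rare_charges(samples, set(), 10, rng) == samples


def test_simulate_to_files_round_trips_through_reader(tmp_path):
    cfg = SimulationConfig(rt_span=0.5, mz_min=400.0, mz_max=410.0,
                           n_features=3, rng_seed=13)
    ms1_path, truth_path = simulate_to_files(cfg, str(tmp_path))
    scans = read_ms1(ms1_path)
    lcms_map, _ = simulate_map(cfg)
    # a trailing all-empty scan is not representable in the text dialect
    assert lcms_map.n_scans - 1 <= len(scans) <= lcms_map.n_scans
    rts = {round(s.rt, 6) for s in scans}
    assert {round(float(r), 6) for r in lcms_map.rt_of_scan[:-1]} <= rts
    total_written = sum(s.intensity.sum() for s in scans)
    assert total_written == pytest.approx(lcms_map.raw.sum(), rel=1e-6)
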