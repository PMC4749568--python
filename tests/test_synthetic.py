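"""Generator checks: geometry, DCV occupancy law, gold deposition law,
vesicle diameters, and rendered image stacks."""

import numpy as np
import pytest

from sigold import SimConfig, generate_dataset
from sigold.config import ConfigurationError
from sigold.synthetic import (
    LabelingDesign, Neurite, deposit_gold, generate_neurites,
    generate_synapses, make_paired_grid_design, make_whole_body_design,
    render_if_stacks, sample_clear_diameters, sample_dcv_counts,
    sample_dcv_diameters, warp_volume, SyntheticDataset,
)


def _line_neurite(nid="n1", n_sections=100, x=1.0, area=0.25):
    path = np.column_stack([np.full(n_sections, x), np.zeros(n_sections)])
    return Neurite(id=nid, side="right", section_range=(0, n_sections),
                   path=path, area_per_section=np.full(n_sections, area),
                   true_peptides=frozenset({"PDF"}))


# ---------------------------------------------------------------------------
# dataset composition

def test_empty_dataset():
    cfg = SimConfig(n_neurites=0, seed=1)
    ds = generate_dataset(cfg)
    assert ds.neurites == []
    assert all(len(row) == 0 for row in ds.gold.values())


def test_same_seed_byte_identical_serialization():
    cfg = SimConfig(n_neurites=20, seed=3)
    a = generate_dataset(cfg, n_synapses=5).to_json()
    b = generate_dataset(SimConfig(n_neurites=20, seed=3),
                         n_synapses=5).to_json()
    assert a == b
    c = generate_dataset(SimConfig(n_neurites=20, seed=4),
                         n_synapses=5).to_json()
    assert a != c


def test_dataset_json_round_trip(small_dataset):
    back = SyntheticDataset.from_json(small_dataset.to_json())
    assert back.to_json() == small_dataset.to_json()


def test_bilateral_mirroring_exhaustive():
    cfg = SimConfig(n_neurites=200, seed=11)
    neurites = generate_neurites(cfg)
    by_id = {n.id: n for n in neurites}
    lefts = [n for n in neurites if n.side == "left"]
    assert len(lefts) == 100
    for ln in lefts:
        partner = by_id[ln.mirror_of]
        assert partner.side == "right"
        np.testing.assert_allclose(ln.path[:, 0], -partner.path[:, 0],
                                   atol=1e-9)
        np.testing.assert_allclose(ln.path[:, 1], partner.path[:, 1])
        assert ln.true_peptides == partner.true_peptides


def test_invalid_config_names_field():
    with pytest.raises(ConfigurationError, match="enhancement_prob"):
        SimConfig(enhancement_prob=1.5)
    with pytest.raises(ConfigurationError, match="n_sections"):
        SimConfig(n_sections=0)


# ---------------------------------------------------------------------------
# DCV occupancy chain

def test_absorbing_off_state_gives_all_zero_track(rng):
    cfg = SimConfig(dcv_on_rate=0.0, seed=0)
    n = _line_neurite(n_sections=500)
    track = sample_dcv_counts(n, cfg, rng)
    # stationary on-fraction is 0, so the chain starts and stays off
    assert np.all(track.counts == 0)


def test_stationary_mean_matches_closed_form(rng):
    cfg = SimConfig(n_sections=10_000, dcv_on_rate=0.2, dcv_off_rate=0.1,
                    dcv_mean=4.0, seed=0)
    n = _line_neurite(n_sections=10_000)
    track = sample_dcv_counts(n, cfg, rng)
    pi_on = 0.2 / 0.3
    expected = pi_on * 4.0
    # binomial(on) x Poisson variance, 3 sigma Monte-Carlo band
    var = pi_on * (4.0 + 4.0 ** 2) - expected ** 2
    se = np.sqrt(var / 10_000)
    assert abs(track.counts.mean() - expected) < 3 * se


def test_zero_run_lengths_geometric(rng):
    p_on = 0.25
    cfg = SimConfig(n_sections=30_000, dcv_on_rate=p_on, dcv_off_rate=0.2,
                    seed=0)
    n = _line_neurite(n_sections=30_000)
    track = sample_dcv_counts(n, cfg, rng)
    on = track.counts > 0
    # interior runs of 'off-state' sections; occupancy zeros from the
    # Poisson are rare enough not to distort the law at dcv_mean=4
    runs, cur = [], 0
    for v in on:
        if v:
            if cur:
                runs.append(cur)
            cur = 0
        else:
            cur += 1
    runs = np.asarray(runs)
    # geometric(p_on): mean 1/p_on
    assert abs(runs.mean() - 1 / p_on) < 3 * runs.std(ddof=1) / np.sqrt(len(runs))
    # memorylessness: P(L > 2 | L > 1) close to P(L > 1)
    p_gt1 = (runs > 1).mean()
    p_gt2_given = (runs > 2).sum() / max((runs > 1).sum(), 1)
    assert abs(p_gt1 - p_gt2_given) < 0.05


# ---------------------------------------------------------------------------
# gold deposition

def _uniform_design(n_sections, antibody="PDF"):
    return LabelingDesign([(antibody, (0, n_sections))])


def test_omitted_primary_limit_all_zero(rng):
    cfg = SimConfig(gold_per_dcv=0.0, background_rate=0.0, n_sections=100,
                    seed=0)
    n = _line_neurite()
    track = sample_dcv_counts(n, cfg, rng)
    gold = deposit_gold([n], {n.id: track}, _uniform_design(100), cfg, rng)
    assert all(c == 0 for row in gold.values() for c in row.values())


def test_no_dcv_no_background_zero_count(rng):
    cfg = SimConfig(background_rate=0.0, n_sections=50, seed=0)
    n = _line_neurite(n_sections=50)
    track = sample_dcv_counts(n, cfg, rng)
    track.counts[:] = 0
    gold = deposit_gold([n], {n.id: track}, _uniform_design(50), cfg, rng)
    assert all(c == 0 for row in gold.values() for c in row.values())


def test_thinned_poisson_mean(rng):
    # alpha=2, D=3, S=1 (cognate), lambda_bg=0, p_enh=0.5 -> mean 3.0
    n_rep = 10_000
    cfg = SimConfig(gold_per_dcv=2.0, background_rate=0.0,
                    enhancement_prob=0.5, n_sections=n_rep, seed=0)
    n = _line_neurite(n_sections=n_rep)
    track = sample_dcv_counts(n, cfg, rng)
    track.counts[:] = 3
    gold = deposit_gold([n], {n.id: track}, _uniform_design(n_rep), cfg, rng)
    counts = np.array([row[n.id] for row in gold.values()])
    mean = 0.5 * 2.0 * 3.0
    se = np.sqrt(mean / n_rep)  # thinned Poisson: var == mean
    assert abs(counts.mean() - mean) < 3 * se


def test_deposit_outside_stack_raises(rng, small_config):
    n = _line_neurite(n_sections=10)
    cfg = SimConfig(n_sections=10)
    track = sample_dcv_counts(n, cfg, rng)
    bad = LabelingDesign([("PDF", (5, 15))])
    with pytest.raises(ValueError, match="outside"):
        deposit_gold([n], {n.id: track}, bad, cfg, rng)


def test_cell_count_conservation(small_dataset):
    # number of gold cells == sum over runs of run length x intersecting
    # neurites (all neurites span the full stack here)
    ds = small_dataset
    expected = sum(
        (s1 - s0) * sum(1 for n in ds.neurites if n.spans(s0))
        for _, (s0, s1) in ds.design.assignments
    )
    assert sum(len(row) for row in ds.gold.values()) == expected


# ---------------------------------------------------------------------------
# labeling designs

def test_paired_grid_design_geometry():
    cfg = SimConfig(seed=5)
    d = make_paired_grid_design(cfg)
    d.validate(cfg.n_sections)
    assert d.style == "paired-grids"
    for ab in cfg.antibody_panel:
        runs = d.runs_for(ab)
        assert len(runs) == 2
        assert all(4 <= s1 - s0 <= 6 for s0, s1 in runs)
        gap = runs[1][0] - runs[0][0]
        assert 40 <= gap <= 80  # approximately 50 sections apart


def test_whole_body_design_geometry():
    cfg = SimConfig(n_sections=5056, seed=5)
    d = make_whole_body_design(cfg)
    d.validate(cfg.n_sections)
    for ab in cfg.antibody_panel:
        runs = d.runs_for(ab)
        assert len(runs) == 2
        assert all(1 <= s1 - s0 <= 6 for s0, s1 in runs)


# ---------------------------------------------------------------------------
# synapses and vesicle diameters

def test_dcv_diameter_sample_near_63(rng):
    d = sample_dcv_diameters(100, rng)
    assert abs(d.mean() - 63.0) < 3 * 8.4 / np.sqrt(100)
    assert np.all(d > 0)


def test_clear_diameters_below_threshold_with_predicted_rate(rng):
    # P(clear vesicle >= 45 nm) from the truncated-normal upper tail
    from scipy import stats
    n = 20_000
    d = sample_clear_diameters(n, rng)
    a = (0 - 35.0) / 5.0
    p_pred = stats.truncnorm.sf((45.0 - 35.0) / 5.0, a, np.inf)
    p_obs = (d >= 45.0).mean()
    assert abs(p_obs - p_pred) < 3 * np.sqrt(p_pred * (1 - p_pred) / n)


def test_zero_synapses_requested(rng, small_config):
    assert generate_synapses([], small_config, rng, n_synapses=0) == []


def test_synapse_truth_classes(small_dataset):
    for sy in small_dataset.synapses:
        pre = small_dataset.neurite(sy.pre_neurite_id)
        expected = "peptidergic" if pre.true_peptides else "classical"
        assert sy.vesicle_class_truth == expected
        assert np.all(sy.vesicle_diameters_nm > 0)


# ---------------------------------------------------------------------------
# rendered image stacks

def test_render_identity_equals_ground_truth():
    ss = render_if_stacks(1, rng=np.random.default_rng(0),
                          shape=(4, 16, 16), rotation_sd_deg=0.0,
                          scale_sd=0.0, translation_sd_vox=0.0,
                          deform_amp_vox=0.0, noise_sd=0.0)
    np.testing.assert_allclose(ss.stacks[0].data, ss.ground_truth,
                               atol=1e-12)


def test_render_full_cohort_at_desk_scale():
    ss = render_if_stacks(36, rng=np.random.default_rng(1), shape=(8, 64, 64))
    assert len(ss.stacks) == 36
    assert len(ss.true_affines) == 36


def test_inverse_transform_recovers_pattern():
    from sigold.registration import ncc
    ss = render_if_stacks(3, rng=np.random.default_rng(2), shape=(8, 64, 64),
                          deform_amp_vox=0.0, noise_sd=0.0)
    for st, aff in zip(ss.stacks, ss.true_affines):
        A, t = aff[:, :3], aff[:, 3]
        Ainv = np.linalg.inv(A)
        inv = np.c_[Ainv, -Ainv @ t]
        recovered = warp_volume(st.data, inv)
        # interior crop: edge voxels are lost to out-of-volume resampling
        sl = (slice(1, -1), slice(4, -4), slice(4, -4))
        assert ncc(recovered[sl], ss.ground_truth[sl]) > 0.98
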