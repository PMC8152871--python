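"""Run designs, the seeded cohort generator, rendering, and behavior."""

import numpy as np
import pytest

from syntaxconn import (
    CONDITIONS,
    build_run_design,
    classify_pairs,
    default_generative_spec,
    extract_roi_series,
    partial_corr_matrix,
    population_partial_corr,
    render_volumes,
    simulate_behavior,
    simulate_participant,
    simulate_run,
    sphere_mask,
)
from syntaxconn.compare import behavioral_contrast
from syntaxconn.simulate import (
    GenerativeSpec,
    SimulateError,
    canonical_hrf,
    random_generative_spec,
)
from tests.conftest import make_catalog


def test_default_run_design_totals():
    design = build_run_design(seed=3)
    assert design.total_duration_s == 256.0
    assert design.n_volumes == 128
    assert len(design.trials) == 32
    counts = {c: 0 for c in CONDITIONS}
    for t in design.trials:
        counts[t.condition] += 1
    assert all(v == 4 for v in counts.values())


def test_run_design_is_block_randomized():
    design = build_run_design(seed=9)
    for block_start in range(0, 32, 8):
        block = {t.condition for t in design.trials[block_start:block_start + 8]}
        assert block == set(CONDITIONS)


def test_empty_design():
    design = build_run_design(trials_per_condition=0)
    assert design.n_volumes == 0 and design.total_duration_s == 0.0


def test_tr_must_divide_duration():
    with pytest.raises(SimulateError, match="does not divide"):
        build_run_design(tr_s=3.0)


def test_condition_boxcar_covers_stimulus_windows():
    design = build_run_design(seed=1)
    for cond in CONDITIONS:
        # 4 trials x 6-s stimulus at TR 2 -> 12 volumes flagged
        assert design.condition_boxcar(cond).sum() == 12


def test_volume_states_follow_trial_load():
    design = build_run_design(seed=2)
    states = design.volume_states()
    t = design.volume_times()
    for trial in design.trials:
        expected = "harder" if trial.condition in ("Pas+", "Pot", "Pot+") else "easier"
        inside = (t >= trial.onset_s) & (t < trial.onset_s + 8.0)
        assert all(states[inside] == expected)


def test_hrf_shape():
    h = canonical_hrf(2.0)
    assert h.max() == pytest.approx(1.0)
    assert h[0] == pytest.approx(0.0, abs=1e-6)
    assert np.argmax(h) * 2.0 == pytest.approx(5.0, abs=1.1)  # peak near 5 s
    assert h.min() < 0  # undershoot


def test_generator_is_deterministic():
    spec = default_generative_spec(seed=11)
    runs_a, truth_a = simulate_participant(spec, 5)
    runs_b, truth_b = simulate_participant(spec, 5)
    for a, b in zip(runs_a, runs_b):
        assert np.array_equal(a.data, b.data)
    runs_c, _ = simulate_participant(spec, 6)
    assert not np.array_equal(runs_a[0].data, runs_c[0].data)
    assert len(runs_a) == 6
    assert all(r.n_timepoints == 128 for r in runs_a)


def test_non_positive_definite_precision_rejected(catalog25):
    omega = -np.eye(25)
    with pytest.raises(SimulateError, match="positive definite"):
        GenerativeSpec(
            catalog=catalog25,
            precision_easier=omega,
            precision_harder=np.eye(25),
            ar_coef=0.3,
            task_amplitude=0.4,
            condition_gain={},
        )


def test_ar_coefficient_bounds(catalog25):
    with pytest.raises(SimulateError, match="AR"):
        GenerativeSpec(
            catalog=catalog25,
            precision_easier=np.eye(25),
            precision_harder=np.eye(25),
            ar_coef=1.0,
            task_amplitude=0.4,
            condition_gain={},
        )


def test_planted_flags_respect_threshold():
    """Ground-truth invariant: enhanced pop r > 0.20 >= suppressed pop r."""
    spec = default_generative_spec(seed=0)
    truth = spec.ground_truth()
    idx = {n: k for k, n in enumerate(truth.region_names)}
    ph = truth.population_partial("harder")
    pe = truth.population_partial("easier")
    assert truth.enhanced_pairs and truth.suppressed_pairs
    for a, b in truth.enhanced_pairs:
        assert ph[idx[a], idx[b]] > 0.20 >= pe[idx[a], idx[b]]
    for a, b in truth.suppressed_pairs:
        assert pe[idx[a], idx[b]] > 0.20 >= ph[idx[a], idx[b]]


def test_trial_level_state_switching_runs():
    spec = default_generative_spec(seed=4)
    design = build_run_design(seed=4)
    a = simulate_run(spec, design, [1, 2, 3], state_switching="trial")
    b = simulate_run(spec, design, [1, 2, 3], state_switching="trial")
    assert np.array_equal(a.data, b.data)
    assert a.data.shape == (25, 128)


def test_random_structure_spec_is_well_conditioned():
    for seed in (1, 2, 3):
        spec = random_generative_spec(seed=seed, structure_seed=seed)
        assert np.linalg.eigvalsh(spec.precision_easier).min() > 0.05


def small_catalog():
    return make_catalog({"a": "I", "b": "I", "c": "II"}, spacing_mm=30.0)


def small_grid():
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    affine[:3, 3] = (-75.0, -15.0, -15.0)
    return affine, (51, 11, 11)


def test_render_extract_round_trip_is_lossless(rng):
    """Zero voxel noise: extraction recovers the planted series exactly."""
    cat = small_catalog()
    affine, shape = small_grid()
    data = rng.normal(size=(3, 16))
    from syntaxconn.roi import RoiTimeSeriesSet

    ts = RoiTimeSeriesSet(
        participant="p", run="r", data=data, tr_s=2.0, region_names=cat.names
    )
    vol = render_volumes(ts, cat, affine, shape, noise_sd=0.0)
    masks = [sphere_mask(r.center_mm, 6.0, affine, shape) for r in cat]
    recovered = extract_roi_series(vol, masks, region_names=cat.names)
    assert np.allclose(recovered.data, data, atol=1e-12)


def test_render_rejects_overlapping_spheres(rng):
    cat = make_catalog({"a": "I", "b": "I"}, spacing_mm=6.0)  # centers 6 mm apart
    affine, shape = small_grid()
    from syntaxconn.roi import RoiTimeSeriesSet

    ts = RoiTimeSeriesSet(
        participant="p",
        run="r",
        data=rng.normal(size=(2, 4)),
        tr_s=2.0,
        region_names=cat.names,
    )
    with pytest.raises(SimulateError, match="overlap"):
        render_volumes(ts, cat, affine, shape)


def test_render_noise_averages_down_as_sqrt_of_sphere_size(rng):
    """33-voxel sphere: residual sd of the recovered series ~ sigma/sqrt(33)."""
    cat = make_catalog({"a": "I"})
    affine, shape = small_grid()
    sigma, n_t = 0.5, 400
    data = rng.normal(size=(1, n_t))
    from syntaxconn.roi import RoiTimeSeriesSet

    ts = RoiTimeSeriesSet(
        participant="p", run="r", data=data, tr_s=2.0, region_names=cat.names
    )
    vol = render_volumes(ts, cat, affine, shape, noise_sd=sigma, seed=3)
    mask = sphere_mask(cat.regions[0].center_mm, 6.0, affine, shape)
    assert len(mask) == 33
    recovered = extract_roi_series(vol, [mask]).data[0]
    residual_sd = np.std(recovered - data[0])
    assert residual_sd == pytest.approx(sigma / np.sqrt(33), rel=0.2)


def test_end_to_end_volume_pipeline_recovers_partial_correlations(rng):
    """Planted network -> volumes -> sphere extraction -> partial correlation."""
    cat = small_catalog()
    omega = np.array([[1.0, -0.4, 0.0], [-0.4, 1.0, -0.3], [0.0, -0.3, 1.0]])
    x = np.linalg.cholesky(np.linalg.inv(omega)) @ rng.standard_normal((3, 2000))
    from syntaxconn.roi import RoiTimeSeriesSet

    ts = RoiTimeSeriesSet(
        participant="p", run="r", data=x, tr_s=2.0, region_names=cat.names
    )
    affine, shape = small_grid()
    vol = render_volumes(ts, cat, affine, shape, noise_sd=0.0)
    masks = [sphere_mask(r.center_mm, 6.0, affine, shape) for r in cat]
    recovered = extract_roi_series(vol, masks, region_names=cat.names)
    est = partial_corr_matrix(recovered.data, region_names=cat.names)
    pop = population_partial_corr(omega)
    assert np.max(np.abs(est.values - pop)) < 0.08


def test_behavior_bounds_and_structure():
    table = simulate_behavior(seed=2)
    assert set(table["condition"]) == set(CONDITIONS)
    assert table["error_rate"].between(0, 100).all()
    assert (table["mean_rt"] > 0).all()
    assert table.groupby("group")["participant"].nunique().to_dict() == {
        "extra": 9, "lpmc_f3": 9, "normal": 16,
    }


def test_null_behavior_generator_gives_null_t():
    """With the planted contrast scaled to zero the paired t is ~null."""
    ps, ts = [], []
    for seed in range(20):
        table = simulate_behavior(
            group_sizes={"normal": 16}, seed=seed, effect_scale=0.0
        )
        res = behavioral_contrast(table, "error", "paired")
        ps.append(res.p)
        ts.append(res.t)
    assert abs(np.mean(ts)) < 1.0
    assert np.mean([p < 0.05 for p in ps]) <= 0.2


def test_behavior_determinism():
    a = simulate_behavior(seed=7)
    b = simulate_behavior(seed=7)
    assert a.equals(b)


def test_nifti_round_trip(tmp_path, rng):
    """Write a rendered 4D NIfTI and sphere-extract it back."""
    import nibabel as nib

    from syntaxconn import extract_from_nifti
    from syntaxconn.roi import RoiTimeSeriesSet

    cat = small_catalog()
    affine, shape = small_grid()
    data = rng.normal(size=(3, 8))
    ts = RoiTimeSeriesSet(
        participant="p", run="r", data=data, tr_s=2.0, region_names=cat.names
    )
    vol = render_volumes(ts, cat, affine, shape, noise_sd=0.0)
    path = tmp_path / "sim.nii.gz"
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), path)
    recovered = extract_from_nifti(path, cat)
    assert recovered.region_names == cat.names
    assert np.allclose(recovered.data, data, atol=1e-5)  # float32 round-off


def test_cohort_config_loading(tmp_path):
    from syntaxconn import load_cohort_config

    config = tmp_path / "cohort.yaml"
    config.write_text(
        "seed: 3\nnoise_sd: 0.1\nruns_per_participant: 2\n"
        "group_sizes:\n  normal: 4\n  lpmc_f3: 2\n"
    )
    spec = load_cohort_config(config)
    assert spec.seed == 3
    assert spec.noise_sd == 0.1
    assert spec.runs_per_participant == 2
    assert spec.group_sizes == {"normal": 4, "lpmc_f3": 2}
    runs, _ = simulate_participant(spec, 1)
    assert len(runs) == 2
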