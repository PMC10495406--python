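"""Population sampling, mixture fitting, shape inversion and mesh building."""

import numpy as np
import pandas as pd
import pytest

from measurenet.body_model import (DEFAULT_BOUNDS, FEATURE_COLUMNS,
                                   MEASUREMENT_NAMES, Marginal,
                                   PopulationSpec, build_mesh,
                                   default_population, fit_population_model,
                                   importance_sample, sample_cohort,
                                   semi_axis_from_circumference,
                                   ellipse_perimeter,
                                   shape_from_measurements)
from measurenet.parts import PART_CLASSES
from measurenet.tape_measure import named_measurements

from conftest import REQUESTED, quick_subjects


# ---- specs and marginals ---------------------------------------------------

def test_population_spec_validates_invariants():
    spec = default_population("male")
    assert spec.mean_whr == pytest.approx(0.90, abs=0.005)
    assert default_population("female").mean_whr == pytest.approx(0.85,
                                                                  abs=0.005)
    with pytest.raises(ValueError, match="WHR"):
        bad = dict(spec.marginals)
        bad["waist"] = Marginal("lognormal", 1400.0, 50.0)
        PopulationSpec(sex="male", marginals=bad)
    with pytest.raises(ValueError):
        Marginal("lognormal", -5.0, 1.0)
    with pytest.raises(ValueError, match="bounds"):
        bad = dict(spec.marginals)
        bad["waist"] = Marginal("lognormal", 400.0, 50.0)
        bad["hip"] = Marginal("lognormal", 520.0, 50.0)
        PopulationSpec(sex="male", marginals=bad)


def test_copula_sampling_matches_marginals():
    spec = default_population("female")
    table = spec.sample(4000, np.random.default_rng(0))
    for name in ("height", "waist", "hip"):
        m = spec.marginals[name]
        assert table[name].mean() == pytest.approx(m.mean, rel=0.02)
        assert table[name].std() == pytest.approx(m.sd, rel=0.10)


def test_ramanujan_inversion_is_consistent():
    for c, rho in ((900.0, 0.75), (350.0, 0.9)):
        a = semi_axis_from_circumference(c, rho)
        assert ellipse_perimeter(a, rho * a) * 1000 == pytest.approx(c,
                                                                     rel=1e-12)


# ---- mixture fitting -------------------------------------------------------

def _table_from_arrays(x: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(x, columns=FEATURE_COLUMNS)
    df.insert(0, "sex", "male")
    df.insert(0, "subject_id", np.arange(len(df)))
    return df


def test_bic_recovers_two_separated_components():
    rng = np.random.default_rng(42)
    spec = default_population("male")
    base = spec.sample(1000, rng)[FEATURE_COLUMNS].to_numpy()
    shifted = base.copy()
    # shift far beyond 6 sd on several coordinates
    shifted[:, 2:] *= 2.2
    shifted[:, 0] += 0.5
    x = np.vstack([base, shifted])
    model = fit_population_model(_table_from_arrays(x), max_clusters=4, seed=0)
    assert model.n_components == 2
    assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)
    for cov in model.covariances:
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > 0)


def test_point_mass_data_selects_one_component():
    row = np.array([[1.75, 80.0, 1000.0, 900.0, 1030.0, 580.0, 385.0, 330.0]])
    x = np.repeat(row, 60, axis=0)
    with pytest.warns(UserWarning, match="covariance floor"):
        model = fit_population_model(_table_from_arrays(x), max_clusters=3,
                                     seed=0)
    assert model.n_components == 1


def test_fit_requires_enough_rows():
    spec = default_population("male")
    table = spec.sample(30, np.random.default_rng(0))
    with pytest.raises(ValueError, match="at least"):
        fit_population_model(table, max_clusters=4, seed=0)


def test_fit_is_deterministic_given_seed():
    table = default_population("male").sample(300, np.random.default_rng(1))
    m1 = fit_population_model(table, max_clusters=3, seed=7)
    m2 = fit_population_model(table, max_clusters=3, seed=7)
    assert m1.n_components == m2.n_components
    assert np.allclose(m1.means, m2.means)


# ---- importance sampling ---------------------------------------------------

@pytest.fixture(scope="module")
def biased_model():
    """Mixture fitted on a waist-biased scan sample."""
    from measurenet.body_model import scan_population

    table = scan_population("male").sample(1500, np.random.default_rng(3))
    return fit_population_model(table, max_clusters=3, seed=3)


def test_importance_sampling_corrects_marginal_bias(biased_model):
    target = default_population("male")
    x = importance_sample(biased_model, target, 4000, seed=5)
    assert x.shape == (4000, len(FEATURE_COLUMNS))
    j = FEATURE_COLUMNS.index("waist")
    assert x[:, j].mean() == pytest.approx(target.marginals["waist"].mean,
                                           rel=0.05)


def test_importance_sampling_single_draw(biased_model):
    x = importance_sample(biased_model, default_population("male"), 1, seed=0)
    assert x.shape[0] == 1 and np.all(x > 0)


def test_importance_sampling_deterministic(biased_model):
    target = default_population("male")
    a = importance_sample(biased_model, target, 50, seed=9)
    b = importance_sample(biased_model, target, 50, seed=9)
    assert np.array_equal(a, b)


def test_degenerate_weights_error_names_marginal(biased_model):
    target = default_population("male")
    far = dict(target.marginals)
    far["waist"] = Marginal("lognormal", 1450.0, 10.0)
    far["hip"] = Marginal("lognormal", 1700.0, 10.0)
    target_far = PopulationSpec(sex="male", marginals=far)
    with pytest.raises(ValueError, match="waist|hip"):
        importance_sample(biased_model, target_far, 100, seed=0)


# ---- shape inversion and meshes --------------------------------------------

def test_shape_from_measurements_rejects_out_of_bounds():
    bad = dict(REQUESTED, hip=0.0)
    with pytest.raises(ValueError, match="hip"):
        shape_from_measurements(bad, "male", 1.75)
    with pytest.raises(ValueError, match="height"):
        shape_from_measurements(REQUESTED, "male", 0.9)


def test_scaled_measurements_scale_extraction(male_params):
    scaled_req = {k: 1.1 * v for k, v in REQUESTED.items()}
    params = shape_from_measurements(scaled_req, "male", 1.75)
    ms = named_measurements(build_mesh(params))
    base = named_measurements(build_mesh(male_params))
    for k in REQUESTED:
        assert ms.named[k] == pytest.approx(1.1 * base.named[k], rel=5e-3)


def test_waist_sweep_monotone_and_hip_stable(male_params):
    from dataclasses import replace

    waists = []
    hips = []
    for scale in (0.9, 1.0, 1.1, 1.2):
        semi = dict(male_params.semi_axes)
        semi["waist"] = male_params.semi_axes["waist"] * scale
        ms = named_measurements(build_mesh(replace(male_params,
                                                   semi_axes=semi)))
        waists.append(ms.named["waist"])
        hips.append(ms.named["hip"])
    assert all(w1 < w2 for w1, w2 in zip(waists, waists[1:]))
    assert max(hips) - min(hips) <= 0.002 * min(hips)


def test_mesh_height_and_resolution_convergence(male_params):
    mesh = build_mesh(male_params)
    extent = mesh.vertices[:, 1].max() - mesh.vertices[:, 1].min()
    assert extent == pytest.approx(male_params.height, rel=0.005)
    lo = named_measurements(build_mesh(male_params, angular_resolution=64))
    hi = named_measurements(build_mesh(male_params, angular_resolution=256))
    for k in lo.named:
        assert lo.named[k] == pytest.approx(hi.named[k], rel=0.005)


def test_build_mesh_validates_arguments(male_params):
    with pytest.raises(ValueError):
        build_mesh(male_params, angular_resolution=8)
    with pytest.raises(ValueError):
        build_mesh(male_params, stations=5)


def test_arm_torso_interference_advises_pose():
    from dataclasses import replace

    big = {k: (2.1 * v if k in ("waist", "chest") else v)
           for k, v in REQUESTED.items()}
    big["chest"] = min(big["chest"], 1750.0)
    big["waist"] = min(big["waist"], 1490.0)
    params = shape_from_measurements(big, "male", 1.45)
    params = replace(params, shoulder_abduction_deg=2.0)
    with pytest.raises(ValueError, match="abduction|pose"):
        build_mesh(params)


def test_cohort_meshes_closed_and_fully_labeled():
    subjects = quick_subjects("female", 25, seed=7)
    for s in subjects:
        mesh = build_mesh(s.params, angular_resolution=16, stations=20)
        assert len(mesh.face_labels) == len(mesh.faces)
        assert set(np.unique(mesh.face_labels)) <= set(PART_CLASSES)
        assert np.all(mesh.vertices[:, 1] >= 0)
        tm = mesh.to_trimesh()
        for comp in tm.split(only_watertight=False):
            assert comp.is_watertight


def test_sample_cohort_pipeline_end_to_end():
    subjects = sample_cohort(default_population("male"), 25, seed=2,
                             bootstrap_n=600, max_clusters=3)
    assert len(subjects) == 25
    whr = [s.requested["waist"] / s.requested["hip"] for s in subjects]
    assert 0.6 < np.mean(whr) < 1.2
    for s in subjects:
        for m in MEASUREMENT_NAMES:
            lo, hi = DEFAULT_BOUNDS[m]
            assert lo <= s.requested[m] <= hi
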