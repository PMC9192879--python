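"""Registration, signed distances, parcellation and colour-map export."""

import numpy as np
import pytest
import trimesh

from condylar import surface_morphology as sm
from condylar.imaging_io import SurfaceMesh, read_mesh


def _icosphere(radius=10.0, subdivisions=3):
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(s.vertices), np.asarray(s.faces))


def test_rigid_transform_validation():
    with pytest.raises(ValueError):
        sm.RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))  # reflection
    t = sm.RigidTransform.identity()
    np.testing.assert_allclose(t.matrix, np.eye(4))


def test_rigid_transform_compose_inverse(rng):
    from scipy.spatial.transform import Rotation

    a = sm.RigidTransform(Rotation.random(random_state=1).as_matrix(), rng.normal(size=3))
    b = a.compose(a.inverse())
    np.testing.assert_allclose(b.matrix, np.eye(4), atol=1e-12)


def test_register_identical_meshes_gives_identity(phantom_t0_coarse):
    _, study, _ = phantom_t0_coarse
    res = sm.register_rigid(study.mesh, study.mesh)
    assert res.rms < 1e-6
    assert res.transform.rotation_angle_deg() < 1e-4
    assert not res.warning


def test_register_recovers_known_motion(phantom_t0_coarse):
    _, study, _ = phantom_t0_coarse
    R = trimesh.transformations.rotation_matrix(
        np.radians(10.0), [0.2, 0.5, 0.84], point=[0.0, 0.0, 30.0]
    )
    R[:3, 3] += [2.0, 1.0, 0.0]
    moving = study.mesh.transformed(R)
    res = sm.register_rigid(moving, study.mesh)
    residual = res.transform.matrix @ R
    assert sm.RigidTransform.from_matrix(residual).rotation_angle_deg() < 0.1
    disp = (
        trimesh.transformations.transform_points(study.mesh.vertices, residual)
        - study.mesh.vertices
    )
    assert np.abs(disp).max() < 0.05


def test_register_with_vertex_noise(phantom_t0_coarse, rng):
    _, study, _ = phantom_t0_coarse
    R = trimesh.transformations.rotation_matrix(np.radians(10.0), [0, 1, 0], point=[0, 0, 30.0])
    v = np.asarray(study.mesh.transformed(R).vertices).copy()
    idx = rng.choice(len(v), size=int(0.3 * len(v)), replace=False)
    v[idx] += rng.normal(0.0, 0.1, (len(idx), 3))
    res = sm.register_rigid(SurfaceMesh(v, study.mesh.faces), study.mesh)
    residual = res.transform.matrix @ R
    assert sm.RigidTransform.from_matrix(residual).rotation_angle_deg() < 0.5


def test_signed_distance_identical_meshes_zero():
    sphere = _icosphere()
    d = sm.signed_distances(sphere, sphere)
    np.testing.assert_allclose(d.distances, 0.0, atol=1e-9)


def test_signed_distance_concentric_spheres():
    # query vertices lie exactly on their sphere; targets are tessellated
    # finely enough that facet sag (~r*theta^2/8) is below the tolerance
    inner_q, outer_q = _icosphere(10.0), _icosphere(10.5)
    inner_t, outer_t = _icosphere(10.0, subdivisions=6), _icosphere(10.5, subdivisions=6)
    d = sm.signed_distances(inner_q, outer_t)
    # inflation = apposition = positive everywhere
    assert np.all(d.distances > 0)
    np.testing.assert_allclose(d.distances, 0.5, atol=1e-3)
    back = sm.signed_distances(outer_q, inner_t)
    np.testing.assert_allclose(back.distances, -0.5, atol=1e-3)


def test_partition_examples_and_totality():
    sphere = _icosphere(10.0)
    frame = sm.CondylarFrame(
        superior=(0, 0, 1), anterior=(0, -1, 0), medial=(1, 0, 0), center=(0, 0, 0)
    )
    labels = sm.partition_condylar_surface(sphere, frame)
    assert set(np.unique(labels.labels)) == set(sm.SURFACE_LABELS)  # total partition
    v = sphere.vertices
    top = np.argmax(v[:, 2])
    assert labels.labels[top] == "superior"
    ant = np.argmin(v[:, 1])  # anterior pole (equator)
    assert labels.labels[ant] == "anterior"
    med = np.argmax(v[:, 0])
    assert labels.labels[med] == "medial"


def test_partition_equivariant_under_joint_rotation(rng):
    from scipy.spatial.transform import Rotation  # noqa: F811

    # a generic pre-rotation keeps vertices off the exact sector boundaries,
    # where float jitter could legitimately flip a label
    sphere = _icosphere(10.0, subdivisions=2)
    R0 = Rotation.from_rotvec([0.31, 0.17, 0.23]).as_matrix()
    M0 = np.eye(4)
    M0[:3, :3] = R0
    sphere = sphere.transformed(M0)
    frame = sm.CondylarFrame(
        superior=(0, 0, 1), anterior=(0, -1, 0), medial=(1, 0, 0), center=(0, 0, 0)
    )
    base = sm.partition_condylar_surface(sphere, frame)
    for _ in range(5):
        R = Rotation.random(random_state=int(rng.integers(0, 2**31))).as_matrix()
        M = np.eye(4)
        M[:3, :3] = R
        rotated = sphere.transformed(M)
        labels = sm.partition_condylar_surface(rotated, frame.rotated(R))
        assert np.array_equal(labels.labels, base.labels)


def test_per_surface_means_uniform_map():
    sphere = _icosphere(10.0)
    frame = sm.CondylarFrame(superior=(0, 0, 1), anterior=(0, -1, 0), medial=(1, 0, 0), center=(0, 0, 0))
    labels = sm.partition_condylar_surface(sphere, frame)
    dmap = sm.DistanceMap(np.full(sphere.n_vertices, 0.5))
    means = sm.per_surface_means(dmap, labels)
    for region in sm.SURFACE_LABELS:
        assert means[region]["mean"] == pytest.approx(0.5)


def test_per_surface_means_empty_class_reported_missing():
    sphere = _icosphere(10.0)
    labels = sm.SurfaceLabelField(np.array(["anterior"] * sphere.n_vertices))
    dmap = sm.DistanceMap(np.zeros(sphere.n_vertices))
    means = sm.per_surface_means(dmap, labels)
    assert means["anterior"]["n_vertices"] == sphere.n_vertices
    assert np.isnan(means["posterior"]["mean"]) and means["posterior"]["n_vertices"] == 0


def test_colormap_export_colors_and_scalars(tmp_path):
    sphere = _icosphere(5.0, subdivisions=1)
    d = np.zeros(sphere.n_vertices)
    d[0], d[1] = 1.0, -1.0
    path = tmp_path / "map.ply"
    sm.export_colormap(sphere, sm.DistanceMap(d), path, dmax=1.0)
    back = read_mesh(path)
    assert back.scalars is not None
    np.testing.assert_allclose(back.scalars, d, atol=1e-6)
    tm = trimesh.load(str(path), process=False)
    colors = np.asarray(tm.visual.vertex_colors)[:, :3]
    np.testing.assert_array_equal(colors[0], [255, 0, 0])  # saturated red
    np.testing.assert_array_equal(colors[1], [0, 0, 255])  # saturated blue
    assert np.all(colors[2:] == 255)  # neutral midpoint is white


def test_phantom_offsets_antisymmetric(phantom_pair_fine):
    """Swapping reference/target flips the per-region mean signs."""
    spec, t0, t1, truth, measured = phantom_pair_fine
    from condylar import pipeline, surface_morphology

    reg = surface_morphology.register_rigid(t0.mesh, t1.mesh)
    t0_reg = t0.mesh.transformed(reg.transform.matrix)
    apex = t1.landmarks.get("condyle_apex", t1.side)
    axis_down = t1.landmarks["ramus_axis_inferior"] - t1.landmarks["ramus_axis_superior"]
    axis_down = axis_down / np.linalg.norm(axis_down)
    head, _ = surface_morphology.extract_head_submesh(t1.mesh, apex, axis_down)
    dmap = surface_morphology.signed_distances(head, t0_reg)
    frame = surface_morphology.CondylarFrame.from_landmarks(t1.landmarks, t1.side)
    labels = surface_morphology.partition_condylar_surface(head, frame)
    reverse = surface_morphology.per_surface_means(dmap, labels)
    for region in sm.SURFACE_LABELS:
        assert reverse[region]["mean"] == pytest.approx(
            -measured.surface_means_mm[region], abs=0.05
        )
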