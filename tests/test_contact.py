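"""Penetration volumes, the pressure-module contact law, mesh handling."""

import numpy as np
import pytest
import trimesh
from hypothesis import given
from hypothesis import strategies as st

from wristsim import (
    ContactPair,
    HalfSpaceSurface,
    MeshSurface,
    SphereSurface,
    ValidationError,
    contact_force,
    penetration_volume,
)
from wristsim.contact import spherical_cap_volume


class TestPenetrationVolume:
    def test_separated_spheres(self):
        a = SphereSurface((0, 0, 0), 0.005)
        b = SphereSurface((0, 0, 0.02), 0.005)
        vol, normal = penetration_volume(a, b)
        assert vol == 0.0 and normal is None

    def test_engulfed_sphere_full_volume(self):
        r = 0.004
        sphere = SphereSurface((0, 0, -0.01), r)
        half = HalfSpaceSurface((0, 0, 0), (0, 0, 1))
        vol, _ = penetration_volume(sphere, half)
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * r**3, rel=1e-12)

    @pytest.mark.parametrize("depth", [0.0005, 0.001, 0.002])
    def test_cap_closed_form(self, depth):
        r = 0.008
        sphere = SphereSurface((0, 0, r - depth), r)
        half = HalfSpaceSurface((0, 0, 0), (0, 0, 1))
        vol, normal = penetration_volume(sphere, half)
        assert vol == pytest.approx(np.pi * depth**2 * (3 * r - depth) / 3, rel=1e-12)
        np.testing.assert_allclose(normal, (0, 0, 1))

    def test_displacement_shifts_surface_a(self):
        sphere = SphereSurface((0, 0, 0.009), 0.008)  # 1 mm clearance
        half = HalfSpaceSurface((0, 0, 0), (0, 0, 1))
        assert penetration_volume(sphere, half)[0] == 0.0
        vol, _ = penetration_volume(sphere, half, displacement_a=(0, 0, -0.0015))
        assert vol == pytest.approx(spherical_cap_volume(0.008, 0.0005), rel=1e-12)

    def test_sphere_sphere_lens_symmetry(self):
        a = SphereSurface((0, 0, 0), 0.006)
        b = SphereSurface((0, 0, 0.008), 0.004)
        v1, n1 = penetration_volume(a, b)
        v2, n2 = penetration_volume(b, a)
        assert v1 == pytest.approx(v2, rel=1e-12)
        np.testing.assert_allclose(n1, -np.asarray(n2))
        assert v1 > 0

    def test_voxel_oracle_matches_cap_within_2pc(self):
        """Voxelized mesh estimate vs the analytic spherical cap at 0.2 mm.

        The icosphere is refined enough (subdivision 4) that the polyhedral
        volume deficit stays well below the voxel sampling error.
        """
        r, depth = 0.008, 0.002
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=r)
        mesh.apply_translation((0, 0, r - depth))
        half = HalfSpaceSurface((0, 0, 0), (0, 0, 1))
        vol, _ = penetration_volume(MeshSurface(mesh), half, pitch=2e-4)
        assert vol == pytest.approx(spherical_cap_volume(r, depth), rel=0.02)

    def test_mesh_mesh_lens_coarse(self):
        """Two coarse icospheres against the sphere-sphere closed form;
        tolerance reflects the subdivision-3 polyhedral volume deficit."""
        a = trimesh.creation.icosphere(3, 0.005)
        b = trimesh.creation.icosphere(3, 0.005)
        b.apply_translation((0, 0, 0.008))
        vol, _ = penetration_volume(MeshSurface(a), MeshSurface(b), pitch=1e-4)
        exact, _ = penetration_volume(
            SphereSurface((0, 0, 0), 0.005), SphereSurface((0, 0, 0.008), 0.005)
        )
        assert vol == pytest.approx(exact, rel=0.05)

    def test_non_watertight_mesh_rejected(self):
        mesh = trimesh.creation.icosphere(2, 0.005)
        mesh.update_faces(np.arange(len(mesh.faces) - 5))  # punch a hole
        with pytest.raises(ValidationError):
            MeshSurface(mesh)


class TestContactForce:
    def test_zero_volume_zero_force(self):
        np.testing.assert_array_equal(contact_force(0.6e10, 0.0, (0, 0, 1)), 0.0)

    @given(
        pm=st.floats(1e9, 1e11),
        vol=st.floats(0.0, 1e-7),
        scale=st.floats(1.1, 5.0),
    )
    def test_linearity_in_pm_and_volume(self, pm, vol, scale):
        base = contact_force(pm, vol, (0, 0, 1))
        np.testing.assert_allclose(contact_force(scale * pm, vol, (0, 0, 1)),
                                   scale * base, rtol=1e-12)
        np.testing.assert_allclose(contact_force(pm, scale * vol, (0, 0, 1)),
                                   scale * base, rtol=1e-12)

    def test_magnitude_is_pm_times_volume(self):
        f = contact_force(0.6e10, 2.0e-8, (0, 0, 1))
        assert np.linalg.norm(f) == pytest.approx(120.0, rel=1e-12)

    def test_direction_along_normal(self):
        n = np.array([1.0, 2.0, 2.0]) / 3.0
        f = contact_force(1e10, 1e-8, n)
        np.testing.assert_allclose(f / np.linalg.norm(f), n, rtol=1e-12)


class TestContactPair:
    def test_no_overlap_no_force(self):
        pair = ContactPair(
            "toy",
            SphereSurface((0, 0, 0.010), 0.008),
            HalfSpaceSurface((0, 0, 0), (0, 0, 1)),
            0.6e10,
        )
        f, vol = pair.force()
        assert vol == 0.0
        np.testing.assert_array_equal(f, 0.0)

    def test_force_pushes_surfaces_apart(self):
        pair = ContactPair(
            "toy",
            SphereSurface((0, 0, 0.007), 0.008),
            HalfSpaceSurface((0, 0, 0), (0, 0, 1)),
            0.6e10,
        )
        f, vol = pair.force()
        assert vol > 0 and f[2] > 0  # pushes the sphere out of the floor
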