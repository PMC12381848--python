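"""Cylindrical sector assignment, occupancy and projection stratification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confscape.sectors import (
    GeometryError,
    SectorGeometry,
    SectorTrace,
    assign_sectors,
    center_of_mass,
    cylindrical_coordinates,
    particle_frame,
    sector_azimuth_center,
    sector_occupancy,
    stratify_projection,
)
from confscape.synthetic import SectorSystemSpec, generate_sector_system


@pytest.fixture(scope="module")
def system():
    spec = SectorSystemSpec(
        10, 20, 10,
        sector_schedule=((1, 80), (0, 20), (2, 30), (3, 10), (7, 10)),
        seed=21,
    )
    ensemble, truth = generate_sector_system(spec)
    return spec, ensemble, truth


class TestGeometry:
    def test_unbound_threshold_maps_to_sector_zero(self):
        geo = SectorGeometry(unbound_radius=50.0)
        particle = SectorSystemSpec(4, 8, 4, sector_schedule=((1, 1),)).reference_particle()
        far = np.array([[200.0, 0.0, 0.0]])
        trace = assign_sectors(far, particle, geo)
        assert trace.sector[0] == 0

    def test_dyad_direction_is_sector_one(self):
        spec = SectorSystemSpec(4, 8, 4, sector_schedule=((1, 1),), reference_radius=40.0)
        particle = spec.reference_particle()
        origin, axes = particle_frame(particle)
        point = origin + 45.0 * axes[0]  # along the dyad, inside the unbound radius
        trace = assign_sectors(point[None], particle, spec.default_geometry())
        assert trace.sector[0] == 1

    def test_invalid_geometry_rejected(self):
        with pytest.raises(GeometryError):
            SectorGeometry(unbound_radius=-1.0)
        with pytest.raises(GeometryError):
            SectorGeometry(unbound_radius=10.0, boundaries=((0.0, 1.0),) * 7)

    def test_custom_covering_boundaries_accepted(self):
        width = 2 * np.pi / 7
        bounds = tuple(((i * width) - np.pi, ((i + 1) * width) - np.pi) for i in range(7))
        geo = SectorGeometry(unbound_radius=10.0, boundaries=bounds)
        s = geo.azimuthal_sector(np.array([-np.pi + 0.01, 0.0, np.pi - 0.01]))
        assert s.min() >= 1 and s.max() <= 7

    def test_particle_frame_is_deterministic_and_orthonormal(self):
        particle = SectorSystemSpec(4, 8, 4, sector_schedule=((1, 1),)).reference_particle()
        origin, axes = particle_frame(particle)
        assert np.allclose(axes @ axes.T, np.eye(3), atol=1e-12)
        origin2, axes2 = particle_frame(particle)
        assert np.array_equal(axes, axes2)


class TestRoundTrip:
    def test_ground_truth_recovery_at_least_99_percent(self, system):
        spec, ensemble, truth = system
        trace = assign_sectors(
            center_of_mass(ensemble.xyz, spec.globular_slice),
            spec.reference_particle(),
            spec.default_geometry(),
        )
        recovery = np.mean(trace.sector == truth.sector)
        assert recovery >= 0.99

    def test_cylindrical_coordinates_match_schedule(self, system):
        spec, ensemble, truth = system
        trace = assign_sectors(
            center_of_mass(ensemble.xyz, spec.globular_slice),
            spec.reference_particle(),
            spec.default_geometry(),
        )
        assert np.allclose(trace.r, truth.r, atol=1e-6)
        assert np.allclose(trace.z, truth.z, atol=1e-6)


class TestOccupancy:
    def test_constructed_schedule_reproduces_percentages(self):
        trace = SectorTrace(
            r=np.zeros(1000), theta=np.zeros(1000), z=np.zeros(1000),
            sector=np.repeat([1, 0, 2, 3, 7], [783, 101, 98, 13, 5]),
        )
        occ = sector_occupancy(trace)
        assert occ[1] == pytest.approx(78.3)
        assert occ[0] == pytest.approx(10.1)
        assert occ[2] == pytest.approx(9.8)
        assert occ[3] == pytest.approx(1.3)
        assert occ[7] == pytest.approx(0.5)
        assert occ[4] == occ[5] == occ[6] == 0.0

    def test_single_sector_is_hundred_percent(self):
        trace = SectorTrace(r=np.zeros(5), theta=np.zeros(5), z=np.zeros(5), sector=np.zeros(5, int))
        assert sector_occupancy(trace)[0] == 100.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 7), min_size=1, max_size=200))
    def test_percentages_always_sum_to_100(self, sectors):
        n = len(sectors)
        trace = SectorTrace(
            r=np.zeros(n), theta=np.zeros(n), z=np.zeros(n), sector=np.array(sectors)
        )
        assert sector_occupancy(trace).sum() == pytest.approx(100.0, abs=1e-9)


class TestStratification:
    def test_partition_covers_all_frames(self, system, rng):
        spec, ensemble, truth = system
        coords = rng.uniform(size=(ensemble.n_frames, 2))
        strata = stratify_projection(coords, truth)
        sizes = sum(len(v) for v in strata.values())
        assert sizes == ensemble.n_frames
        all_idx = np.sort(np.concatenate(list(strata.values())))
        assert np.array_equal(all_idx, np.arange(ensemble.n_frames))

    def test_single_sector_returns_everything(self):
        trace = SectorTrace(r=np.zeros(7), theta=np.zeros(7), z=np.zeros(7), sector=np.ones(7, int))
        strata = stratify_projection(np.zeros((7, 2)), trace)
        assert list(strata) == [1] and len(strata[1]) == 7

    def test_length_mismatch_rejected(self):
        trace = SectorTrace(r=np.zeros(5), theta=np.zeros(5), z=np.zeros(5), sector=np.zeros(5, int))
        with pytest.raises(ValueError):
            stratify_projection(np.zeros((4, 2)), trace)

    def test_motif_bearing_sector_concentrates_in_projection(self):
        # frames in sector 2 carry a distinct conformational motif: engineered by
        # concatenating two different polymer populations and checking that the
        # sector-2 subset has a different KDE mode than sector 1
        from confscape.dissimilarity import dissimilarity_matrix
        from confscape.landscape import kde_density
        from confscape.projection import force_scheme
        from confscape.synthetic import PolymerSpec, generate_polymer_ensemble

        plain = generate_polymer_ensemble(PolymerSpec(20, compactness=0.3, seed=31), 60)
        motif = generate_polymer_ensemble(
            PolymerSpec(20, compactness=0.3, exclusive_motif=((1, 18, 6.0), (4, 15, 6.0)), seed=32), 60
        )
        xyz = np.concatenate([plain.xyz, motif.xyz])
        sector = np.repeat([1, 2], 60)
        trace = SectorTrace(r=np.zeros(120), theta=np.zeros(120), z=np.zeros(120), sector=sector)
        proj = force_scheme(dissimilarity_matrix(xyz), seed=2)
        strata = stratify_projection(proj.coords, trace)
        dens = kde_density(proj)
        mode1 = proj.coords[strata[1][np.argmax(dens[strata[1]])]]
        mode2 = proj.coords[strata[2][np.argmax(dens[strata[2]])]]
        spread = proj.coords.std()
        assert np.linalg.norm(mode1 - mode2) > 0.5 * spread
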