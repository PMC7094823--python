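"""Geometry builder: stenciling, membranes, organelles, invariants."""

import math

import numpy as np
import pytest
from scipy import ndimage

from splicesim.geometry import (
    GeometryConfig,
    LatticeSpec,
    SiteLattice,
    SiteType,
    Sphere,
    SphericalShell,
    Spherocylinder,
    build_cell,
    build_membranes,
    fibonacci_sphere,
    grow_er,
    leak_adjacencies,
    place_genes,
    place_mitochondria,
    place_npcs,
    place_speckles,
    speckle_radius_for_fraction,
    stencil_primitive,
    volume_fraction,
)

SIX = ndimage.generate_binary_structure(3, 1)


def empty(edge, spacing, seed=0):
    return SiteLattice.empty(LatticeSpec(edge, spacing), seed=seed)


class TestStencil:
    @pytest.mark.parametrize("radius", [0.8, 1.2])
    def test_sphere_voxel_volume_converges(self, radius):
        # r >= 10 lambda: voxelized volume within 1% of 4/3 pi r^3
        lat = empty(3.2, 0.064)
        stencil_primitive(lat, Sphere((1.6, 1.6, 1.6), radius), SiteType.CYTOPLASM)
        v = lat.count(SiteType.CYTOPLASM) * lat.spec.site_volume
        assert v == pytest.approx(4 / 3 * math.pi * radius**3, rel=0.01)

    def test_default_cell_sphere_volume(self):
        # the 8.9 um cell in the default 18.432 um box: ~2953 um^3 within 1%
        lat = empty(18.432, 0.064)
        c = tuple(lat.center)
        stencil_primitive(lat, Sphere(c, 8.9), SiteType.CYTOPLASM)
        v = lat.count(SiteType.CYTOPLASM) * lat.spec.site_volume
        assert v == pytest.approx(4 / 3 * math.pi * 8.9**3, rel=0.01)
        # extracellular fraction of the whole box, analytic
        extr = lat.count(SiteType.EXTRACELLULAR) / lat.sites.size
        assert extr == pytest.approx(1 - (4 / 3 * math.pi * 8.9**3) / 18.432**3,
                                     abs=0.005)

    def test_zero_radius_paints_nothing(self):
        lat = empty(1.28, 0.064)
        stencil_primitive(lat, Sphere((0.6, 0.6, 0.6), 0.0), SiteType.SPECKLE)
        assert lat.count(SiteType.SPECKLE) == 0

    def test_later_painter_wins(self):
        lat = empty(1.28, 0.064)
        stencil_primitive(lat, Sphere((0.6, 0.6, 0.6), 0.3), SiteType.NUCLEOPLASM)
        stencil_primitive(lat, Sphere((0.7, 0.6, 0.6), 0.3), SiteType.SPECKLE)
        # overlap region carries the later code
        assert lat.sites[tuple(lat.index_of((0.65, 0.6, 0.6)))] == int(
            SiteType.SPECKLE
        )

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            Sphere((0, 0, 0), -1.0)
        with pytest.raises(ValueError):
            Spherocylinder((0, 0, 0), (1, 0, 0), 0.0)
        with pytest.raises(ValueError):
            SphericalShell((0, 0, 0), 0.5, 0.4)


class TestMembranes:
    def test_default_shells_are_closed(self):
        lat = empty(6.4, 0.064)
        build_membranes(lat, 2.8, 1.4, 0.128)
        plasma, nuclear = leak_adjacencies(lat)
        assert plasma == 0 and nuclear == 0

    def test_one_site_thick_shell_still_closed(self):
        lat = empty(6.4, 0.064)
        build_membranes(lat, 2.8, 1.4, 0.064)
        plasma, nuclear = leak_adjacencies(lat)
        assert plasma == 0 and nuclear == 0

    def test_too_thin_shell_rejected(self):
        lat = empty(6.4, 0.064)
        with pytest.raises(ValueError, match="leak"):
            build_membranes(lat, 2.8, 1.4, 0.05)

    def test_nuclear_shell_volume_matches_thin_shell_estimate(self):
        lat = empty(12.8, 0.064)
        build_membranes(lat, 6.0, 4.2, 0.128)
        v = lat.count(SiteType.NUCLEAR_MEMBRANE) * lat.spec.site_volume
        assert v == pytest.approx(4 * math.pi * 4.2**2 * 0.128, rel=0.10)


@pytest.fixture(scope="module")
def nucleus():
    lat = empty(12.8, 0.064)
    build_membranes(lat, 6.0, 4.2, 0.128)
    lat.config = GeometryConfig(
        edge_length=12.8, spacing=0.064, cell_radius=6.0, nuclear_radius=4.2
    )
    return lat


class TestNPCs:

    def test_count_formula(self, nucleus):
        import copy

        lat = copy.deepcopy(nucleus)
        _, count = place_npcs(lat, 7.0, 0.08)
        expected = round(7.0 * 4 * math.pi * 4.2**2)
        assert count == expected == 1552
        # measured pore censuses for a 4.2 um nucleus land near 1515;
        # the density-times-area formula agrees within 5%
        assert abs(count - 1515) / 1515 < 0.05
        # pores punch through: nucleoplasm and cytoplasm both touch NPC sites
        npc = lat.sites == int(SiteType.NPC)
        grown = ndimage.binary_dilation(npc, SIX)
        assert np.any(grown & (lat.sites == int(SiteType.NUCLEOPLASM)))
        assert np.any(grown & (lat.sites == int(SiteType.CYTOPLASM)))
        # no leaks that bypass the pores
        assert leak_adjacencies(lat) == (0, 0)

    def test_zero_density(self, nucleus):
        import copy

        lat = copy.deepcopy(nucleus)
        _, count = place_npcs(lat, 0.0, 0.08)
        assert count == 0 and lat.count(SiteType.NPC) == 0

    def test_counts_scale_with_density(self, nucleus):
        import copy

        counts = {}
        for sc in (0.8, 1.2):
            lat = copy.deepcopy(nucleus)
            _, counts[sc] = place_npcs(lat, 7.0 * sc, 0.08)
        assert counts[1.2] / counts[0.8] == pytest.approx(1.2 / 0.8, rel=0.01)

    def test_negative_density_rejected(self, nucleus):
        with pytest.raises(ValueError):
            place_npcs(nucleus, -1.0, 0.08)

    def test_fibonacci_layout_is_uniformish(self):
        pts = fibonacci_sphere(500)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        # octant occupancy should be balanced
        octants = ((pts > 0) * [1, 2, 4]).sum(axis=1)
        counts = np.bincount(octants, minlength=8)
        assert counts.min() > 0.7 * counts.max()


class TestER:
    @pytest.fixture()
    def shell_cell(self):
        lat = empty(6.4, 0.1)
        build_membranes(lat, 3.0, 1.5, 0.2)
        lat.config = GeometryConfig(
            edge_length=6.4, spacing=0.1, cell_radius=3.0, nuclear_radius=1.5,
            membrane_thickness=0.2,
        )
        return lat

    def test_fraction_hits_target(self, shell_cell):
        grow_er(shell_cell, 0.045, seed=3)
        assert volume_fraction(shell_cell, SiteType.ER) == pytest.approx(
            0.045, abs=0.002
        )

    def test_zero_target(self, shell_cell):
        grow_er(shell_cell, 0.0, seed=3)
        assert shell_cell.count(SiteType.ER) == 0

    def test_seeded_determinism(self):
        lats = []
        for _ in range(2):
            lat = empty(6.4, 0.1)
            build_membranes(lat, 3.0, 1.5, 0.2)
            grow_er(lat, 0.03, seed=7)
            lats.append(lat.sites.copy())
        assert np.array_equal(*lats)
        lat = empty(6.4, 0.1)
        build_membranes(lat, 3.0, 1.5, 0.2)
        grow_er(lat, 0.03, seed=8)
        er_a = lats[0] == int(SiteType.ER)
        er_b = lat.sites == int(SiteType.ER)
        assert er_a.sum() == er_b.sum()  # same fraction ...
        assert not np.array_equal(er_a, er_b)  # ... different shapes

    def test_unreachable_target_names_maximum(self, shell_cell):
        with pytest.raises(ValueError, match="unreachable"):
            grow_er(shell_cell, 0.99, seed=1)


class TestMitochondria:
    @pytest.fixture()
    def cyto_cell(self):
        lat = empty(18.432, 0.128)
        build_membranes(lat, 8.9, 4.2, 0.128)
        lat.config = GeometryConfig(
            edge_length=18.432, spacing=0.128, cell_radius=8.9, nuclear_radius=4.2
        )
        return lat

    def test_discrete_volume_fraction(self, cyto_cell):
        place_mitochondria(cyto_cell, 2000, seed=5)
        frac = volume_fraction(cyto_cell, SiteType.MITOCHONDRIA)
        # 2000 x 0.144 um^3 in a ~3000 um^3 cell
        assert 0.09 <= frac <= 0.12

    def test_network_mode_matches_discrete_volume(self, cyto_cell):
        import copy

        lat2 = copy.deepcopy(cyto_cell)
        place_mitochondria(cyto_cell, 300, seed=5, mode="discrete")
        place_mitochondria(lat2, 300, seed=5, mode="network")
        v1 = cyto_cell.count(SiteType.MITOCHONDRIA)
        v2 = lat2.count(SiteType.MITOCHONDRIA)
        assert abs(v2 - v1) / v1 < 0.02

    def test_zero_count(self, cyto_cell):
        place_mitochondria(cyto_cell, 0, seed=5)
        assert cyto_cell.count(SiteType.MITOCHONDRIA) == 0

    def test_containment_in_cytoplasm(self, cyto_cell):
        place_mitochondria(cyto_cell, 100, seed=5)
        mito = cyto_cell.sites == int(SiteType.MITOCHONDRIA)
        # nothing outside the plasma membrane or inside the nucleus
        ax = cyto_cell.site_centers_axis() - cyto_cell.center[0]
        r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2
                    + ax[None, None, :] ** 2)
        assert np.all(r[mito] > 4.2)
        assert np.all(r[mito] < 8.9)


class TestSpecklesAndGenes:
    def test_radius_formula(self):
        # 10% of a 4.2 um nucleus over n speckles
        d20 = 2 * speckle_radius_for_fraction(20, 0.10, 4.2)
        d50 = 2 * speckle_radius_for_fraction(50, 0.10, 4.2)
        assert d20 == pytest.approx(1.436, abs=0.01)
        assert d50 == pytest.approx(1.058, abs=0.01)

    def test_single_speckle_is_connected(self):
        lat = empty(6.4, 0.064)
        build_membranes(lat, 3.0, 2.2, 0.128)
        lat.config = GeometryConfig(
            edge_length=6.4, spacing=0.064, cell_radius=3.0, nuclear_radius=2.2
        )
        place_speckles(lat, 1, radius=0.35, seed=2)
        _, n_comp = ndimage.label(lat.sites == int(SiteType.SPECKLE), SIX)
        assert n_comp == 1

    @pytest.fixture()
    def nucleus_with_speckles(self):
        lat = empty(10.24, 0.064)
        build_membranes(lat, 5.0, 4.2, 0.128)
        lat.config = GeometryConfig(
            edge_length=10.24, spacing=0.064, cell_radius=5.0, nuclear_radius=4.2
        )
        place_speckles(lat, 8, radius=0.35, seed=2)
        return lat

    def test_genes_hug_the_speckle_surface(self, nucleus_with_speckles):
        lat = nucleus_with_speckles
        place_genes(lat, 16, distance=0.0, shell_width=0.02, seed=3)
        assert lat.gene_positions.shape == (16, 3)
        lam = lat.spec.spacing
        speckles = [
            (np.asarray(o.center), o.radius)
            for k, o, st in lat.placed_objects
            if k == "Sphere" and st == SiteType.SPECKLE
        ]
        for idx, p in zip(lat.gene_positions, lat.gene_coords):
            assert lat.sites[tuple(idx)] == int(SiteType.NUCLEOPLASM)
            d = min(np.linalg.norm(p - c) - r for c, r in speckles)
            assert -1e-9 <= d <= 0.02 + lam

    def test_mean_distance_monotone_in_d(self, nucleus_with_speckles):
        lat = nucleus_with_speckles
        speckles = [
            (np.asarray(o.center), o.radius)
            for k, o, st in lat.placed_objects
            if k == "Sphere" and st == SiteType.SPECKLE
        ]
        means = []
        for d in (0.05, 0.2, 0.5, 0.9):
            place_genes(lat, 12, distance=d, shell_width=0.02, seed=4)
            dist = [
                min(np.linalg.norm(p - c) - r for c, r in speckles)
                for p in lat.gene_coords
            ]
            means.append(np.mean(dist))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_zero_genes(self, nucleus_with_speckles):
        place_genes(nucleus_with_speckles, 0, seed=1)
        assert nucleus_with_speckles.gene_positions.shape[0] == 0

    def test_unreachable_shell_rejected(self, nucleus_with_speckles):
        with pytest.raises(ValueError):
            place_genes(nucleus_with_speckles, 4, distance=50.0, seed=1)


class TestBuildCell:
    def test_all_11_site_types_present(self, small_cell):
        present = set(np.unique(small_cell.sites).tolist())
        assert present == {int(st) for st in SiteType}

    def test_organelle_free_cell_has_8_codes(self, small_cell_config):
        import dataclasses

        cfg = dataclasses.replace(
            small_cell_config, n_mitochondria=0, er_fraction=0.0, golgi_sheets=0
        )
        lat = build_cell(cfg)
        present = set(np.unique(lat.sites).tolist())
        assert present == {int(st) for st in SiteType} - {
            int(SiteType.MITOCHONDRIA), int(SiteType.GOLGI), int(SiteType.ER)
        }

    def test_intracellular_fractions_partition_unity(self, small_cell):
        total = sum(
            volume_fraction(small_cell, st)
            for st in SiteType
            if st != SiteType.EXTRACELLULAR
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_nuclear_bodies_stay_in_nucleus(self, small_cell):
        cfg = small_cell.config
        ax = small_cell.site_centers_axis() - small_cell.center[0]
        r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2
                    + ax[None, None, :] ** 2)
        for st in (SiteType.SPECKLE, SiteType.CAJAL):
            mask = small_cell.sites == int(st)
            assert np.all(r[mask] < cfg.nuclear_radius)
        for st in (SiteType.MITOCHONDRIA, SiteType.ER, SiteType.GOLGI):
            mask = small_cell.sites == int(st)
            assert np.all(r[mask] > cfg.nuclear_radius - small_cell.spec.spacing)

    def test_nucleus_volume_fraction_matches_spheres(self):
        # a 4.2 um nucleus in a 3000 um^3 cell occupies ~10.3%
        v_n = 4 / 3 * math.pi * 4.2**3
        assert v_n / 3000 == pytest.approx(0.1034, abs=0.001)

    def test_identical_config_and_seed_reproduce_bitwise(self, small_cell_config):
        a = build_cell(small_cell_config)
        b = build_cell(small_cell_config)
        assert np.array_equal(a.sites, b.sites)
        assert np.array_equal(a.gene_positions, b.gene_positions)

    def test_volume_fraction_rejects_unknown_code(self, small_cell):
        with pytest.raises(ValueError):
            volume_fraction(small_cell, 99)
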