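"""Shell counting, Shrake–Rupley SASA and ensemble averaging."""

import math

import numpy as np
import pytest
import biotite.structure as struc

from metox.descriptors import (
    DescriptorParams,
    VDW_RADII,
    count_within_radius,
    ensemble_descriptors,
    relative_sasa,
    shrake_rupley,
    sidechain_sasa,
)
from metox.structure import (
    select_methionines,
    select_water_oxygens,
    strip_waters,
)
from metox.synthetic import ProbeSpec, build_ensemble, build_probe


def brute_force_count(frame, center, candidates, radius, box=None):
    """Independent all-pairs oracle for the shell count."""
    n = 0
    for j in candidates:
        if j == center:
            continue
        diff = frame[j] - frame[center]
        if box is not None:
            diff = diff - box * np.round(diff / box)
        if math.sqrt(float(diff @ diff)) <= radius:
            n += 1
    return n


class TestCountWithinRadius:
    def test_simple_distances(self):
        frame = np.array([[0, 0, 0], [3, 0, 0], [0, 5, 0], [0, 0, 7]], dtype=float)
        assert count_within_radius(frame, 0, [1, 2, 3], 6.0) == 2

    def test_boundary_is_inclusive(self):
        frame = np.array([[0, 0, 0], [6.0, 0, 0]])
        assert count_within_radius(frame, 0, [1], 6.0) == 1

    def test_minimum_image(self):
        frame = np.array([[0.5, 5, 5], [9.5, 5, 5]])
        box = np.array([10.0, 10.0, 10.0])
        # 9 Å apart directly, 1 Å through the boundary
        assert count_within_radius(frame, 0, [1], 2.0, box) == 1
        assert count_within_radius(frame, 0, [1], 2.0) == 0

    def test_small_box_is_ambiguous(self):
        frame = np.array([[0, 0, 0], [9, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="periodic image"):
            count_within_radius(frame, 0, [1], 6.0, np.array([10.0, 10.0, 10.0]))

    def test_center_excluded_from_candidates(self):
        frame = np.zeros((1, 3))
        assert count_within_radius(frame, 0, [0], 6.0) == 0

    @pytest.mark.parametrize("use_box", [False, True])
    def test_matches_brute_force_oracle(self, use_box):
        rng = np.random.default_rng(42 + use_box)
        for _ in range(60):
            n = rng.integers(2, 40)
            box = np.array([20.0, 25.0, 30.0]) if use_box else None
            frame = rng.uniform(0, 20, (n, 3))
            radius = rng.uniform(1.0, 8.0)
            center = int(rng.integers(0, n))
            candidates = rng.choice(n, size=rng.integers(1, n), replace=False)
            expected = brute_force_count(frame, center, candidates, radius, box)
            assert count_within_radius(frame, center, candidates, radius, box) == expected


class TestShrakeRupley:
    def test_isolated_atom_closed_form(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([1.7]))
        exact = 4 * math.pi * (1.7 + 1.4) ** 2
        assert area[0] == pytest.approx(exact, rel=0.01)

    def test_distant_atoms_are_full_spheres(self):
        frame = np.array([[0, 0, 0], [100.0, 0, 0]])
        areas = shrake_rupley(frame, np.array([1.7, 1.7]))
        exact = 4 * math.pi * 3.1**2
        assert np.allclose(areas, exact, rtol=0.01)

    def test_caged_atom_has_zero_area(self):
        from metox.descriptors import fibonacci_sphere

        cage = 2.0 * fibonacci_sphere(200)
        frame = np.vstack([[0.0, 0.0, 0.0], cage])
        radii = np.full(len(frame), 1.7)
        areas = shrake_rupley(frame, radii, targets=[0])
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_quadrature_convergence(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 8, (25, 3))
        radii = np.full(25, 1.7)
        a960 = shrake_rupley(coords, radii, DescriptorParams(sphere_points=960))
        a4000 = shrake_rupley(coords, radii, DescriptorParams(sphere_points=4000))
        assert abs(a960.sum() - a4000.sum()) / a4000.sum() < 0.02

    def test_area_non_increasing_as_neighbor_approaches(self):
        radii = np.array([1.7, 1.7])
        last = math.inf
        for distance in (8.0, 6.0, 5.0, 4.0, 3.0, 2.0):
            frame = np.array([[0, 0, 0], [distance, 0, 0]])
            area = shrake_rupley(frame, radii, targets=[0])[0]
            assert area <= last + 1e-9
            last = area

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            shrake_rupley(np.zeros((1, 3)), np.array([0.0]))

    @pytest.mark.parametrize("seed", [2, 5, 8])
    def test_matches_independent_implementation(self, seed):
        """biotite's Shrake–Rupley, fed the same radii, agrees within 5%."""
        model, _ = build_probe(
            ProbeSpec(n_waters_in=4, n_ser_in=1, n_tyr_in=1, seed=seed)
        )
        sub = model.subset(strip_waters(model))
        radii = np.array([VDW_RADII.get(e, 1.7) for e in sub.element])
        mine = shrake_rupley(sub.coords, radii)
        arr = struc.AtomArray(sub.n_atoms)
        arr.coord = sub.coords.astype(np.float32)
        arr.atom_name = sub.atom_name
        arr.element = sub.element
        arr.res_name = sub.res_name
        arr.chain_id = sub.chain_id
        arr.res_id = sub.res_id
        arr.hetero = sub.hetero
        oracle = struc.sasa(arr, probe_radius=1.4, point_number=1000, vdw_radii=radii)
        assert mine.sum() == pytest.approx(float(np.nansum(oracle)), rel=0.05)


class TestSidechainSasa:
    def test_exposed_probe_sidechain_is_mostly_accessible(self, solvated_probe):
        model, _ = solvated_probe
        site = select_methionines(model)[0]
        area = sidechain_sasa(model, site)
        assert relative_sasa(area, "MET") > 50.0

    def test_buried_sidechain_in_cage(self):
        model, _ = build_probe(
            ProbeSpec(cage=True, cage_rmin=2.6, cage_rmax=5.2, seed=1)
        )
        site = select_methionines(model)[0]
        assert sidechain_sasa(model, site) < 1.0

    def test_empty_sidechain_is_an_error(self, solvated_probe):
        from metox.structure import MethionineSite

        model, _ = solvated_probe
        site = select_methionines(model)[0]
        bare = MethionineSite(site.chain_id, site.residue_label,
                              site.sulfur_index, ())
        with pytest.raises(ValueError):
            sidechain_sasa(model, bare)


class TestRelativeSasa:
    @pytest.mark.parametrize(
        "area,expected", [(0.0, 0.0), (224.4, 100.0), (112.2, 50.0)]
    )
    def test_met_reference_scaling(self, area, expected):
        assert relative_sasa(area, "MET") == pytest.approx(expected)

    def test_unknown_residue_lists_known(self):
        with pytest.raises(KeyError, match="MET"):
            relative_sasa(10.0, "XYZ")

    def test_exceeding_reference_warns(self):
        with pytest.warns(UserWarning, match="exceeds"):
            relative_sasa(300.0, "MET")


class TestEnsembleDescriptors:
    def test_scheduled_means_are_exact(self):
        ens, truth = build_ensemble(ProbeSpec(n_ser_in=2, seed=5), [4, 8])
        (record,) = ensemble_descriptors(ens, select_methionines(ens.topology))
        assert record.WCN == pytest.approx(6.0, abs=0)
        assert record.OH == pytest.approx(2.0, abs=0)
        assert record.n_frames == 2

    def test_long_random_schedule_matches_bookkeeping(self):
        rng = np.random.default_rng(17)
        schedule = rng.integers(0, 7, size=40).tolist()
        ens, truth = build_ensemble(ProbeSpec(n_ser_in=1, seed=23), schedule)
        (record,) = ensemble_descriptors(ens, select_methionines(ens.topology))
        assert record.WCN == pytest.approx(truth.wcn_mean, abs=1e-12)
        assert record.OH == pytest.approx(truth.oh_mean, abs=1e-12)

    def test_static_single_frame_degenerates(self, solvated_probe):
        from metox.structure import Ensemble

        model, truth = solvated_probe
        ens = Ensemble(topology=model, frames=model.coords[None, :, :])
        (record,) = ensemble_descriptors(ens, select_methionines(model))
        assert record.dSASA_abs == pytest.approx(record.sSASA_abs)
        assert record.WCN == truth.wcn
        assert record.OH == truth.oh

    def test_removing_waters_zeroes_wcn_only(self):
        ens, _ = build_ensemble(ProbeSpec(n_ser_in=2, seed=5), [4, 8])
        mask = strip_waters(ens.topology)
        dry = type(ens)(topology=ens.topology.subset(mask),
                        frames=ens.frames[:, mask, :])
        (record,) = ensemble_descriptors(dry, select_methionines(dry.topology))
        assert record.WCN == 0.0
        assert record.OH == pytest.approx(2.0)

    def test_zero_sites_is_valid_and_empty(self):
        ens, _ = build_ensemble(ProbeSpec(seed=1), [1])
        assert ensemble_descriptors(ens, []) == []
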