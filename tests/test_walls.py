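import itertools

import numpy as np
import pytest

import apexkit as ak

from conftest import two_block_volume


def brute_force_facets(vol, inten):
    """Exhaustive scan of all 6-connected voxel pairs (oracle)."""
    labels = vol.labels
    sz, sy, sx = vol.spacing
    area = {0: sy * sx, 1: sz * sx, 2: sz * sy}
    acc = {}
    nz, ny, nx = labels.shape
    for z, y, x in itertools.product(range(nz), range(ny), range(nx)):
        for axis, (dz, dy, dx) in enumerate([(1, 0, 0), (0, 1, 0), (0, 0, 1)]):
            z2, y2, x2 = z + dz, y + dy, x + dx
            if z2 >= nz or y2 >= ny or x2 >= nx:
                continue
            a, b = int(labels[z, y, x]), int(labels[z2, y2, x2])
            if a == b:
                continue
            pair = (min(a, b), max(a, b))
            i = 0.5 * (inten.values[z, y, x] + inten.values[z2, y2, x2])
            rec = acc.setdefault(pair, [0.0, 0.0, np.zeros(3)])
            w = area[axis]
            mid = np.array(
                [
                    (x + 0.5) * sx + 0.5 * sx * dx,
                    (y + 0.5) * sy + 0.5 * sy * dy,
                    (z + 0.5) * sz + 0.5 * sz * dz,
                ]
            )
            rec[0] += w
            rec[1] += w * i
            rec[2] = rec[2] + w * mid
    return {
        pair: (tot, num / tot, cen / tot) for pair, (tot, num, cen) in acc.items()
    }


def oracle_new_wall_calls(facets, tie_tol=1e-9):
    """Per-cell minimum search by plain loops (oracle)."""
    eligible = [f for f in facets if f.eligible]
    cells = sorted({c for f in eligible for c in f.pair})
    cell_min = {
        c: min(f.signal_density for f in eligible if c in f.pair) for c in cells
    }
    return {
        f.pair
        for f in eligible
        if f.signal_density <= cell_min[f.cell_a] * (1 + tie_tol)
        and f.signal_density <= cell_min[f.cell_b] * (1 + tie_tol)
    }


class TestExtractFacets:
    def test_uniform_two_block_interface(self):
        vol, inten = two_block_volume(100.0, 100.0)
        facets = [f for f in ak.extract_facets(vol, inten, min_face_elements=1) if f.eligible]
        assert len(facets) == 1
        f = facets[0]
        assert f.pair == (1, 2)
        assert f.area == pytest.approx(4.0)
        assert f.signal_density == pytest.approx(100.0)
        assert f.centroid == pytest.approx([3.0, 2.0, 2.0])  # xyz um

    def test_density_averages_both_flanking_sides(self):
        vol, inten = two_block_volume(80.0, 120.0)
        f = [f for f in ak.extract_facets(vol, inten, 1) if f.eligible][0]
        assert f.signal_density == pytest.approx(100.0)

    def test_matches_exhaustive_voxel_pair_oracle(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 20, size=(6, 7, 8)).astype(np.int32)
        labels[0, 0, 0] = 1
        values = rng.random((6, 7, 8)) * 50
        vol = ak.LabeledVolume(labels=labels, spacing=(2.0, 1.0, 0.5))
        inten = ak.IntensityVolume(values=values, spacing=(2.0, 1.0, 0.5))
        facets = ak.extract_facets(vol, inten, min_face_elements=1)
        oracle = brute_force_facets(vol, inten)
        assert {f.pair for f in facets} == set(oracle)
        for f in facets:
            area, dens, cen = oracle[f.pair]
            assert f.area == pytest.approx(area)
            assert f.signal_density == pytest.approx(dens)
            assert f.centroid == pytest.approx(cen)

    def test_min_face_elements_filters_small_interfaces(self):
        vol, inten = two_block_volume()
        assert [f for f in ak.extract_facets(vol, inten, min_face_elements=5) if f.eligible] == []

    def test_empty_segmentation_is_an_error(self):
        labels = np.ones((2, 2, 2), np.int32)
        vol = ak.LabeledVolume(labels=labels, spacing=(1, 1, 1), background_label=2)
        # background_label=2 leaves tissue, but an all-background view fails
        vol2 = ak.LabeledVolume.__new__(ak.LabeledVolume)
        object.__setattr__(vol2, "labels", np.zeros((2, 2, 2), np.int32))
        object.__setattr__(vol2, "spacing", (1.0, 1.0, 1.0))
        object.__setattr__(vol2, "background_label", 0)
        inten = ak.IntensityVolume(values=np.zeros((2, 2, 2)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="empty segmentation"):
            ak.extract_facets(vol2, inten)


def _chain_volume(densities):
    """Cells 1..n in a row; facet (i, i+1) built with the given densities."""
    n = len(densities) + 1
    labels = np.zeros((3, 3, 2 * n + 2), np.int32)
    values = np.zeros_like(labels, dtype=float)
    for c in range(n):
        labels[1, 1, 1 + 2 * c : 3 + 2 * c] = c + 1
    for i, d in enumerate(densities):
        values[1, 1, 2 + 2 * i] = d
        values[1, 1, 3 + 2 * i] = d
    vol = ak.LabeledVolume(labels=labels, spacing=(1, 1, 1))
    inten = ak.IntensityVolume(values=values, spacing=(1, 1, 1))
    return ak.extract_facets(vol, inten, min_face_elements=1)


class TestCallNewWalls:
    def test_triangle_example(self):
        # cells A,B,C with densities A-B=10, A-C=20, B-C=30: only A-B called
        facets = []
        for (a, b), d in {(1, 2): 10.0, (1, 3): 20.0, (2, 3): 30.0}.items():
            f = ak.Facet(
                cell_a=a, cell_b=b,
                face_voxels=np.zeros((1, 2, 3), np.int32),
                face_axes=np.zeros(1, np.int8),
                face_points=np.zeros((1, 3)),
                face_areas=np.ones(1),
                area=1.0, centroid=np.zeros(3), signal_density=d, eligible=True,
            )
            facets.append(f)
        ak.call_new_walls(facets)
        called = {f.pair for f in facets if f.is_new_wall}
        assert called == {(1, 2)}
        assert called == oracle_new_wall_calls(facets)

    def test_exact_tie_calls_all_tied_facets(self):
        facets = ak.call_new_walls(_chain_volume([10.0, 10.0, 30.0]), tie_tol=0.0)
        called = {f.pair for f in facets if f.is_new_wall}
        # cell 2 ties its two facets; (1,2) minimal for 1, (2,3) minimal for... 3's
        # min is 10 too (its facets are 10 and 30)
        assert called == oracle_new_wall_calls(facets, tie_tol=0.0) == {(1, 2), (2, 3)}

    def test_single_cell_surrounded_by_background_yields_no_calls(self):
        labels = np.zeros((4, 4, 4), np.int32)
        labels[1:3, 1:3, 1:3] = 1
        vol = ak.LabeledVolume(labels=labels, spacing=(1, 1, 1))
        inten = ak.IntensityVolume(values=np.ones((4, 4, 4)), spacing=(1, 1, 1))
        facets = ak.call_new_walls(ak.extract_facets(vol, inten, 1))
        assert all(not f.is_new_wall for f in facets)

    def test_background_facets_never_called_even_if_weakest(self, small_volume):
        vol, inten, _, _ = small_volume
        facets = ak.call_new_walls(ak.extract_facets(vol, inten))
        assert all(not f.is_new_wall for f in facets if not f.eligible)

    def test_invariant_under_monotone_intensity_rescaling(self, small_volume):
        # only the within-cell ranks of facet densities matter: a global
        # increasing affine rescaling of the image leaves the call set fixed
        vol, inten, _, _ = small_volume
        f1 = ak.call_new_walls(ak.extract_facets(vol, inten), tie_tol=0.0)
        called1 = {f.pair for f in f1 if f.is_new_wall}
        warped = ak.IntensityVolume(values=inten.values * 7.5 + 11.0, spacing=inten.spacing)
        f2 = ak.call_new_walls(ak.extract_facets(vol, warped), tie_tol=0.0)
        called2 = {f.pair for f in f2 if f.is_new_wall}
        assert called1 == called2

    def test_equals_oracle_on_seeded_small_volumes(self):
        for seed in range(5):
            params = ak.MeristemSimParams.small(seed=seed)
            vol, inten, _, _ = ak.generate_meristem(params)
            facets = ak.call_new_walls(ak.extract_facets(vol, inten))
            called = {f.pair for f in facets if f.is_new_wall}
            assert called == oracle_new_wall_calls(facets)


class TestDetectDivisions:
    def test_noise_free_detection_is_exact(self, small_volume):
        vol, inten, frame, truth = small_volume
        facets = ak.detect_divisions(vol, inten, frame=frame)
        ev = ak.evaluate_detection(facets, truth)
        assert ev["recall"] == 1.0
        assert ev["precision"] == 1.0

    def test_all_equal_intensities_reduce_to_mutual_tie_oracle(self):
        facets = _chain_volume([10.0, 10.0, 10.0, 10.0])
        ak.call_new_walls(facets, tie_tol=0.0)
        called = {f.pair for f in facets if f.is_new_wall}
        assert called == oracle_new_wall_calls(facets, tie_tol=0.0)
        assert called == {(i, i + 1) for i in range(1, 5)}  # everything ties

    def test_angles_filled_for_called_facets(self, small_volume):
        vol, inten, frame, truth = small_volume
        facets = ak.detect_divisions(vol, inten, frame=frame, regions=ak.default_regions())
        called = [f for f in facets if f.is_new_wall]
        assert called and all(np.isfinite(f.angle_to_axis) for f in called)
        assert all(f.region in {"AR", "RC", "RP", "NONE"} for f in facets)
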