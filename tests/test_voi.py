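import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perishell.voi import (
    VOIParams,
    build_voi_set,
    dilate,
    erode_one_voxel,
    label_lesions,
    make_ball,
    outer_shell,
    perilesion_shell,
    tissue_masks,
)
from perishell.volume import Volume

from oracles import (
    ball_offsets,
    brute_dilate,
    brute_erode,
    brute_label,
    brute_ring_family,
    random_lesion_wm_config,
)


def _vol(data):
    return Volume(data=np.asarray(data), affine=np.eye(4))


class TestBall:
    @pytest.mark.parametrize("radius", [0, 1, 2, 3, 4])
    def test_offsets_match_enumeration(self, radius):
        ball = make_ball(radius)
        got = {tuple(o) for o in ball.offsets}
        assert got == set(ball_offsets(radius))

    def test_known_counts(self):
        assert len(make_ball(0)) == 1
        assert len(make_ball(1)) == 7
        assert len(make_ball(2)) == 33

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            make_ball(-1)

    def test_symmetry(self):
        offs = {tuple(o) for o in make_ball(3).offsets}
        assert all((-x, -y, -z) in offs for x, y, z in offs)


class TestMorphology:
    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_dilate_matches_brute_force(self, rng, radius):
        mask = rng.random((14, 14, 14)) > 0.92
        got = dilate(mask, make_ball(radius))
        np.testing.assert_array_equal(got, brute_dilate(mask, radius))

    def test_erode_matches_brute_force(self, rng):
        mask = rng.random((14, 14, 14)) > 0.4
        np.testing.assert_array_equal(erode_one_voxel(mask), brute_erode(mask))

    def test_erosion_at_border(self):
        # a voxel on the array border has an out-of-volume neighbor -> eroded
        mask = np.ones((4, 4, 4), dtype=bool)
        ero = erode_one_voxel(mask)
        assert not ero[0].any() and not ero[-1].any()
        assert ero[1:3, 1:3, 1:3].all()

    def test_single_voxel_erodes_to_empty(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[3, 3, 3] = True
        assert not erode_one_voxel(mask).any()

    def test_radius2_sphere_erodes_to_radius1(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        for off in ball_offsets(2):
            mask[tuple(np.array((4, 4, 4)) + np.array(off))] = True
        ero = erode_one_voxel(mask)
        expected = np.zeros_like(mask)
        for off in ball_offsets(1):
            expected[tuple(np.array((4, 4, 4)) + np.array(off))] = True
        np.testing.assert_array_equal(ero, expected)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_dilation_erosion_adjunction(self, seed):
        # dilate(A) >= A and erode(A) <= A; erode(dilate(A)) >= A
        r = np.random.default_rng(seed)
        mask = r.random((10, 10, 10)) > 0.9
        dil = dilate(mask, make_ball(1))
        assert (mask <= dil).all()
        assert (erode_one_voxel(mask) <= mask).all()
        inner = erode_one_voxel(dil)
        # adjunction holds away from the array border
        assert (mask[1:-1, 1:-1, 1:-1] <= inner[1:-1, 1:-1, 1:-1]).all()


class TestLabeling:
    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill(self, rng, connectivity):
        for _ in range(5):
            mask = rng.random((12, 12, 12)) > 0.8
            comps = label_lesions(mask, connectivity=connectivity)
            _, n_ref = brute_label(mask, connectivity=connectivity)
            assert comps.count == n_ref
            # same partition: each implementation component maps to exactly
            # one reference component and vice versa
            ref_labels, _ = brute_label(mask, connectivity=connectivity)
            for k in range(1, comps.count + 1):
                refs = np.unique(ref_labels[comps.labels == k])
                assert len(refs) == 1

    def test_diagonal_voxels_connectivity(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = True
        mask[2, 2, 2] = True
        assert label_lesions(mask, connectivity=26).count == 1
        assert label_lesions(mask, connectivity=6).count == 2

    def test_labels_in_raster_order(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[4, 4, 4] = True  # later in raster order
        mask[1, 1, 1] = True
        comps = label_lesions(mask)
        assert comps.labels[1, 1, 1] == 1
        assert comps.labels[4, 4, 4] == 2

    def test_per_lesion_info(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        comps = label_lesions(mask)
        info = comps.per_lesion[0]
        assert info.n_voxels == 8
        assert info.bbox == ((1, 3), (1, 3), (1, 3))

    def test_bad_connectivity(self):
        with pytest.raises(ValueError):
            label_lesions(np.zeros((3, 3, 3), dtype=bool), connectivity=4)


class TestShells:
    def test_pl_of_single_voxel_in_full_wm(self):
        shape = (11, 11, 11)
        les = np.zeros(shape, dtype=bool)
        les[5, 5, 5] = True
        wm = np.ones(shape, dtype=bool) & ~les
        pl = perilesion_shell(les, wm, les)
        # ball(2) has 33 offsets; minus the lesion voxel itself -> 32
        assert pl.sum() == 32
        assert not pl[5, 5, 5]

    def test_pl_excludes_other_lesions(self):
        shape = (13, 13, 13)
        les_a = np.zeros(shape, dtype=bool)
        les_a[5, 5, 5] = True
        les_b = np.zeros(shape, dtype=bool)
        les_b[5, 5, 7] = True
        all_les = les_a | les_b
        wm = np.ones(shape, dtype=bool) & ~all_les
        pl = perilesion_shell(les_a, wm, all_les)
        assert not pl[5, 5, 7]
        assert pl.sum() == 31  # 32 minus the voxel occupied by lesion b

    def test_lesion_not_subset_raises(self):
        shape = (8, 8, 8)
        les = np.zeros(shape, dtype=bool)
        les[2, 2, 2] = True
        with pytest.raises(ValueError, match="subset"):
            perilesion_shell(les, np.ones(shape, bool), np.zeros(shape, bool))

    def test_invalid_shell_index(self):
        z = np.zeros((5, 5, 5), dtype=bool)
        with pytest.raises(ValueError):
            outer_shell(4, z, z, np.ones((5, 5, 5), bool))

    def test_shell_family_matches_brute_force_random(self, rng):
        for _ in range(8):
            lesions, wm = random_lesion_wm_config(rng, size=20, n_lesions=2)
            wm = wm & ~lesions
            comps = label_lesions(lesions)
            for k in range(1, comps.count + 1):
                les_k = comps.component(k)
                pl = perilesion_shell(les_k, wm, lesions)
                ref_pl, ref_shells = brute_ring_family(les_k, lesions, wm)
                np.testing.assert_array_equal(pl, ref_pl)
                inner = lesions | pl
                for n, ref in zip((1, 2, 3), ref_shells):
                    s = outer_shell(n, pl, inner, wm)
                    np.testing.assert_array_equal(s, ref)
                    inner |= s

    def test_shells_nested_and_disjoint(self, rng):
        lesions, wm = random_lesion_wm_config(rng, size=22, n_lesions=1)
        wm = wm & ~lesions
        pl = perilesion_shell(lesions, wm, lesions)
        inner = lesions | pl
        shells = []
        for n in (1, 2, 3):
            s = outer_shell(n, pl, inner, wm)
            shells.append(s)
            inner |= s
        masks = [lesions, pl, *shells]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                assert not (masks[i] & masks[j]).any()
        # every shell voxel is WM
        for s in [pl, *shells]:
            assert (s <= wm).all()


class TestTissueMasks:
    def test_threshold_is_strict(self):
        prob = np.full((3, 3, 3), 0.9)
        prob[1, 1, 1] = 0.90001
        gm, wm = tissue_masks(prob, prob, np.zeros((3, 3, 3), bool), threshold=0.9)
        assert wm.sum() == 1 and wm[1, 1, 1]
        assert gm.sum() == 1

    def test_lesions_excluded(self):
        prob = np.ones((3, 3, 3))
        les = np.zeros((3, 3, 3), dtype=bool)
        les[0, 0, 0] = True
        gm, wm = tissue_masks(prob, prob, les)
        assert not wm[0, 0, 0] and not gm[0, 0, 0]
        assert wm.sum() == 26

    def test_invalid_probability_rejected(self):
        bad = np.full((2, 2, 2), 1.5)
        with pytest.raises(ValueError, match="probabilities"):
            tissue_masks(bad, bad, np.zeros((2, 2, 2), bool))


def _simple_subject(shape=(24, 24, 24), lesion_center=(12, 12, 12), radius=2):
    les = np.zeros(shape, dtype=bool)
    for off in ball_offsets(radius):
        les[tuple(np.array(lesion_center) + np.array(off))] = True
    wm_prob = np.full(shape, 0.98)
    gm_prob = np.full(shape, 0.01)
    common = np.ones(shape, dtype=np.uint8)
    return (
        _vol(les.astype(np.uint8)),
        _vol(gm_prob),
        _vol(wm_prob),
        _vol(common),
    )


class TestBuildVOISet:
    def test_full_pipeline_single_lesion(self):
        les, gm, wm, common = _simple_subject()
        vs = build_voi_set(les, gm, wm, common)
        assert len(vs.per_lesion_vois) == 1
        assert not vs.dropped
        plv = vs.per_lesion_vois[0]
        # radius-2 sphere erodes to the radius-1 ball (7 voxels)
        assert plv.lesion.sum() == 7
        # validate() already ran; re-run defensively
        vs.validate(common=common)

    def test_tiny_lesion_dropped_by_erosion(self):
        shape = (16, 16, 16)
        les = np.zeros(shape, dtype=np.uint8)
        les[8, 8, 8] = 1
        _, gm, wm, common = _simple_subject(shape)
        vs = build_voi_set(_vol(les), gm, wm, common)
        assert not vs.per_lesion_vois
        assert len(vs.dropped) == 1
        assert vs.dropped[0].dropped == "emptied by erosion"

    def test_retain_eroded_empty_option(self):
        shape = (16, 16, 16)
        les = np.zeros(shape, dtype=np.uint8)
        les[8, 8, 8] = 1
        _, gm, wm, common = _simple_subject(shape)
        vs = build_voi_set(
            _vol(les), gm, wm, common, VOIParams(retain_eroded_empty=True)
        )
        assert len(vs.per_lesion_vois) == 1
        assert vs.per_lesion_vois[0].lesion.sum() == 1

    def test_lesion_outside_common_volume_dropped(self):
        les, gm, wm, _ = _simple_subject()
        common = np.ones((24, 24, 24), dtype=np.uint8)
        common[:, :, 13:] = 0  # cuts through the shell family
        vs = build_voi_set(les, gm, wm, _vol(common))
        assert not vs.per_lesion_vois
        assert vs.dropped[0].dropped == "outside common volume"

    def test_trim_instead_of_drop(self):
        les, gm, wm, _ = _simple_subject()
        common = np.ones((24, 24, 24), dtype=np.uint8)
        common[:, :, 15:] = 0
        vs = build_voi_set(les, gm, wm, _vol(common), VOIParams(drop_partial=False))
        assert len(vs.per_lesion_vois) == 1
        assert not vs.shell3.as_bool()[:, :, 15:].any()

    def test_exclude_perilesion_from_wm(self):
        les, gm, wm, common = _simple_subject()
        default = build_voi_set(les, gm, wm, common)
        strict = build_voi_set(
            les, gm, wm, common, VOIParams(exclude_perilesion_from_wm=True)
        )
        # default WM includes PL voxels; strict variant removes them
        assert (default.wm.as_bool() & default.pl.as_bool()).sum() > 0
        assert not (strict.wm.as_bool() & strict.pl.as_bool()).any()
        # both exclude lesion voxels
        assert not (default.wm.as_bool() & default.lesion.as_bool()).any()

    def test_union_masks_disjoint_two_close_lesions(self):
        shape = (32, 32, 32)
        les = np.zeros(shape, dtype=bool)
        for c in ((12, 16, 16), (21, 16, 16)):  # families overlap
            for off in ball_offsets(2):
                les[tuple(np.array(c) + np.array(off))] = True
        _, gm, wm, common = _simple_subject(shape)
        vs = build_voi_set(_vol(les.astype(np.uint8)), gm, wm, common)
        m = vs.union_masks()
        ring = ["lesion", "pl", "shell1", "shell2", "shell3"]
        for i, a in enumerate(ring):
            for b in ring[i + 1 :]:
                assert not (m[a] & m[b]).any()

    def test_no_lesions_gives_tissue_masks_only(self):
        shape = (16, 16, 16)
        _, gm, wm, common = _simple_subject(shape)
        vs = build_voi_set(_vol(np.zeros(shape, np.uint8)), gm, wm, common)
        assert not vs.per_lesion_vois
        assert not vs.lesion.as_bool().any()
        assert vs.wm.as_bool().all()
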