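"""Volume-of-interest construction around white-matter lesions.

Given a binary lesion segmentation, tissue-probability maps, and the
subject's common imaging volume, this module builds the full VOI family
used by the analysis:

* per-lesion connected components, each eroded by one voxel,
* a two-voxel-wide perilesional (PL) shell of normal-appearing white
  matter around each lesion,
* three one-voxel-wide concentric shells (shell 1-3) outside the PL,
  built by dilating the PL mask with discrete Euclidean balls of radius
  1, 2, 3 voxels and subtracting everything interior,
* GM and WM masks from tissue probabilities thresholded strictly above
  0.9, with lesion voxels excluded from every non-lesion VOI.

All shell geometry uses discrete Euclidean balls: the structuring element
of radius n contains every integer offset with squared norm <= n**2.
Radii are interpreted in voxels on the (isotropic 1 mm) analysis grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = [
    "LesionComponents",
    "LesionInfo",
    "PerLesionVOI",
    "StructuringElement",
    "VOIParams",
    "VOISet",
    "build_voi_set",
    "erode_one_voxel",
    "label_lesions",
    "make_ball",
    "outer_shell",
    "perilesion_shell",
    "tissue_masks",
]


def _as_bool(mask: Volume | np.ndarray) -> np.ndarray:
    if isinstance(mask, Volume):
        return mask.as_bool()
    arr = np.asarray(mask)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask is not binary")
        arr = arr.astype(bool)
    return arr


@dataclass(frozen=True)
class StructuringElement:
    """Discrete Euclidean ball: integer offsets with norm <= radius."""

    radius: int
    offsets: np.ndarray  # (n_offsets, 3) int
    footprint: np.ndarray  # (2r+1,)**3 bool

    def __len__(self) -> int:
        return len(self.offsets)


def make_ball(radius: int) -> StructuringElement:
    """Sphere-shaped structuring element of radius ``radius`` voxels.

    radius 0 -> the origin only; radius 1 -> origin plus the 6 face
    neighbors (7 offsets); radius 2 -> 33 offsets.
    """
    radius = int(radius)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = np.arange(-radius, radius + 1)
    dx, dy, dz = np.meshgrid(r, r, r, indexing="ij")
    footprint = dx**2 + dy**2 + dz**2 <= radius**2
    offsets = np.stack([dx[footprint], dy[footprint], dz[footprint]], axis=1)
    return StructuringElement(radius=radius, offsets=offsets, footprint=footprint)


BALL1 = make_ball(1)
BALL2 = make_ball(2)


def dilate(mask: Volume | np.ndarray, ball: StructuringElement) -> np.ndarray:
    """Binary dilation by a spherical structuring element."""
    m = _as_bool(mask)
    if ball.radius == 0:
        return m.copy()
    return ndimage.binary_dilation(m, structure=ball.footprint)


def erode_one_voxel(mask: Volume | np.ndarray) -> np.ndarray:
    """Morphological erosion by the radius-1 ball (6-neighborhood cross)."""
    m = _as_bool(mask)
    return ndimage.binary_erosion(m, structure=BALL1.footprint, border_value=0)


@dataclass(frozen=True)
class LesionInfo:
    label: int
    n_voxels: int
    bbox: tuple[tuple[int, int], ...]  # (start, stop) per axis
    dropped: str | None = None  # reason, or None if retained


@dataclass
class LesionComponents:
    """Connected lesion components with deterministic labeling.

    Labels are consecutive 1..count, ordered by the first voxel of each
    component in array (raster) order.
    """

    labels: np.ndarray
    count: int
    per_lesion: list[LesionInfo]

    def component(self, label: int) -> np.ndarray:
        return self.labels == label


def label_lesions(lesion_mask: Volume | np.ndarray, connectivity: int = 26) -> LesionComponents:
    """Label maximal connected lesion components.

    ``connectivity`` is 6 (faces), 18 (faces+edges), or 26 (full 3x3x3
    neighborhood, the default for lesion labeling).
    """
    m = _as_bool(lesion_mask)
    structure = {
        6: ndimage.generate_binary_structure(3, 1),
        18: ndimage.generate_binary_structure(3, 2),
        26: ndimage.generate_binary_structure(3, 3),
    }.get(connectivity)
    if structure is None:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    raw, n = ndimage.label(m, structure=structure)
    # Relabel by first raster-order voxel so label order is deterministic
    # regardless of the backend's internal sweep.
    order = np.full(n + 1, -1, dtype=int)
    flat = raw.ravel()
    first = {}
    for idx in np.flatnonzero(flat):
        lab = flat[idx]
        if lab not in first:
            first[lab] = idx
            if len(first) == n:
                break
    for new, (lab, _) in enumerate(sorted(first.items(), key=lambda kv: kv[1]), start=1):
        order[lab] = new
    labels = np.where(raw > 0, order[raw], 0).astype(np.int32)
    infos = []
    slices = ndimage.find_objects(labels)
    for k in range(1, n + 1):
        sl = slices[k - 1]
        bbox = tuple((s.start, s.stop) for s in sl)
        infos.append(LesionInfo(label=k, n_voxels=int((labels == k).sum()), bbox=bbox))
    return LesionComponents(labels=labels, count=n, per_lesion=infos)


def perilesion_shell(
    lesion_k: Volume | np.ndarray,
    wm_mask: Volume | np.ndarray,
    all_lesions: Volume | np.ndarray,
) -> np.ndarray:
    """Two-voxel-wide perilesional shell of WM around one lesion.

    dilate(lesion_k, ball(2)) minus every lesion voxel (of any lesion),
    intersected with the WM mask.
    """
    les = _as_bool(lesion_k)
    wm = _as_bool(wm_mask)
    allles = _as_bool(all_lesions)
    if les.shape != wm.shape or les.shape != allles.shape:
        raise ValueError("grid mismatch between lesion and WM masks")
    if (les & ~allles).any():
        raise ValueError("lesion_k must be a subset of all_lesions")
    return dilate(les, BALL2) & ~allles & wm


def outer_shell(
    n: int,
    pl: Volume | np.ndarray,
    inner: Volume | np.ndarray,
    wm_mask: Volume | np.ndarray,
) -> np.ndarray:
    """Concentric shell n in {1,2,3}: dilate(PL, ball(n)) \\ inner, in WM.

    ``inner`` must contain all lesion voxels, the PL, and shells 1..n-1;
    excluding the full interior (not just shell n-1) guarantees shells are
    pairwise disjoint by construction.
    """
    if n not in (1, 2, 3):
        raise ValueError("shell index must be 1, 2 or 3")
    p = _as_bool(pl)
    inn = _as_bool(inner)
    wm = _as_bool(wm_mask)
    if p.shape != inn.shape or p.shape != wm.shape:
        raise ValueError("grid mismatch")
    return dilate(p, make_ball(n)) & ~inn & wm


def tissue_masks(
    gm_prob: Volume | np.ndarray,
    wm_prob: Volume | np.ndarray,
    all_lesions: Volume | np.ndarray,
    threshold: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary GM/WM masks: probability strictly above threshold, lesions out."""
    gp = gm_prob.data if isinstance(gm_prob, Volume) else np.asarray(gm_prob)
    wp = wm_prob.data if isinstance(wm_prob, Volume) else np.asarray(wm_prob)
    for p in (gp, wp):
        valid = p[~np.isnan(p)] if np.issubdtype(p.dtype, np.floating) else p
        if (valid < 0).any() or (valid > 1).any():
            raise ValueError("tissue probabilities must lie in [0, 1]")
    les = _as_bool(all_lesions)
    gm = (gp > threshold) & ~les
    wm = (wp > threshold) & ~les
    return gm, wm


@dataclass
class PerLesionVOI:
    """The VOI family of a single retained lesion (boolean arrays)."""

    label: int
    lesion: np.ndarray
    pl: np.ndarray
    shell1: np.ndarray
    shell2: np.ndarray
    shell3: np.ndarray

    def masks(self) -> dict[str, np.ndarray]:
        return {
            "lesion": self.lesion,
            "pl": self.pl,
            "shell1": self.shell1,
            "shell2": self.shell2,
            "shell3": self.shell3,
        }


@dataclass(frozen=True)
class VOIParams:
    """Tunable VOI-construction parameters.

    connectivity: lesion component connectivity (6/18/26; default 26).
    tissue_threshold: tissue-probability cut (strict >; default 0.9).
    shells_from_eroded: build PL/shells around the eroded lesion masks
        (default) or around the original pre-erosion masks.
    drop_partial: drop a lesion whose VOIs leave the common imaging
        volume (default) instead of trimming them to it.
    retain_eroded_empty: keep a single-voxel stand-in for lesions emptied
        by erosion instead of dropping them.
    exclude_perilesion_from_wm: remove PL and shell voxels from the
        (NA)WM mask (off by default: only lesion voxels are excluded
        from non-lesion VOIs).
    """

    connectivity: int = 26
    tissue_threshold: float = 0.9
    shells_from_eroded: bool = True
    drop_partial: bool = True
    retain_eroded_empty: bool = False
    exclude_perilesion_from_wm: bool = False


@dataclass
class VOISet:
    """All VOIs of one subject, pairwise consistent by construction."""

    lesion: Volume
    pl: Volume
    shell1: Volume
    shell2: Volume
    shell3: Volume
    wm: Volume
    gm: Volume
    per_lesion_vois: list[PerLesionVOI]
    dropped: list[LesionInfo]
    provenance: dict = field(default_factory=dict)

    def union_masks(self) -> dict[str, np.ndarray]:
        return {
            "lesion": self.lesion.as_bool(),
            "pl": self.pl.as_bool(),
            "shell1": self.shell1.as_bool(),
            "shell2": self.shell2.as_bool(),
            "shell3": self.shell3.as_bool(),
            "wm": self.wm.as_bool(),
            "gm": self.gm.as_bool(),
        }

    def validate(self, common: Volume | np.ndarray | None = None) -> None:
        """Assert structural invariants; raises AssertionError on violation."""
        m = self.union_masks()
        ring_names = ["lesion", "pl", "shell1", "shell2", "shell3"]
        for i, a in enumerate(ring_names):
            for b in ring_names[i + 1 :]:
                assert not (m[a] & m[b]).any(), f"{a} and {b} overlap"
        assert not (m["lesion"] & m["wm"]).any(), "lesion voxels inside WM mask"
        assert not (m["lesion"] & m["gm"]).any(), "lesion voxels inside GM mask"
        if common is not None:
            c = _as_bool(common)
            for name, mask in m.items():
                assert not (mask & ~c).any(), f"{name} leaves the common volume"
        for plv in self.per_lesion_vois:
            pm = plv.masks()
            names = list(pm)
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    assert not (pm[a] & pm[b]).any(), (
                        f"lesion {plv.label}: {a} and {b} overlap"
                    )


def build_voi_set(
    lesion_mask: Volume,
    gm_prob: Volume,
    wm_prob: Volume,
    common: Volume,
    params: VOIParams = VOIParams(),
) -> VOISet:
    """Construct the complete VOI set for one subject.

    Pipeline: label lesion components, erode each by one voxel (dropping
    components emptied by erosion), build per-lesion PL and shells 1-3 in
    WM, threshold the tissue-probability maps, restrict everything to the
    common imaging volume, and drop (or trim) lesions whose VOIs are not
    fully covered.
    """
    affine = lesion_mask.affine.copy()
    common_b = common.as_bool()
    comps = label_lesions(lesion_mask, connectivity=params.connectivity)

    dropped: list[LesionInfo] = []
    eroded: dict[int, np.ndarray] = {}
    for info in comps.per_lesion:
        comp = comps.component(info.label)
        ero = erode_one_voxel(comp)
        if not ero.any():
            if params.retain_eroded_empty:
                # keep the first voxel of the original component
                idx = np.unravel_index(np.flatnonzero(comp)[0], comp.shape)
                ero = np.zeros_like(comp)
                ero[idx] = True
            else:
                dropped.append(
                    LesionInfo(info.label, info.n_voxels, info.bbox, "emptied by erosion")
                )
                continue
        eroded[info.label] = ero

    # geometry basis: eroded masks by default, original components otherwise
    if params.shells_from_eroded:
        basis = eroded
    else:
        basis = {lab: comps.component(lab) for lab in eroded}
    all_basis = np.zeros(lesion_mask.shape, dtype=bool)
    for b in basis.values():
        all_basis |= b

    gm, wm = tissue_masks(gm_prob, wm_prob, all_basis, threshold=params.tissue_threshold)

    per_lesion: list[PerLesionVOI] = []
    for info in comps.per_lesion:
        if info.label not in basis:
            continue
        les = eroded[info.label]
        geom = basis[info.label]
        pl = perilesion_shell(geom, wm, all_basis)
        inner = all_basis | pl
        shells = []
        for n in (1, 2, 3):
            s = outer_shell(n, pl, inner, wm)
            shells.append(s)
            inner = inner | s
        family = [les, pl, *shells]
        outside = any((mask & ~common_b).any() for mask in family)
        if outside:
            if params.drop_partial:
                dropped.append(
                    LesionInfo(info.label, info.n_voxels, info.bbox, "outside common volume")
                )
                continue
            family = [mask & common_b for mask in family]
            if not family[0].any():
                dropped.append(
                    LesionInfo(info.label, info.n_voxels, info.bbox, "outside common volume")
                )
                continue
        per_lesion.append(PerLesionVOI(info.label, *family))

    shape = lesion_mask.shape
    union = {k: np.zeros(shape, dtype=bool) for k in ("lesion", "pl", "shell1", "shell2", "shell3")}
    for plv in per_lesion:
        for name, mask in plv.masks().items():
            union[name] |= mask
    # union-level priority: a voxel in the PL of one lesion and a shell of
    # another counts once, in the innermost class
    union["shell1"] &= ~(union["lesion"] | union["pl"])
    union["shell2"] &= ~(union["lesion"] | union["pl"] | union["shell1"])
    union["shell3"] &= ~(union["lesion"] | union["pl"] | union["shell1"] | union["shell2"])

    wm_final = wm & common_b
    gm_final = gm & common_b
    if params.exclude_perilesion_from_wm:
        wm_final &= ~(union["pl"] | union["shell1"] | union["shell2"] | union["shell3"])
    for k in union:
        union[k] &= common_b

    def vol(mask: np.ndarray) -> Volume:
        return Volume(data=mask.astype(np.uint8), affine=affine.copy(), units="")

    voiset = VOISet(
        lesion=vol(union["lesion"]),
        pl=vol(union["pl"]),
        shell1=vol(union["shell1"]),
        shell2=vol(union["shell2"]),
        shell3=vol(union["shell3"]),
        wm=vol(wm_final),
        gm=vol(gm_final),
        per_lesion_vois=per_lesion,
        dropped=dropped,
        provenance={
            "connectivity": params.connectivity,
            "tissue_threshold": params.tissue_threshold,
            "shells_from_eroded": params.shells_from_eroded,
            "drop_partial": params.drop_partial,
            "n_components": comps.count,
            "n_retained": len(per_lesion),
        },
    )
    voiset.validate(common=common_b)
    return voiset
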