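"""Synthetic multi-parametric brain phantom cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes,
not anatomy: nested ellipsoids define a background/CSF region, a grey
matter ribbon, and a white matter core; spherical lesions are placed
fully inside the WM core with enough separation that each lesion's
perilesional shell family (PL + shells 1-3) is disjoint from every
other's.  Each of the nine biomarker maps is painted piecewise constant
from a value table (per-tissue means, lesion-to-shell radial profiles),
plus three noise layers:

* a per-subject random effect shifting all tissues of one subject,
* a per-lesion, per-class random effect (between-lesion heterogeneity,
  largest for the lesion core of qT1/qT2/qT2*/PD/QSM),
* i.i.d. voxel noise.

Default value tables are the cohort medians and lesion-level radial
profiles of the emulated study population (13 MS patients, 14 healthy
controls); all scales are tunable, and zeroing every sigma yields a
phantom whose VOI means the pipeline must recover exactly.

Shell geometry during painting reuses :mod:`perishell.voi` -- the same
code path the analysis pipeline runs -- so the painted classes and the
extracted VOIs coincide by construction.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from . import voi as voi_mod
from .extract import voi_mean
from .voi import VOIParams, VOISet, build_voi_set, make_ball
from .volume import BIOMARKERS, BIOMARKER_UNITS, ReferenceGrid, Volume

__all__ = [
    "PhantomSpec",
    "SyntheticSubject",
    "default_value_table",
    "generate_cohort",
    "generate_subject",
    "simulate_subject_table",
    "write_cohort",
]

RING_CLASSES = ("lesion", "pl", "shell1", "shell2", "shell3")

# --- built-in value tables ------------------------------------------------
# Healthy-control tissue medians (per-subject means pooled over whole-brain
# GM / WM), with the printed subject range used to set between-subject SDs.
_HC_WM = {
    "MWF": (11.50, 8.87, 13.91),
    "MTsat": (2.68, 2.55, 2.84),
    "ihMTR": (7.05, 6.40, 8.26),
    "qT1": (993.50, 935.60, 1047.00),
    "qT2": (72.51, 69.17, 74.57),
    "qT2star": (43.01, 40.72, 46.12),
    "PD": (68.84, 68.47, 68.95),
    "QSM": (-4.28, -8.73, 0.72),
    "T1wT2w": (1.84, 1.65, 2.04),
}
_HC_GM = {
    "MWF": (3.89, 2.68, 5.51),
    "MTsat": (1.53, 1.44, 1.63),
    "ihMTR": (3.49, 2.64, 4.59),
    "qT1": (1461.40, 1412.30, 1607.20),
    "qT2": (87.60, 84.81, 92.96),
    "qT2star": (61.43, 56.56, 75.27),
    "PD": (76.85, 75.43, 77.92),
    "QSM": (0.00, -0.48, 3.40),
    "T1wT2w": (1.11, 1.09, 1.15),
}
# Normal-appearing tissue medians of the MS group.
_MS_NAWM = {
    "MWF": 10.97, "MTsat": 2.65, "ihMTR": 6.60, "qT1": 1018.30, "qT2": 73.53,
    "qT2star": 44.34, "PD": 68.73, "QSM": -4.33, "T1wT2w": 1.83,
}
_MS_NAGM = {
    "MWF": 3.72, "MTsat": 1.53, "ihMTR": 3.38, "qT1": 1450.80, "qT2": 85.74,
    "qT2star": 62.38, "PD": 76.55, "QSM": 0.98, "T1wT2w": 1.12,
}
# Lesion-level radial profile: mean (SD) of per-lesion means in lesion,
# PL, and shells 1-3.
_RADIAL = {
    "MWF": [(5.52, 3.17), (9.03, 3.28), (9.87, 3.51), (10.11, 3.53), (10.23, 3.53)],
    "MTsat": [(1.49, 0.36), (2.47, 0.29), (2.61, 0.29), (2.65, 0.28), (2.67, 0.26)],
    "ihMTR": [(5.69, 1.72), (6.69, 1.40), (6.87, 1.38), (6.89, 1.35), (6.85, 1.33)],
    "qT1": [
        (1371.75, 201.32), (1027.18, 97.02), (997.21, 100.07),
        (990.54, 90.55), (989.05, 88.54),
    ],
    "qT2": [(99.05, 16.66), (81.88, 6.14), (77.52, 5.04), (76.05, 4.65), (75.09, 4.43)],
    "qT2star": [
        (66.44, 15.04), (46.65, 5.91), (44.81, 4.65), (44.49, 4.33), (44.36, 4.08)
    ],
    "PD": [(77.84, 2.95), (69.70, 1.37), (68.75, 1.15), (68.58, 0.99), (68.50, 0.89)],
    "QSM": [(3.23, 15.85), (-7.70, 10.91), (-7.60, 9.99), (-6.96, 8.92), (-6.50, 8.18)],
    "T1wT2w": [(0.80, 0.21), (1.54, 0.22), (1.68, 0.24), (1.73, 0.24), (1.77, 0.24)],
}
# Subject-level medians in lesion and PL of the MS group (alternative
# seeding for the radial profile).
_MS_LESION_PL = {
    "MWF": (3.79, 9.67), "MTsat": (1.28, 2.39), "ihMTR": (5.35, 7.00),
    "qT1": (1403.50, 1050.30), "qT2": (107.92, 83.24), "qT2star": (70.51, 46.74),
    "PD": (78.54, 69.61), "QSM": (6.51, -7.45), "T1wT2w": (0.65, 1.48),
}


def default_value_table() -> dict:
    """The built-in cohort value tables, with units.

    Returns a dict with keys ``hc_wm``, ``hc_gm`` (median, min, max of
    HC subject means), ``nawm``, ``nagm`` (MS medians), ``lesion_pl``
    (MS subject-level lesion/PL medians), ``radial`` (lesion-level
    mean/SD per ring class), and ``units``.
    """
    return {
        "hc_wm": dict(_HC_WM),
        "hc_gm": dict(_HC_GM),
        "nawm": dict(_MS_NAWM),
        "nagm": dict(_MS_NAGM),
        "lesion_pl": dict(_MS_LESION_PL),
        "radial": {b: [tuple(t) for t in v] for b, v in _RADIAL.items()},
        "units": dict(BIOMARKER_UNITS),
    }


def _quarter_range(table: dict[str, tuple[float, float, float]]) -> dict[str, float]:
    # a subject range over ~14 participants spans roughly +-2 SD
    return {b: (hi - lo) / 4.0 for b, (_, lo, hi) in table.items()}


@dataclass
class PhantomSpec:
    """Full parameterization of a synthetic cohort.

    Geometry is in voxels on an isotropic grid (default 1 mm).  Lesions
    are spheres with radius drawn from ``radius_range``; centers are
    rejection-sampled so that each lesion's whole shell family (radius
    + 5 voxels) lies inside the WM core and is separated from every
    other family by at least ``family_gap`` voxels, which keeps ring
    classes of different lesions disjoint and ground truth exact.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: float = 1.0
    brain_axes: tuple[float, float, float] = (40.0, 42.0, 36.0)
    wm_axes: tuple[float, float, float] = (30.0, 32.0, 26.0)
    n_lesions_range: tuple[int, int] = (3, 5)
    radius_range: tuple[int, int] = (2, 3)
    family_gap: int = 1
    max_placement_tries: int = 20000

    wm_mean: dict[str, float] = field(
        default_factory=lambda: {b: v[0] for b, v in _HC_WM.items()}
    )
    gm_mean: dict[str, float] = field(
        default_factory=lambda: {b: v[0] for b, v in _HC_GM.items()}
    )
    group_effect_wm: dict[str, float] = field(
        default_factory=lambda: {b: _MS_NAWM[b] - _HC_WM[b][0] for b in BIOMARKERS}
    )
    group_effect_gm: dict[str, float] = field(
        default_factory=lambda: {b: _MS_NAGM[b] - _HC_GM[b][0] for b in BIOMARKERS}
    )
    radial_profile: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            b: {c: _RADIAL[b][i][0] for i, c in enumerate(RING_CLASSES)}
            for b in BIOMARKERS
        }
    )
    sigma_lesion: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            b: {c: _RADIAL[b][i][1] for i, c in enumerate(RING_CLASSES)}
            for b in BIOMARKERS
        }
    )
    sigma_subject: dict[str, float] = field(
        default_factory=lambda: _quarter_range(_HC_WM)
    )
    sigma_voxel: dict[str, float] = field(
        default_factory=lambda: {b: _RADIAL[b][4][1] for b in BIOMARKERS}
    )
    lesion_sd_scale: float = 1.0
    subject_sd_scale: float = 1.0
    voxel_sd_scale: float = 1.0
    missing_qsm_hc: bool = True
    coarse_modalities: tuple[str, ...] = ()
    coarse_spacing: float = 2.0
    t2w_reference: float = 100.0

    # -- named configurations -------------------------------------------
    @classmethod
    def default(cls) -> "PhantomSpec":
        return cls()

    @classmethod
    def noise_free(cls, **kw) -> "PhantomSpec":
        """All random effects off: painted values are the table values."""
        return cls(lesion_sd_scale=0.0, subject_sd_scale=0.0, voxel_sd_scale=0.0, **kw)

    @classmethod
    def null(cls, **kw) -> "PhantomSpec":
        """Global null: no group effect and no lesions, groups exchangeable."""
        zero = {b: 0.0 for b in BIOMARKERS}
        return cls(
            group_effect_wm=dict(zero),
            group_effect_gm=dict(zero),
            n_lesions_range=(0, 0),
            missing_qsm_hc=False,
            **kw,
        )

    @classmethod
    def low_heterogeneity(cls, scale: float = 0.2, **kw) -> "PhantomSpec":
        """Between-lesion heterogeneity damped to ``scale`` of its default.

        At scale 0.2, the per-subject pooled lesion/PL difference is at
        least ~5 between-lesion SDs away from zero for every biomarker,
        so the within-patient sign structure (PL above lesion for the
        myelin-sensitive markers and T1w/T2w, below for the relaxometry,
        PD, and susceptibility markers) holds in essentially every
        simulated patient.
        """
        return cls(lesion_sd_scale=scale, **kw)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("shape", "n_lesions_range", "radius_range", "coarse_modalities"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def validate(self) -> None:
        if any(s < 8 for s in self.shape):
            raise ValueError("phantom grid too small")
        if self.radius_range[0] < 2:
            raise ValueError("lesion radius must be >= 2 voxels")
        for scale in (self.lesion_sd_scale, self.subject_sd_scale, self.voxel_sd_scale):
            if scale < 0:
                raise ValueError("noise scales must be >= 0")
        for b in BIOMARKERS:
            if b not in self.wm_mean or b not in self.gm_mean:
                raise ValueError(f"value table incomplete for {b}")
            if set(self.radial_profile[b]) != set(RING_CLASSES):
                raise ValueError(f"radial profile incomplete for {b}")


@dataclass
class SyntheticSubject:
    """One simulated participant with full ground truth."""

    subject: str
    group: str  # "MS" or "HC"
    tissue_labels: Volume  # 0 background, 1 GM, 2 WM
    gm_prob: Volume
    wm_prob: Volume
    lesion_mask: Volume  # original (pre-erosion) segmentation; empty for HC
    panel: dict[str, Volume]  # painted biomarker maps (includes T1wT2w)
    t1w: Volume
    t2w: Volume
    truth: dict
    vois: VOISet | None = None  # geometry used for painting (MS only)


# --- geometry -------------------------------------------------------------


def _ellipsoid(shape, center, axes) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, axes):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def _geometry(spec: PhantomSpec) -> np.ndarray:
    """Tissue label field: 0 background/CSF, 1 GM ribbon, 2 WM core."""
    center = tuple((s - 1) / 2.0 for s in spec.shape)
    brain = _ellipsoid(spec.shape, center, spec.brain_axes)
    wm = _ellipsoid(spec.shape, center, spec.wm_axes)
    labels = np.zeros(spec.shape, dtype=np.int8)
    labels[brain] = 1
    labels[wm] = 2
    return labels


def _place_lesions(
    spec: PhantomSpec, wm: np.ndarray, rng: np.random.Generator
) -> list[tuple[tuple[int, int, int], int]]:
    lo, hi = spec.n_lesions_range
    n_lesions = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    placed: list[tuple[tuple[int, int, int], int]] = []
    if n_lesions == 0:
        return placed
    shape = wm.shape
    tries = 0
    while len(placed) < n_lesions and tries < spec.max_placement_tries:
        tries += 1
        r = int(rng.integers(spec.radius_range[0], spec.radius_range[1] + 1))
        c = tuple(int(rng.integers(0, s)) for s in shape)
        # full shell family must stay inside the WM core
        fam = make_ball(r + 5).offsets + np.array(c)
        if (fam < 0).any() or (fam >= np.array(shape)).any():
            continue
        if not wm[fam[:, 0], fam[:, 1], fam[:, 2]].all():
            continue
        ok = True
        for (pc, pr) in placed:
            d = np.linalg.norm(np.array(c, dtype=float) - np.array(pc, dtype=float))
            if d < (r + 5) + (pr + 5) + spec.family_gap:
                ok = False
                break
        if ok:
            placed.append((c, r))
    if len(placed) < n_lesions:
        raise RuntimeError(
            f"could not place {n_lesions} lesions after {tries} tries; "
            "enlarge the grid or reduce the lesion count"
        )
    return placed


def _paint_mask(shape, lesions) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for c, r in lesions:
        ball = make_ball(r).offsets + np.array(c)
        mask[ball[:, 0], ball[:, 1], ball[:, 2]] = True
    return mask


def _subject_rng(master_seed: int, group: str, index: int) -> np.random.Generator:
    """Documented substream rule: SeedSequence(master, spawn_key=(g, i)).

    Adding subjects or reordering groups never perturbs the stream of an
    existing subject.
    """
    gkey = 0 if group == "MS" else 1
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(gkey, index)))


def generate_subject(
    spec: PhantomSpec, group: str, seed: int, index: int = 0, subject: str | None = None
) -> SyntheticSubject:
    """Generate one synthetic participant, deterministic in (spec, seed, index)."""
    spec.validate()
    if group not in ("MS", "HC"):
        raise ValueError("group must be 'MS' or 'HC'")
    rng = _subject_rng(seed, group, index)
    subject = subject or f"{group}{index + 1:02d}"

    labels = _geometry(spec)
    gm_region = labels == 1
    wm_region = labels == 2
    affine = np.diag([spec.spacing] * 3 + [1.0])
    grid = ReferenceGrid(shape=spec.shape, affine=affine)

    gm_prob = np.where(gm_region, 0.98, np.where(wm_region, 0.01, 0.0))
    wm_prob = np.where(wm_region, 0.98, np.where(gm_region, 0.01, 0.0))

    lesions = _place_lesions(spec, wm_region, rng) if group == "MS" else []
    lesion_mask = _paint_mask(spec.shape, lesions)

    def vol(data, units=""):
        return Volume(data=data, affine=affine.copy(), units=units)

    # ring geometry via the same construction the pipeline applies
    common = vol(np.ones(spec.shape, dtype=np.uint8))
    vois: VOISet | None = None
    if group == "MS":
        vois = build_voi_set(
            vol(lesion_mask.astype(np.uint8)),
            vol(gm_prob),
            vol(wm_prob),
            common,
            VOIParams(),
        )

    # random effects
    subj_eff = {
        b: float(rng.normal(0.0, spec.sigma_subject[b] * spec.subject_sd_scale))
        for b in BIOMARKERS
    }
    lesion_eff: dict[int, dict[str, dict[str, float]]] = {}
    if vois is not None:
        for plv in vois.per_lesion_vois:
            lesion_eff[plv.label] = {
                b: {
                    c: float(
                        rng.normal(
                            0.0, spec.sigma_lesion[b][c] * spec.lesion_sd_scale
                        )
                    )
                    for c in RING_CLASSES
                }
                for b in BIOMARKERS
            }

    ge_wm = spec.group_effect_wm if group == "MS" else {b: 0.0 for b in BIOMARKERS}
    ge_gm = spec.group_effect_gm if group == "MS" else {b: 0.0 for b in BIOMARKERS}

    panel: dict[str, Volume] = {}
    expected_subject: dict[str, dict[str, float]] = {b: {} for b in BIOMARKERS}
    expected_lesion: dict[str, dict[int, dict[str, float]]] = {b: {} for b in BIOMARKERS}
    noise_free: dict[str, np.ndarray] = {}
    for b in BIOMARKERS:
        base = np.full(spec.shape, spec.wm_mean[b] + ge_wm[b] + subj_eff[b])
        base[gm_region] = spec.gm_mean[b] + ge_gm[b] + subj_eff[b]
        # background/CSF carries the GM value; it enters no VOI mean
        base[labels == 0] = spec.gm_mean[b] + ge_gm[b] + subj_eff[b]
        if vois is not None:
            for plv in vois.per_lesion_vois:
                for c, mask in plv.masks().items():
                    base[mask] = (
                        spec.radial_profile[b][c]
                        + subj_eff[b]
                        + lesion_eff[plv.label][b][c]
                    )
        noise_free[b] = base
        sigma_v = spec.sigma_voxel[b] * spec.voxel_sd_scale
        noisy = base + rng.normal(0.0, sigma_v, spec.shape) if sigma_v > 0 else base.copy()
        panel[b] = vol(noisy, BIOMARKER_UNITS[b])

        # ground truth: noise-free expectation of every VOI mean
        nf = vol(base, BIOMARKER_UNITS[b])
        if vois is not None:
            expected_subject[b]["avgLesion"] = voi_mean(nf, vois.lesion)[0]
            expected_subject[b]["avgPL"] = voi_mean(nf, vois.pl)[0]
            expected_subject[b]["NAWM"] = voi_mean(nf, vois.wm)[0]
            expected_subject[b]["NAGM"] = voi_mean(nf, vois.gm)[0]
            for plv in vois.per_lesion_vois:
                expected_lesion[b][plv.label] = {
                    c: voi_mean(nf, m)[0] for c, m in plv.masks().items()
                }
        else:
            wm_mask = (wm_prob > 0.9)
            gm_mask = (gm_prob > 0.9)
            expected_subject[b]["WM"] = float(base[wm_mask].mean())
            expected_subject[b]["GM"] = float(base[gm_mask].mean())

    # weighted volumes from which the pipeline recomputes the T1w/T2w ratio
    t2w = vol(np.full(spec.shape, spec.t2w_reference))
    t1w = vol(panel["T1wT2w"].data * spec.t2w_reference)

    truth = {
        "subject": subject,
        "group": group,
        "seed": int(seed),
        "index": int(index),
        "lesions": [
            {"center": [int(x) for x in c], "radius": int(r)} for c, r in lesions
        ],
        "subject_effect": subj_eff,
        "lesion_effect": {
            str(lab): eff for lab, eff in lesion_eff.items()
        },
        "expected_subject_means": expected_subject,
        "expected_lesion_means": {
            b: {str(lab): v for lab, v in expected_lesion[b].items()}
            for b in BIOMARKERS
        },
    }
    return SyntheticSubject(
        subject=subject,
        group=group,
        tissue_labels=vol(labels),
        gm_prob=vol(gm_prob),
        wm_prob=vol(wm_prob),
        lesion_mask=vol(lesion_mask.astype(np.uint8)),
        panel=panel,
        t1w=t1w,
        t2w=t2w,
        truth=truth,
        vois=vois,
    )


def generate_cohort(
    spec: PhantomSpec, n_ms: int, n_hc: int, seed: int
) -> list[SyntheticSubject]:
    """Generate an in-memory cohort of n_ms MS patients and n_hc controls.

    Exactly one HC subject (the first) lacks the QSM modality when
    ``spec.missing_qsm_hc`` is set, emulating an aborted susceptibility
    scan.
    """
    if n_ms < 0 or n_hc < 0:
        raise ValueError("cohort sizes must be >= 0")
    subjects = [generate_subject(spec, "MS", seed, i) for i in range(n_ms)]
    for j in range(n_hc):
        sub = generate_subject(spec, "HC", seed, j)
        if spec.missing_qsm_hc and j == 0:
            del sub.panel["QSM"]
            sub.truth["missing_modalities"] = ["QSM"]
            sub.truth["expected_subject_means"].pop("QSM", None)
        subjects.append(sub)
    return subjects


# --- on-disk cohort -------------------------------------------------------


def _coarse_volume(fine: Volume, spec: PhantomSpec, rng_noise=None) -> Volume:
    """Re-grid a painted map onto a coarser grid by nearest sampling."""
    cs = spec.coarse_spacing
    cshape = tuple(int(np.floor((s - 1) * spec.spacing / cs)) + 1 for s in fine.shape)
    caffine = np.diag([cs, cs, cs, 1.0])
    idx = np.indices(cshape, dtype=float) * (cs / spec.spacing)
    idx = np.rint(idx).astype(int)
    data = fine.data[idx[0], idx[1], idx[2]]
    return Volume(data=data, affine=caffine, units=fine.units)


def write_cohort(subjects: list[SyntheticSubject], outdir: str | Path, spec: PhantomSpec) -> Path:
    """Write a cohort to disk: per-subject NIfTI files, a manifest CSV,
    ground-truth JSON, and the serialized spec."""
    from .volume import write_volume
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    truths = {}
    for sub in subjects:
        sdir = outdir / sub.subject
        sdir.mkdir(exist_ok=True)
        files: dict[str, Volume] = {
            "lesion_mask": sub.lesion_mask,
            "gm_prob": sub.gm_prob,
            "wm_prob": sub.wm_prob,
            "T1w": sub.t1w,
            "T2w": sub.t2w,
        }
        for b, v in sub.panel.items():
            if b == "T1wT2w":
                continue  # recomputed downstream from T1w and T2w
            if b in spec.coarse_modalities:
                v = _coarse_volume(v, spec)
            files[b] = v
        for name, v in files.items():
            fname = f"{name}.nii.gz"
            dtype = np.uint8 if name == "lesion_mask" else np.float64
            write_volume(v, sdir / fname, dtype=dtype)
            rows.append(
                {
                    "subject": sub.subject,
                    "group": sub.group,
                    "map": name,
                    "file": f"{sub.subject}/{fname}",
                    "units": v.units,
                }
            )
        truths[sub.subject] = sub.truth
    with open(outdir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["subject", "group", "map", "file", "units"])
        writer.writeheader()
        writer.writerows(rows)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truths, fh, indent=1, sort_keys=True)
    with open(outdir / "phantom_spec.yaml", "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=True)
    return outdir


# --- subject-level marginal simulator -------------------------------------


@lru_cache(maxsize=8)
def _ring_counts(radius: int) -> dict[str, int]:
    """Voxel counts of the ring classes around one isolated spherical lesion."""
    size = 2 * (radius + 6) + 3
    shape = (size, size, size)
    center = (size // 2,) * 3
    mask = np.zeros(shape, dtype=bool)
    ball = make_ball(radius).offsets + np.array(center)
    mask[ball[:, 0], ball[:, 1], ball[:, 2]] = True
    eroded = voi_mod.erode_one_voxel(mask)
    wm = np.ones(shape, dtype=bool) & ~eroded
    pl = voi_mod.perilesion_shell(eroded, wm, eroded)
    inner = eroded | pl
    counts = {"lesion": int(eroded.sum()), "pl": int(pl.sum())}
    for n in (1, 2, 3):
        s = voi_mod.outer_shell(n, pl, inner, wm)
        counts[f"shell{n}"] = int(s.sum())
        inner |= s
    return counts


@lru_cache(maxsize=4)
def _tissue_counts(shape: tuple, brain_axes: tuple, wm_axes: tuple) -> tuple[int, int]:
    labels = _geometry(
        PhantomSpec(shape=shape, brain_axes=brain_axes, wm_axes=wm_axes)
    )
    return int((labels == 2).sum()), int((labels == 1).sum())


def simulate_subject_table(
    spec: PhantomSpec, n_ms: int, n_hc: int, seed: int
) -> pd.DataFrame:
    """Draw a subject-level cohort table directly from the phantom's model.

    This is the analytic subject-level marginal of the image generator:
    per-subject and per-lesion effects are drawn from the same
    distributions, ring-class voxel counts come from the shared shell
    geometry, and voxel noise enters through its pooled standard error.
    It produces the same joint distribution of subject means as
    rendering, segmenting, and averaging full volumes, at a tiny
    fraction of the cost -- used for Monte-Carlo calibration studies.
    """
    spec.validate()
    n_wm_region, n_gm = _tissue_counts(
        tuple(spec.shape), tuple(spec.brain_axes), tuple(spec.wm_axes)
    )
    records = []
    surround = ("pl", "shell1", "shell2", "shell3")
    for group, n_subj in (("MS", n_ms), ("HC", n_hc)):
        for i in range(n_subj):
            rng = _subject_rng(seed, group, i)
            if group == "MS":
                lo, hi = spec.n_lesions_range
                n_les = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
                radii = [
                    int(rng.integers(spec.radius_range[0], spec.radius_range[1] + 1))
                    for _ in range(n_les)
                ]
            else:
                radii = []
            subj_eff = {
                b: float(rng.normal(0.0, spec.sigma_subject[b] * spec.subject_sd_scale))
                for b in BIOMARKERS
            }
            counts = [_ring_counts(r) for r in radii]
            lesion_eff = [
                {
                    b: {
                        c: float(
                            rng.normal(0.0, spec.sigma_lesion[b][c] * spec.lesion_sd_scale)
                        )
                        for c in RING_CLASSES
                    }
                    for b in BIOMARKERS
                }
                for _ in radii
            ]
            subject = f"{group}{i + 1:02d}"
            missing = (
                ["QSM"] if (group == "HC" and i == 0 and spec.missing_qsm_hc) else []
            )
            for b in BIOMARKERS:
                if b in missing:
                    continue
                sig_v = spec.sigma_voxel[b] * spec.voxel_sd_scale
                ge_wm = spec.group_effect_wm[b] if group == "MS" else 0.0
                ge_gm = spec.group_effect_gm[b] if group == "MS" else 0.0
                wm_val = spec.wm_mean[b] + ge_wm + subj_eff[b]
                gm_val = spec.gm_mean[b] + ge_gm + subj_eff[b]
                if group == "HC":
                    vois = {"WM": (wm_val, n_wm_region), "GM": (gm_val, n_gm)}
                else:
                    n_lesion_vox = sum(c["lesion"] for c in counts)
                    n_pl_vox = sum(c["pl"] for c in counts)
                    n_surround = sum(c[s] for c in counts for s in surround)
                    n_nawm = n_wm_region - n_lesion_vox
                    vois = {"NAGM": (gm_val, n_gm)}
                    # NAWM pools far WM plus the painted surround classes
                    total = wm_val * (n_nawm - n_surround)
                    for c, eff in zip(counts, lesion_eff):
                        for s in surround:
                            total += c[s] * (
                                spec.radial_profile[b][s] + subj_eff[b] + eff[b][s]
                            )
                    vois["NAWM"] = (total / n_nawm if n_nawm else np.nan, n_nawm)
                    if n_lesion_vox:
                        les_total = sum(
                            c["lesion"]
                            * (
                                spec.radial_profile[b]["lesion"]
                                + subj_eff[b]
                                + eff[b]["lesion"]
                            )
                            for c, eff in zip(counts, lesion_eff)
                        )
                        pl_total = sum(
                            c["pl"]
                            * (spec.radial_profile[b]["pl"] + subj_eff[b] + eff[b]["pl"])
                            for c, eff in zip(counts, lesion_eff)
                        )
                        vois["avgLesion"] = (les_total / n_lesion_vox, n_lesion_vox)
                        vois["avgPL"] = (pl_total / n_pl_vox, n_pl_vox)
                for voi_name, (mean, n_vox) in vois.items():
                    if n_vox <= 0 or np.isnan(mean):
                        continue
                    value = mean + (
                        float(rng.normal(0.0, sig_v / np.sqrt(n_vox))) if sig_v > 0 else 0.0
                    )
                    records.append(
                        (subject, group, b, voi_name, "subject", -1, value, n_vox)
                    )
    from .extract import COHORT_COLUMNS

    return pd.DataFrame(records, columns=COHORT_COLUMNS)
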