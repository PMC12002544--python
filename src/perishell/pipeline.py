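"""End-to-end analysis: maps + masks -> VOIs -> cohort table -> statistics.

One subject at a time: resample every quantitative map onto the
anatomical reference grid (trilinear for maps, nearest-neighbor for
masks), derive the T1w/T2w ratio when the weighted images are supplied,
intersect the per-map coverage into the common imaging volume, build the
VOI set, and extract lesion- and subject-level means.  Cohort-level
assembly simply concatenates subject records; group medians and the test
battery operate on the resulting long table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .extract import lesion_level_table, subject_level_summary
from .phantom import SyntheticSubject
from .voi import VOIParams, VOISet, build_voi_set
from .volume import (
    ReferenceGrid,
    Volume,
    common_imaging_volume,
    read_volume,
    resample_nearest,
    resample_trilinear,
    t1w_t2w_ratio,
)

__all__ = ["SubjectResult", "analyze_cohort", "analyze_subject", "load_cohort_dir"]

_MASK_NAMES = ("lesion_mask", "gm_prob", "wm_prob")
_WEIGHTED = ("T1w", "T2w")


@dataclass
class SubjectResult:
    subject: str
    group: str
    records: pd.DataFrame
    vois: VOISet
    dropped: list = field(default_factory=list)


def analyze_subject(
    subject: str,
    group: str,
    maps: dict[str, Volume],
    gm_prob: Volume,
    wm_prob: Volume,
    lesion_mask: Volume | None = None,
    params: VOIParams = VOIParams(),
) -> SubjectResult:
    """Run the single-subject analysis.

    ``maps`` holds the quantitative maps (any subset of the nine-marker
    panel, on arbitrary grids) and optionally the weighted ``T1w``/``T2w``
    images from which the T1w/T2w ratio is derived.  HC subjects pass no
    lesion mask; their WM/GM VOIs are built against an empty one.
    """
    import numpy as np

    ref_vol = lesion_mask if lesion_mask is not None else wm_prob
    grid = ReferenceGrid(shape=ref_vol.shape, affine=ref_vol.affine)

    def on_grid_mask(v: Volume) -> Volume:
        return v if v.same_grid(grid) else resample_nearest(v, grid)

    def on_grid_map(v: Volume) -> Volume:
        return v if v.same_grid(grid) else resample_trilinear(v, grid)

    gm_prob = on_grid_mask(gm_prob)
    wm_prob = on_grid_mask(wm_prob)
    if lesion_mask is None:
        lesion_mask = Volume(
            data=np.zeros(grid.shape, dtype=np.uint8), affine=grid.affine.copy()
        )
    else:
        lesion_mask = on_grid_mask(lesion_mask)

    panel: dict[str, Volume] = {}
    for name, vol in maps.items():
        if name in _WEIGHTED:
            continue
        panel[name] = on_grid_map(vol)
    if "T1wT2w" not in panel and all(w in maps for w in _WEIGHTED):
        panel["T1wT2w"] = t1w_t2w_ratio(
            on_grid_map(maps["T1w"]), on_grid_map(maps["T2w"])
        )

    common = common_imaging_volume(list(panel.values()))
    vois = build_voi_set(lesion_mask, gm_prob, wm_prob, common, params)

    frames = [subject_level_summary(panel, vois, subject=subject, group=group)]
    if group == "MS":
        frames.append(lesion_level_table(panel, vois, subject=subject, group=group))
    records = pd.concat(frames, ignore_index=True)
    return SubjectResult(
        subject=subject, group=group, records=records, vois=vois, dropped=vois.dropped
    )


def _analyze_synthetic(sub: SyntheticSubject, params: VOIParams) -> SubjectResult:
    maps = dict(sub.panel)
    # the ratio map is always recomputed from the weighted images,
    # exactly as for an on-disk cohort
    maps.pop("T1wT2w", None)
    maps["T1w"] = sub.t1w
    maps["T2w"] = sub.t2w
    return analyze_subject(
        sub.subject,
        sub.group,
        maps,
        sub.gm_prob,
        sub.wm_prob,
        lesion_mask=sub.lesion_mask if sub.group == "MS" else None,
        params=params,
    )


def load_cohort_dir(cohort_dir: str | Path):
    """Yield (subject, group, {map name: Volume}) from a cohort manifest."""
    cohort_dir = Path(cohort_dir)
    manifest = cohort_dir / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(manifest)
    per_subject: dict[str, dict] = {}
    order: list[str] = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            sid = row["subject"]
            if sid not in per_subject:
                per_subject[sid] = {"group": row["group"], "maps": {}}
                order.append(sid)
            per_subject[sid]["maps"][row["map"]] = (row["file"], row["units"])
    for sid in order:
        entry = per_subject[sid]
        vols = {
            name: read_volume(cohort_dir / fname, units=units)
            for name, (fname, units) in entry["maps"].items()
        }
        yield sid, entry["group"], vols


def analyze_cohort(
    cohort: str | Path | list[SyntheticSubject],
    params: VOIParams = VOIParams(),
) -> tuple[pd.DataFrame, list[SubjectResult]]:
    """Analyze a cohort (directory path or in-memory synthetic subjects).

    Returns the concatenated long-format cohort table and per-subject
    results (VOI sets, dropped-lesion reports).
    """
    results: list[SubjectResult] = []
    if isinstance(cohort, (str, Path)):
        for sid, group, vols in load_cohort_dir(cohort):
            maps = {
                k: v for k, v in vols.items() if k not in _MASK_NAMES
            }
            results.append(
                analyze_subject(
                    sid,
                    group,
                    maps,
                    vols["gm_prob"],
                    vols["wm_prob"],
                    lesion_mask=vols.get("lesion_mask") if group == "MS" else None,
                    params=params,
                )
            )
    else:
        for sub in cohort:
            results.append(_analyze_synthetic(sub, params))
    if not results:
        raise ValueError("empty cohort")
    table = pd.concat([r.records for r in results], ignore_index=True)
    return table, results
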