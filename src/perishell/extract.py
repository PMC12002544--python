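"""Biomarker extraction: VOI means at lesion, subject, and group level.

The unit of analysis is the arithmetic mean of a quantitative map over a
VOI, excluding missing voxels.  Three levels are produced:

* lesion level -- each lesion (with its own PL and shells 1-3) is treated
  separately, one mean per (lesion, biomarker, VOI class);
* subject level -- per subject, one mean per biomarker per applicable VOI;
  ``avgLesion`` and ``avgPL`` are voxel-pooled means over the union lesion
  and union PL masks (so each voxel, not each lesion, carries equal
  weight);
* group level -- cohort medians and ranges of the subject means.

Everything funnels into a long-format table with one record per value,
which the statistics and reporting layers consume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .voi import VOISet
from .volume import Volume

__all__ = [
    "COHORT_COLUMNS",
    "group_level_medians",
    "lesion_level_table",
    "subject_level_summary",
    "voi_mean",
]

#: Columns of the long-format cohort table.
COHORT_COLUMNS = [
    "subject",
    "group",
    "biomarker",
    "voi",
    "level",
    "lesion_id",
    "value",
    "n_voxels",
]

#: Subject-level VOI names per group.
SUBJECT_VOIS_MS = ("avgLesion", "avgPL", "NAWM", "NAGM")
SUBJECT_VOIS_HC = ("WM", "GM")
LESION_VOIS = ("lesion", "pl", "shell1", "shell2", "shell3")


def voi_mean(map_vol: Volume, mask: Volume | np.ndarray) -> tuple[float, int]:
    """Mean of a map over a mask, skipping missing voxels.

    Returns ``(value, n_voxels)`` where n_voxels is the number of valid
    voxels that entered the mean.  An empty effective mask yields
    ``(nan, 0)``; the caller decides whether to drop or propagate.
    """
    m = mask.as_bool() if isinstance(mask, Volume) else np.asarray(mask, dtype=bool)
    if m.shape != map_vol.shape:
        raise ValueError("map and mask must be on the same grid")
    vals = map_vol.data[m]
    vals = vals[~np.isnan(vals)] if np.issubdtype(vals.dtype, np.floating) else vals
    if vals.size == 0:
        return float("nan"), 0
    return float(vals.mean()), int(vals.size)


def lesion_level_table(
    panel: dict[str, Volume],
    vois: VOISet,
    subject: str = "",
    group: str = "MS",
) -> pd.DataFrame:
    """One record per (retained lesion, biomarker, VOI class).

    VOI classes are lesion, PL, and shells 1-3 of each individual lesion.
    Cells whose effective mask is empty (e.g., a shell fully eaten by the
    WM intersection, or a missing modality) are omitted.
    """
    records = []
    for plv in vois.per_lesion_vois:
        for voi_name, mask in plv.masks().items():
            for biomarker, vol in panel.items():
                value, n = voi_mean(vol, mask)
                if n == 0:
                    continue
                records.append(
                    (subject, group, biomarker, voi_name, "lesion", plv.label, value, n)
                )
    return pd.DataFrame(records, columns=COHORT_COLUMNS)


def subject_level_summary(
    panel: dict[str, Volume],
    vois: VOISet,
    subject: str = "",
    group: str = "MS",
) -> pd.DataFrame:
    """Subject-level means: avgLesion/avgPL (MS) and (NA)WM, (NA)GM.

    avgLesion and avgPL pool voxels over the union lesion / union PL
    masks, so a patient's lesion count matters only through its voxels.
    Missing modalities simply contribute no records.
    """
    if group == "MS":
        masks = {
            "avgLesion": vois.lesion,
            "avgPL": vois.pl,
            "NAWM": vois.wm,
            "NAGM": vois.gm,
        }
    else:
        masks = {"WM": vois.wm, "GM": vois.gm}
    records = []
    for voi_name, mask in masks.items():
        for biomarker, vol in panel.items():
            value, n = voi_mean(vol, mask)
            if n == 0:
                continue
            records.append((subject, group, biomarker, voi_name, "subject", -1, value, n))
    return pd.DataFrame(records, columns=COHORT_COLUMNS)


def group_level_medians(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort median and (min, max) of subject means per (biomarker, VOI, group).

    Medians use the midpoint convention for even sample sizes.  Cells with
    no subject-level records are omitted.
    """
    subj = cohort[cohort["level"] == "subject"]
    if subj.empty:
        return pd.DataFrame(
            columns=["group", "biomarker", "voi", "median", "min", "max", "n_subjects"]
        )
    agg = (
        subj.groupby(["group", "biomarker", "voi"])["value"]
        .agg(median="median", min="min", max="max", n_subjects="count")
        .reset_index()
    )
    return agg
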