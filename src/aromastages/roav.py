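"""Relative odor activity values (rOAV).

A compound's aroma impact depends on its content *and* on how little
of it a human nose needs to notice. The odor activity of compound i is
its content-to-threshold ratio C_i / T_i; the rOAV rescales these so
the most aroma-active compound in the evaluation scope scores exactly
100:

    rOAV_i = (C_i / C_max) × (T_max / T_i) × 100
           = (C_i / T_i) / (C_max / T_max) × 100

where (C_max, T_max) belong to the reference compound with the highest
activity. Compounds with rOAV ≥ 1 are key aroma contributors; those
with 0.1 ≤ rOAV < 1 contribute to the overall profile; anything below
is minor. Compounds without a literature threshold cannot be scored
and are reported as ``no_threshold``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AbundanceTable,
    CompoundInfo,
    SampleMeta,
    Stage,
    UnitTag,
    ValidationError,
)
from .screening import ContrastResult

logger = logging.getLogger(__name__)

__all__ = [
    "ROAVTable",
    "compute_roav",
    "classify_contribution",
    "average_roav",
    "key_compound_report",
]

_SCOPES = ("global", "per_sample", "per_group")


def classify_contribution(roav: float) -> str:
    """Contribution band: key (≥ 1), contributor ([0.1, 1)), minor (< 0.1)."""
    if roav < 0:
        raise ValidationError(f"rOAV must be >= 0, got {roav}")
    if roav >= 1.0:
        return "key"
    if roav >= 0.1:
        return "contributor"
    return "minor"


@dataclass
class ROAVTable:
    """Per-compound, per-replicate and per-group rOAV summaries.

    ``per_sample`` holds replicate-level rOAVs (samples × compounds);
    ``summary`` aggregates them as mean ± SD per (batch, stage) group
    with the contribution class of the group mean.
    """

    reference_compound_id: str
    scope: str
    per_sample: pd.DataFrame
    summary: pd.DataFrame  # compound_id, batch, stage, roav_mean, roav_sd, ...
    no_threshold_ids: list[str]

    def group_mean(self, compound_id: str, batch: str, stage: Stage) -> float:
        m = self.summary
        row = m[(m["compound_id"] == compound_id) & (m["batch"] == batch)
                & (m["stage"] == stage.value)]
        if row.empty:
            raise ValidationError(
                f"no rOAV summary for {compound_id!r} in ({batch}, {stage.value})")
        return float(row["roav_mean"].iloc[0])

    def compound_group_means(self, compound_id: str) -> dict[tuple[str, str], float]:
        m = self.summary[self.summary["compound_id"] == compound_id]
        return {(r.batch, r.stage): float(r.roav_mean)
                for r in m.itertuples()}

    def average_over_groups(self, compound_id: str) -> float:
        """Mean of the per-group mean rOAVs (the "average rOAV")."""
        vals = list(self.compound_group_means(compound_id).values())
        return average_roav(vals)

    def to_records(self) -> list[dict]:
        df = self.summary.sort_values(["compound_id", "batch", "stage"],
                                      kind="mergesort")
        return df.to_dict(orient="records")


def compute_roav(
    contents: AbundanceTable,
    thresholds: Mapping[str, float],
    scope: str = "global",
    samples: Optional[Sequence[SampleMeta]] = None,
) -> ROAVTable:
    """Compute rOAVs for every thresholded compound.

    The reference (rOAV = 100) compound maximizes the mean
    content-to-threshold ratio over the scope: the whole dataset
    (``global``, default — makes rOAVs comparable across stages), each
    sample (``per_sample``) or each (batch, stage) group
    (``per_group``). Replicate-level rOAVs are summarized as
    mean ± SD per group when sample metadata is given. Ties in the
    reference argmax break by compound_id lexicographic order.
    """
    if scope not in _SCOPES:
        raise ValidationError(f"unknown scope {scope!r}; pick from {_SCOPES}")
    if contents.unit_tag is not UnitTag.percent:
        raise ValidationError(
            f"contents must be relative (percent) units, got "
            f"{contents.unit_tag.value}; run relative_content first")
    vals = contents.values
    if (vals.to_numpy() < 0).any():
        raise ValidationError("negative content")

    comp_ids = sorted(contents.compound_ids)  # lexicographic tie-break
    thr = {}
    for cid in comp_ids:
        t = thresholds.get(cid)
        if t is not None:
            if not t > 0:
                raise ValidationError(
                    f"compound {cid!r}: threshold must be > 0, got {t}")
            thr[cid] = float(t)
    if not thr:
        raise ValidationError("no compound has an odor threshold")
    no_threshold = [c for c in comp_ids if c not in thr]

    scored = list(thr)
    activity = vals[scored].div(pd.Series(thr), axis=1)  # C_i / T_i per sample

    meta = {s.sample_id: s for s in samples} if samples else {}

    if scope == "global":
        ref = _argmax_ref(activity.mean(axis=0))
        per_sample = activity.div(float(activity[ref].mean())) * 100.0
    elif scope == "per_group":
        if not samples:
            raise ValidationError("per_group scope needs sample metadata")
        per_sample = activity.copy()
        refs = {}
        for (batch, stage), ids in _group_ids(samples).items():
            grp = activity.loc[ids]
            ref_g = _argmax_ref(grp.mean(axis=0))
            refs[(batch, stage)] = ref_g
            per_sample.loc[ids] = grp.div(float(grp[ref_g].mean())) * 100.0
        ref = min(set(refs.values())) if len(set(refs.values())) == 1 else \
            _argmax_ref(activity.mean(axis=0))
    else:  # per_sample
        ref_series = activity.idxmax(axis=1)
        per_sample = activity.div(activity.max(axis=1), axis=0) * 100.0
        ref = _argmax_ref(activity.mean(axis=0))

    summary = _summarize(per_sample, meta)
    logger.info("rOAV reference compound: %s (scope=%s)", ref, scope)
    return ROAVTable(
        reference_compound_id=ref, scope=scope, per_sample=per_sample,
        summary=summary, no_threshold_ids=no_threshold,
    )


def _argmax_ref(mean_activity: pd.Series) -> str:
    best = mean_activity.max()
    candidates = sorted(mean_activity.index[mean_activity == best])
    return candidates[0]


def _group_ids(samples: Sequence[SampleMeta]) -> dict[tuple[str, Stage], list[str]]:
    out: dict[tuple[str, Stage], list[str]] = {}
    for s in samples:
        out.setdefault((s.batch, s.stage), []).append(s.sample_id)
    return out


def _summarize(per_sample: pd.DataFrame,
               meta: Mapping[str, SampleMeta]) -> pd.DataFrame:
    rows = []
    if meta:
        groups: dict[tuple[str, Stage], list[str]] = {}
        for sid in per_sample.index:
            s = meta.get(sid)
            if s is None:
                raise ValidationError(f"sample {sid!r} missing from metadata")
            groups.setdefault((s.batch, s.stage), []).append(sid)
        for (batch, stage), ids in groups.items():
            block = per_sample.loc[ids]
            means = block.mean(axis=0)
            sds = block.std(axis=0, ddof=1) if len(ids) > 1 else \
                pd.Series(0.0, index=block.columns)
            for cid in per_sample.columns:
                m = float(means[cid])
                rows.append((cid, batch, stage.value, m, float(sds[cid]),
                             classify_contribution(m)))
    else:
        means = per_sample.mean(axis=0)
        sds = per_sample.std(axis=0, ddof=1) if len(per_sample) > 1 else \
            pd.Series(0.0, index=per_sample.columns)
        for cid in per_sample.columns:
            m = float(means[cid])
            rows.append((cid, "all", "all", m, float(sds[cid]),
                         classify_contribution(m)))
    return pd.DataFrame(
        rows, columns=["compound_id", "batch", "stage", "roav_mean",
                       "roav_sd", "contribution_class"])


def average_roav(group_values: Sequence[float]) -> float:
    """Arithmetic mean of per-group rOAVs (reported to 2 decimals in
    summaries; returned at full precision here)."""
    vals = [float(v) for v in group_values]
    if not vals:
        raise ValidationError("cannot average an empty list of rOAVs")
    return float(np.mean(vals))


def key_compound_report(
    roav_table: ROAVTable,
    screens: Sequence[ContrastResult],
) -> pd.DataFrame:
    """Restrict rOAV reporting to screen-selected compounds.

    A compound enters the report if any contrast selected it; it is
    flagged ``primary`` when any group-mean rOAV reaches 1. Selected
    compounds lacking a threshold are listed with status
    ``no_threshold`` so they are visibly unscored rather than silently
    dropped.
    """
    selected: set[str] = set()
    for s in screens:
        selected |= s.selected_ids
    scored = set(roav_table.summary["compound_id"])
    overlap = selected & (scored | set(roav_table.no_threshold_ids))
    if not overlap:
        logger.warning("no overlap between screen selection and rOAV table")
        return pd.DataFrame(columns=["compound_id", "max_group_roav",
                                     "average_roav", "status"])
    rows = []
    for cid in sorted(overlap):
        if cid in scored:
            gm = roav_table.compound_group_means(cid)
            max_roav = max(gm.values())
            avg = average_roav(list(gm.values()))
            status = "primary" if max_roav >= 1.0 else \
                classify_contribution(max_roav)
            rows.append((cid, max_roav, avg, status))
        else:
            rows.append((cid, float("nan"), float("nan"), "no_threshold"))
    return pd.DataFrame(rows, columns=["compound_id", "max_group_roav",
                                       "average_roav", "status"])
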