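"""Flavor-wheel aggregation of key aroma compounds.

Key compounds (rOAV ≥ 1 in at least one batch-stage group) are binned
into seven sensory categories — minty, woody, floral, fruity, green,
phenol, creamy — via their annotated aroma category. Per category the
wheel carries the member compounds with descriptors and average rOAV,
the cumulative (summed) rOAV per (batch, stage) group, and a Welch
t-test comparison between batches with the usual star annotation
(ns, *, **, ***, ****).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    AromaCategory,
    CompoundInfo,
    SampleMeta,
    Stage,
    ValidationError,
)
from .roav import ROAVTable, average_roav

logger = logging.getLogger(__name__)

__all__ = [
    "FlavorWheel",
    "map_categories",
    "cumulative_roav",
    "compare_category",
    "stars_for_p",
    "build_wheel",
    "replicate_category_totals",
]

WHEEL_CATEGORIES = tuple(c.value for c in AromaCategory.wheel_order())


def stars_for_p(p: float) -> str:
    """Monotone significance annotation: ns, *, **, ***, ****."""
    if not 0 <= p <= 1:
        raise ValidationError(f"p must be in [0, 1], got {p}")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "ns"


def map_categories(
    compounds: Sequence[CompoundInfo],
    roav_table: ROAVTable,
) -> dict[str, list[str]]:
    """Assign each qualifying compound to exactly one wheel category.

    A compound qualifies when any group-mean rOAV reaches 1. A
    qualifying compound without an aroma category but with descriptors
    falls back to the category named by its first descriptor if that
    matches a wheel sector; otherwise it is an error listing the
    compound. Category ``none`` compounds are excluded with a warning.
    """
    by_id = {c.compound_id: c for c in compounds}
    membership: dict[str, list[str]] = {c: [] for c in WHEEL_CATEGORIES}
    missing: list[str] = []
    for cid in sorted(set(roav_table.summary["compound_id"])):
        gm = roav_table.compound_group_means(cid)
        if max(gm.values()) < 1.0:
            continue
        info = by_id.get(cid)
        if info is None:
            missing.append(cid)
            continue
        cat = info.aroma_category
        if cat is AromaCategory.none:
            fallback = next(
                (d for d in info.aroma_descriptors if d in WHEEL_CATEGORIES),
                None)
            if fallback is None:
                logger.warning(
                    "key compound %s has no aroma category; excluded", cid)
                continue
            logger.warning(
                "key compound %s: category taken from first descriptor %r",
                cid, fallback)
            cat_name = fallback
        else:
            cat_name = cat.value
        membership[cat_name].append(cid)
    if missing:
        raise ValidationError(
            f"qualifying compounds lack annotation records: {missing}")
    return membership


def cumulative_roav(
    membership: Mapping[str, Sequence[str]],
    roav_table: ROAVTable,
    group: tuple[str, Stage],
) -> dict[str, float]:
    """Per-category sum of member group-mean rOAVs; empty category → 0."""
    batch, stage = group
    present = set(zip(roav_table.summary["batch"],
                      roav_table.summary["stage"]))
    if (batch, stage.value) not in present:
        raise ValidationError(
            f"group ({batch}, {stage.value}) absent from rOAV table")
    out: dict[str, float] = {}
    for cat in WHEEL_CATEGORIES:
        total = 0.0
        for cid in membership.get(cat, ()):
            total += roav_table.group_mean(cid, batch, stage)
        out[cat] = total
    return out


def replicate_category_totals(
    membership: Mapping[str, Sequence[str]],
    roav_table: ROAVTable,
    sample_ids: Sequence[str],
) -> dict[str, np.ndarray]:
    """Per-category rOAV totals at replicate resolution (for the t-test)."""
    block = roav_table.per_sample.loc[list(sample_ids)]
    out = {}
    for cat in WHEEL_CATEGORIES:
        members = [c for c in membership.get(cat, ()) if c in block.columns]
        out[cat] = block[members].sum(axis=1).to_numpy() if members \
            else np.zeros(len(sample_ids))
    return out


def compare_category(
    batch1_values: Sequence[float],
    batch2_values: Sequence[float],
) -> tuple[float, str]:
    """Two-sided Welch t-test between batches on replicate-level totals."""
    a = np.asarray(batch1_values, dtype=float)
    b = np.asarray(batch2_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need >= 2 replicate totals on each side")
    if np.array_equal(a, b) or (a.std() == 0 and b.std() == 0
                                and a.mean() == b.mean()):
        return 1.0, "ns"
    t, p = stats.ttest_ind(a, b, equal_var=False)
    p = float(p)
    return p, stars_for_p(p)


@dataclass
class FlavorWheel:
    """Hierarchical category → compound → descriptor structure."""

    categories: list[str]
    members: dict[str, list[dict]]            # category -> compound entries
    cumulative: dict[str, dict[str, float]]   # "batch|stage" -> cat -> total
    comparisons: dict[str, dict]              # category -> {p, stars}

    def to_records(self) -> dict:
        return {
            "categories": {
                cat: self.members.get(cat, []) for cat in self.categories
            },
            "cumulative_roav": self.cumulative,
            "comparisons": self.comparisons,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_records(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FlavorWheel":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            categories=list(payload["categories"]),
            members={k: v for k, v in payload["categories"].items()},
            cumulative=payload["cumulative_roav"],
            comparisons=payload["comparisons"],
        )


def build_wheel(
    membership: Mapping[str, Sequence[str]],
    roav_table: ROAVTable,
    compounds: Sequence[CompoundInfo],
    cumulative: Mapping[str, Mapping[str, float]],
    comparisons: Mapping[str, tuple[float, str]],
) -> FlavorWheel:
    """Assemble the wheel with deterministic ordering.

    Categories appear in canonical wheel order; compounds within a
    sector sort by descending average rOAV (ties by compound_id).
    """
    by_id = {c.compound_id: c for c in compounds}
    members: dict[str, list[dict]] = {}
    for cat in WHEEL_CATEGORIES:
        entries = []
        for cid in membership.get(cat, ()):
            info = by_id.get(cid)
            gm = roav_table.compound_group_means(cid)
            entries.append({
                "compound": cid,
                "name": info.name if info else cid,
                "descriptors": list(info.aroma_descriptors) if info else [],
                "avg_roav": round(average_roav(list(gm.values())), 2),
                "per_group": {f"{b}|{s}": round(v, 4)
                              for (b, s), v in sorted(gm.items())},
            })
        entries.sort(key=lambda e: (-e["avg_roav"], e["compound"]))
        members[cat] = entries
    return FlavorWheel(
        categories=list(WHEEL_CATEGORIES),
        members=members,
        cumulative={k: dict(v) for k, v in cumulative.items()},
        comparisons={cat: {"p": p, "stars": s}
                     for cat, (p, s) in comparisons.items()},
    )
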