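"""Differential-compound selection and cross-contrast set algebra.

A compound is called differential for a contrast when its OPLS-DA
VIP exceeds the VIP threshold AND its univariate p-value is below the
p threshold (both strict, the conventional "VIP > 1.0, p < 0.05"
rule). The Venn partition then splits the union of selected compounds
into exact membership cells across any number of named contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chemometrics import (
    OPLSDAModel,
    autoscale,
    cross_validate_q2,
    fit_oplsda,
    permutation_test,
)
from .datamodel import (
    AbundanceTable,
    Contrast,
    SampleMeta,
    ValidationError,
    samples_in_group,
)
from .quant import univariate_table

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastResult",
    "select_differential",
    "venn_partition",
    "run_contrast",
    "VennPartition",
]


@dataclass
class ContrastResult:
    """Per-compound screening outcome for one two-group contrast."""

    contrast: str
    table: pd.DataFrame  # compound_id, vip, p, log2fc, regulation, selected
    vip_threshold: float
    p_threshold: float
    model: Optional[OPLSDAModel] = None

    @property
    def selected_ids(self) -> set[str]:
        return set(self.table.loc[self.table["selected"], "compound_id"])

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())


def select_differential(
    vip: Sequence[float],
    pvals: Sequence[float],
    log2fc: Sequence[float],
    compound_ids: Sequence[str],
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
    regulation: Optional[Sequence[str]] = None,
    contrast: str = "",
) -> ContrastResult:
    """Apply the VIP ∧ p selection rule (strict inequalities)."""
    vip = np.asarray(vip, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    log2fc = np.asarray(log2fc, dtype=float)
    n = len(compound_ids)
    if not (len(vip) == len(pvals) == len(log2fc) == n):
        raise ValidationError(
            "vip, pvals, log2fc and compound_ids must be aligned")
    selected = (vip > vip_threshold) & (pvals < p_threshold)
    df = pd.DataFrame({
        "compound_id": list(compound_ids),
        "vip": vip,
        "p": pvals,
        "log2fc": log2fc,
        "selected": selected,
    })
    if regulation is not None:
        df["regulation"] = list(regulation)
    logger.info("contrast %s: %d/%d compounds selected (VIP > %g, p < %g)",
                contrast or "?", int(selected.sum()), n,
                vip_threshold, p_threshold)
    return ContrastResult(contrast=contrast, table=df,
                          vip_threshold=vip_threshold,
                          p_threshold=p_threshold)


def run_contrast(
    table: AbundanceTable,
    samples: Sequence[SampleMeta],
    contrast: Contrast,
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    n_ortho: int = 1,
    n_folds: int = 7,
    n_perm: int = 0,
    seed: int = 0,
    scaling: str = "unit_variance",
) -> ContrastResult:
    """Full screen for one contrast: OPLS-DA VIP + per-compound ANOVA.

    Group a is the reference (earlier stage); positive predictive
    scores and positive log2 fold changes point to group b. Set
    ``n_perm > 0`` to attach a label-permutation validation record to
    the fitted model.
    """
    ids_a = samples_in_group(samples, contrast.group_a)
    ids_b = samples_in_group(samples, contrast.group_b)
    if not ids_a or not ids_b:
        empty = contrast.group_a if not ids_a else contrast.group_b
        raise ValidationError(
            f"contrast {contrast.name!r}: no samples in group "
            f"({empty[0]}, {empty[1].value})")
    sub = table.subset_samples(ids_a + ids_b)
    y = [0] * len(ids_a) + [1] * len(ids_b)
    X = autoscale(sub, mode=scaling)
    model = fit_oplsda(X, y, n_ortho=n_ortho)
    model.q2 = cross_validate_q2(X, y, n_ortho=n_ortho,
                                 n_folds=n_folds, seed=seed)
    if n_perm > 0:
        model.permutation = permutation_test(
            X, y, n_ortho=n_ortho, n_perm=n_perm, seed=seed,
            n_folds=n_folds)
    uni = univariate_table(sub, ids_a, ids_b, fc_threshold=fc_threshold,
                           p_threshold=p_threshold)
    result = select_differential(
        vip=model.vip, pvals=uni["p"], log2fc=uni["log2fc"],
        compound_ids=list(sub.compound_ids),
        vip_threshold=vip_threshold, p_threshold=p_threshold,
        regulation=list(uni["regulation"]), contrast=contrast.name,
    )
    result.model = model
    return result


@dataclass
class VennPartition:
    """Exact membership cells over ≥ 2 named selected-compound sets."""

    contrast_names: list[str]
    cells: dict[frozenset, set[str]]  # subset of names -> compounds

    @property
    def common(self) -> set[str]:
        """The full-intersection cell ("common differential compounds")."""
        return set(self.cells.get(frozenset(self.contrast_names), set()))

    def cell(self, *names: str) -> set[str]:
        return set(self.cells.get(frozenset(names), set()))

    def to_records(self) -> dict:
        return {
            "contrasts": self.contrast_names,
            "cells": {
                "+".join(sorted(key)): sorted(val)
                for key, val in self.cells.items() if val
            },
        }


def venn_partition(selected_sets: Mapping[str, set[str]]) -> VennPartition:
    """Partition compounds by the exact subset of contrasts selecting them."""
    names = list(selected_sets)
    if len(names) < 2:
        raise ValidationError("Venn partition needs at least 2 contrasts")
    universe: set[str] = set().union(*selected_sets.values())
    cells: dict[frozenset, set[str]] = {}
    for compound in universe:
        members = frozenset(n for n in names if compound in selected_sets[n])
        cells.setdefault(members, set()).add(compound)
    return VennPartition(contrast_names=names, cells=cells)
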