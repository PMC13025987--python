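"""Core data model shared by every analysis stage.

The central container is :class:`AbundanceTable`, a nonnegative
compound-by-sample matrix (samples are rows) carrying a unit tag that
records where in the semi-quantification chain the values sit:
``raw_area`` (GC-MS peak areas), ``is_normalized`` (µg/g after internal
standard scaling) or ``percent`` (per-sample relative content).
Compound annotations (chemical class, aroma descriptors and category,
odor threshold) and the batch/stage/replicate sample design live in
:class:`CompoundInfo` and :class:`SampleMeta` records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Stage",
    "ChemicalClass",
    "AromaCategory",
    "UnitTag",
    "AbundanceTable",
    "SampleMeta",
    "CompoundInfo",
    "Contrast",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input table violates a data-model invariant."""


class Stage(str, Enum):
    """Pile-fermentation sampling stage, in process order."""

    RM = "RM"  # raw material
    IF = "IF"  # intermediate fermentation (midpoint)
    FF = "FF"  # final fermentation

    @classmethod
    def ordered(cls) -> list["Stage"]:
        return [cls.RM, cls.IF, cls.FF]


class ChemicalClass(str, Enum):
    hydrocarbon = "hydrocarbon"
    alcohol = "alcohol"
    ketone = "ketone"
    ester = "ester"
    aldehyde = "aldehyde"
    heterocyclic = "heterocyclic"
    aromatic = "aromatic"
    phenol = "phenol"
    acid = "acid"
    other = "other"


class AromaCategory(str, Enum):
    """Sensory attributes of the flavor wheel (canonical order)."""

    minty = "minty"
    woody = "woody"
    floral = "floral"
    fruity = "fruity"
    green = "green"
    phenol = "phenol"
    creamy = "creamy"
    none = "none"

    @classmethod
    def wheel_order(cls) -> list["AromaCategory"]:
        return [cls.minty, cls.woody, cls.floral, cls.fruity,
                cls.green, cls.phenol, cls.creamy]


class UnitTag(str, Enum):
    raw_area = "raw_area"
    is_normalized = "is_normalized"
    percent = "percent"


@dataclass(frozen=True)
class SampleMeta:
    """One fermentation sample: (batch, stage, replicate) identifies it."""

    sample_id: str
    batch: str
    stage: Stage
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be >= 1, "
                f"got {self.replicate}"
            )

    @property
    def group(self) -> tuple[str, Stage]:
        return (self.batch, self.stage)


@dataclass(frozen=True)
class CompoundInfo:
    """Annotation record for one volatile compound.

    ``odor_threshold`` is the literature perception threshold in µg/kg;
    compounds without one are excluded from odor-activity scoring.
    ``aroma_category`` places the compound in one flavor-wheel sector.
    """

    compound_id: str
    name: str
    chemical_class: ChemicalClass
    aroma_descriptors: tuple[str, ...] = ()
    aroma_category: AromaCategory = AromaCategory.none
    odor_threshold: Optional[float] = None
    threshold_source: str = ""

    def __post_init__(self) -> None:
        if self.odor_threshold is not None and not self.odor_threshold > 0:
            raise ValidationError(
                f"compound {self.compound_id!r}: odor_threshold must be > 0, "
                f"got {self.odor_threshold}"
            )


@dataclass
class AbundanceTable:
    """Nonnegative samples × compounds abundance matrix.

    ``values`` is a DataFrame indexed by sample_id with one column per
    compound_id. An optional internal-standard column may be present
    while ``unit_tag`` is ``raw_area``; it is consumed (and removed) by
    the internal-standard normalization step.
    """

    values: pd.DataFrame
    unit_tag: UnitTag = UnitTag.raw_area
    internal_standard_id: Optional[str] = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].tolist()
            raise ValidationError(f"duplicated sample ids: {dupes}")
        if v.columns.has_duplicates:
            dupes = v.columns[v.columns.duplicated()].tolist()
            raise ValidationError(f"duplicated compound ids: {dupes}")
        arr = v.to_numpy(dtype=float)
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing abundance at sample {v.index[r]!r}, "
                f"compound {v.columns[c]!r} (explicit 0 means not detected)"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative abundance {arr[r, c]} at sample {v.index[r]!r}, "
                f"compound {v.columns[c]!r}"
            )
        if (self.internal_standard_id is not None
                and self.internal_standard_id not in v.columns):
            raise ValidationError(
                f"internal standard {self.internal_standard_id!r} is not a "
                "column of the abundance table"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.values.index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return replace(self, values=self.values.loc[list(sample_ids)].copy())

    def drop_compound(self, compound_id: str) -> "AbundanceTable":
        return AbundanceTable(
            values=self.values.drop(columns=[compound_id]),
            unit_tag=self.unit_tag,
            internal_standard_id=None
            if compound_id == self.internal_standard_id
            else self.internal_standard_id,
        )


@dataclass(frozen=True)
class Contrast:
    """A named two-group comparison between (batch, stage) cells.

    Group b is conventionally the later stage, so positive log2
    fold changes mean accumulation during fermentation.
    """

    name: str
    group_a: tuple[str, Stage]
    group_b: tuple[str, Stage]

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValidationError(
                f"contrast {self.name!r}: groups must be disjoint"
            )

    @classmethod
    def parse(cls, text: str) -> "Contrast":
        """Parse ``'IF1:RM1'``-style shorthand (stage + batch number).

        A purely numeric batch part is normalized to the ``F``-prefixed
        batch labels of the two-batch study design (``1`` → ``F1``).
        """

        def _group(token: str) -> tuple[str, Stage]:
            stage = Stage(token[:2])
            batch = token[2:]
            if batch.isdigit():
                batch = f"F{batch}"
            return (batch, stage)

        try:
            b_txt, a_txt = text.split(":")
            gb, ga = _group(b_txt), _group(a_txt)
        except (ValueError, IndexError) as exc:
            raise ValidationError(
                f"cannot parse contrast {text!r}; expected like 'IF1:RM1'"
            ) from exc
        return cls(name=f"{b_txt}_vs_{a_txt}", group_a=ga, group_b=gb)


def samples_in_group(
    samples: Sequence[SampleMeta], group: tuple[str, Stage]
) -> list[str]:
    """Sample ids belonging to one (batch, stage) cell, in input order."""
    batch, stage = group
    return [s.sample_id for s in samples
            if s.batch == batch and s.stage == stage]
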