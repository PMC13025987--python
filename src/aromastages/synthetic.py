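"""Synthetic volatile-profile generator emulating a two-batch,
three-stage pile-fermentation study.

The generator produces the abundance/annotation/metadata trio the
pipeline consumes, with the statistical structure the analysis assumes:

* log-normal peak areas (positive, right-skewed, like GC-MS data);
* class-level stage trends (alcohols decline over fermentation,
  esters and aromatics rise);
* a per-compound batch signature that shrinks stage by stage, so the
  two batches start apart and converge as fermentation progresses;
* a set of planted differential compounds with a known minimum
  |log2| stage effect, recorded in :class:`GroundTruth` so screening
  sensitivity and false-discovery rate can be measured;
* one pseudo-compound spiked at a constant amount acting as the
  internal-standard channel.

Default dimensions mirror the emulated study: 2 batches × 3 stages ×
3 biological replicates (18 samples) and 134 compounds across 10
chemical classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .datamodel import (
    AbundanceTable,
    AromaCategory,
    ChemicalClass,
    CompoundInfo,
    SampleMeta,
    Stage,
    UnitTag,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "export_ground_truth",
    "DEFAULT_CLASS_COUNTS",
    "INTERNAL_STANDARD_ID",
]

INTERNAL_STANDARD_ID = "IS_3hexanone_d4"

# Class inventory of the emulated study: 134 identified volatiles.
DEFAULT_CLASS_COUNTS: dict[ChemicalClass, int] = {
    ChemicalClass.hydrocarbon: 33,
    ChemicalClass.alcohol: 22,
    ChemicalClass.ketone: 15,
    ChemicalClass.ester: 13,
    ChemicalClass.aldehyde: 13,
    ChemicalClass.heterocyclic: 12,
    ChemicalClass.aromatic: 8,
    ChemicalClass.phenol: 6,
    ChemicalClass.acid: 5,
    ChemicalClass.other: 7,
}

# Multiplicative class trends (RM→IF factor, IF→FF factor): alcohols
# decline during fermentation while esters and aromatics accumulate.
DEFAULT_CLASS_STAGE_MULTIPLIERS: dict[ChemicalClass, tuple[float, float]] = {
    ChemicalClass.hydrocarbon: (0.95, 0.95),
    ChemicalClass.alcohol: (0.75, 0.80),
    ChemicalClass.ketone: (1.00, 1.00),
    ChemicalClass.ester: (1.25, 1.20),
    ChemicalClass.aldehyde: (1.00, 0.95),
    ChemicalClass.heterocyclic: (1.05, 1.05),
    ChemicalClass.aromatic: (1.25, 1.20),
    ChemicalClass.phenol: (1.05, 1.00),
    ChemicalClass.acid: (1.00, 1.00),
    ChemicalClass.other: (1.00, 1.00),
}

# Aroma descriptor lexicon: category -> representative notes.
_DESCRIPTOR_LEXICON: dict[AromaCategory, tuple[str, ...]] = {
    AromaCategory.minty: ("minty", "cooling", "herbal"),
    AromaCategory.woody: ("woody", "pine", "earthy"),
    AromaCategory.floral: ("floral", "rose", "honey"),
    AromaCategory.fruity: ("fruity", "citrus", "berry"),
    AromaCategory.green: ("green", "grassy", "fresh"),
    AromaCategory.phenol: ("phenolic", "medicinal", "smoky"),
    AromaCategory.creamy: ("creamy", "buttery", "sweet"),
}


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the generator.

    ``batch_effect_sd`` gives the natural-log sd of the per-compound
    batch signature at each stage; the default halves per transition so
    batches converge. ``replicate_cv`` is the within-group coefficient
    of variation of the log-normal replicate noise. Planted compounds
    receive an additional stage effect of at least
    ``planted_log2_effect`` in |log2| (default 2, i.e. 4-fold), applied
    from the IF stage onward with random sign.
    """

    class_counts: dict[ChemicalClass, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    n_batches: int = 2
    stages: tuple[Stage, ...] = (Stage.RM, Stage.IF, Stage.FF)
    n_replicates: int = 3
    baseline_log_mean: float = 13.0   # ln peak area, ~4.4e5 counts
    baseline_log_sd: float = 1.5
    class_stage_multipliers: dict[ChemicalClass, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_STAGE_MULTIPLIERS))
    batch_effect_sd: tuple[float, ...] = (0.30, 0.15, 0.075)
    replicate_cv: float = 0.20
    n_planted_differential: int = 20
    planted_log2_effect: float = 2.0
    threshold_log_range: tuple[float, float] = (0.1, 1000.0)  # µg/kg
    is_area: float = 1.0e6
    seed: int = 0

    def validate(self) -> None:
        if not self.class_counts or any(v <= 0 for v in self.class_counts.values()):
            raise ValidationError("class_counts must all be positive")
        if self.n_batches < 1 or self.n_replicates < 1:
            raise ValidationError("n_batches and n_replicates must be >= 1")
        if self.replicate_cv < 0:
            raise ValidationError("replicate_cv must be >= 0")
        if self.planted_log2_effect < 0:
            raise ValidationError("planted_log2_effect must be >= 0")
        if len(self.batch_effect_sd) < len(self.stages):
            raise ValidationError(
                "batch_effect_sd needs one value per stage")
        if any(sd < 0 for sd in self.batch_effect_sd):
            raise ValidationError("batch_effect_sd values must be >= 0")
        lo, hi = self.threshold_log_range
        if not (0 < lo <= hi):
            raise ValidationError("threshold_log_range must satisfy 0 < lo <= hi")
        for cls, (f1, f2) in self.class_stage_multipliers.items():
            if f1 <= 0 or f2 <= 0:
                raise ValidationError(
                    f"stage multipliers for {cls.value} must be > 0")
        if self.n_planted_differential > sum(self.class_counts.values()):
            raise ValidationError(
                "cannot plant more differential compounds than exist")

    @property
    def n_compounds(self) -> int:
        return sum(self.class_counts.values())


@dataclass
class GroundTruth:
    """Planted differential compounds and their true stage effects."""

    planted_ids: set[str]
    stage_multipliers: dict[str, dict[str, float]]  # compound -> stage -> ×
    seed: int


def generate_dataset(
    config: Optional[SimulationConfig] = None,
) -> tuple[AbundanceTable, list[CompoundInfo], list[SampleMeta], GroundTruth]:
    """Generate one seeded abundance/annotation/metadata trio + truth.

    The expected abundance of compound c in sample s is

        baseline_c × stage_factor_c(stage) × batch_factor_c(batch, stage)

    times log-normal replicate noise with CV ``replicate_cv``. The
    batch factor is exp(sd_stage × z_{c,batch}) with a single latent
    z per (compound, batch), so the batch signature keeps its direction
    but shrinks as fermentation homogenizes the piles.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    compounds = _make_compounds(config, rng)
    comp_ids = [c.compound_id for c in compounds if c.compound_id != INTERNAL_STANDARD_ID]
    samples = _make_samples(config)

    n_c = len(comp_ids)
    baseline = np.exp(rng.normal(config.baseline_log_mean,
                                 config.baseline_log_sd, size=n_c))

    # cumulative class stage factors, per compound
    cls_by_comp = {c.compound_id: c.chemical_class for c in compounds}
    stage_factor = np.ones((len(config.stages), n_c))
    for j, cid in enumerate(comp_ids):
        f1, f2 = config.class_stage_multipliers.get(
            cls_by_comp[cid], (1.0, 1.0))
        cum = 1.0
        for i, _stage in enumerate(config.stages):
            if i == 1:
                cum *= f1
            elif i >= 2:
                cum *= f2
            stage_factor[i, j] = cum

    # planted differential effects: |log2| >= planted_log2_effect from IF on
    planted_idx = rng.choice(n_c, size=config.n_planted_differential,
                             replace=False)
    planted_ids: set[str] = set()
    truth_mult: dict[str, dict[str, float]] = {}
    for j in planted_idx:
        cid = comp_ids[j]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        log2_eff = config.planted_log2_effect * (1.0 + 0.25 * rng.random())
        mult = 2.0 ** (sign * log2_eff)
        for i, stage in enumerate(config.stages):
            if i >= 1:
                stage_factor[i, j] *= mult
        planted_ids.add(cid)
        truth_mult[cid] = {
            stage.value: (mult if i >= 1 else 1.0)
            for i, stage in enumerate(config.stages)
        }

    # batch signature: one latent z per (compound, batch), stage-scaled sd
    z = rng.normal(size=(config.n_batches, n_c))
    sigma_rep = float(np.sqrt(np.log1p(config.replicate_cv ** 2)))

    stage_index = {s: i for i, s in enumerate(config.stages)}
    rows = []
    for s in samples:
        i = stage_index[s.stage]
        b = int(s.batch.lstrip("F")) - 1
        mean = (baseline
                * stage_factor[i]
                * np.exp(config.batch_effect_sd[i] * z[b]))
        noise = np.exp(rng.normal(-0.5 * sigma_rep ** 2, sigma_rep, size=n_c))
        row = mean * noise
        rows.append(row)

    values = pd.DataFrame(rows, index=[s.sample_id for s in samples],
                          columns=comp_ids)
    # constant-amount internal standard channel; injection variability is
    # a fraction of the biological replicate CV so degenerate limits hold
    is_noise = np.exp(rng.normal(0.0, 0.1 * config.replicate_cv,
                                 size=len(samples)))
    values[INTERNAL_STANDARD_ID] = config.is_area * is_noise
    values.index.name = "sample_id"

    table = AbundanceTable(values=values, unit_tag=UnitTag.raw_area,
                           internal_standard_id=INTERNAL_STANDARD_ID)
    truth = GroundTruth(planted_ids=planted_ids,
                        stage_multipliers=truth_mult, seed=config.seed)
    return table, compounds, samples, truth


def _make_compounds(config: SimulationConfig,
                    rng: np.random.Generator) -> list[CompoundInfo]:
    lo, hi = config.threshold_log_range
    wheel = AromaCategory.wheel_order()
    out: list[CompoundInfo] = []
    k = 0
    for cls in ChemicalClass:
        n = config.class_counts.get(cls, 0)
        for i in range(n):
            k += 1
            cid = f"voc{k:03d}"
            cat = wheel[int(rng.integers(len(wheel)))]
            desc = _DESCRIPTOR_LEXICON[cat]
            n_desc = int(rng.integers(1, len(desc) + 1))
            threshold = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            out.append(CompoundInfo(
                compound_id=cid,
                name=f"{cls.value}-{i + 1}",
                chemical_class=cls,
                aroma_descriptors=tuple(desc[:n_desc]),
                aroma_category=cat,
                odor_threshold=threshold,
                threshold_source="synthetic log-uniform draw",
            ))
    out.append(CompoundInfo(
        compound_id=INTERNAL_STANDARD_ID,
        name="3-hexanone-2,2,4,4-d4 (internal standard)",
        chemical_class=ChemicalClass.other,
        aroma_descriptors=(),
        aroma_category=AromaCategory.none,
        odor_threshold=None,
        threshold_source="",
    ))
    return out


def _make_samples(config: SimulationConfig) -> list[SampleMeta]:
    out = []
    for b in range(1, config.n_batches + 1):
        for stage in config.stages:
            for r in range(1, config.n_replicates + 1):
                out.append(SampleMeta(
                    sample_id=f"{stage.value}{b}_r{r}",
                    batch=f"F{b}",
                    stage=stage,
                    replicate=r,
                ))
    return out


def export_ground_truth(gt: GroundTruth, path: Union[str, Path]) -> None:
    """Write planted compounds and their stage multipliers as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "seed": gt.seed,
        "planted_ids": sorted(gt.planted_ids),
        "stage_multipliers": {
            cid: gt.stage_multipliers[cid] for cid in sorted(gt.stage_multipliers)
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_ground_truth(path: Union[str, Path]) -> GroundTruth:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return GroundTruth(
        planted_ids=set(payload["planted_ids"]),
        stage_multipliers=payload["stage_multipliers"],
        seed=payload["seed"],
    )
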