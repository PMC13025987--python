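"""End-to-end orchestration: normalize → screen → rOAV → flavor wheel.

One :class:`PipelineConfig` drives the whole analysis; every constant
that affects a result (thresholds, fold counts, permutation count,
seed) is echoed into a JSON manifest next to the outputs so any run
can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .datamodel import (
    AbundanceTable,
    Contrast,
    SampleMeta,
    Stage,
    UnitTag,
    ValidationError,
)
from .io import read_dataset, write_results
from .quant import normalize_to_internal_standard, relative_content
from .roav import compute_roav, key_compound_report
from .screening import run_contrast, venn_partition
from .wheel import (
    build_wheel,
    compare_category,
    cumulative_roav,
    map_categories,
    replicate_category_totals,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineResult"]

DEFAULT_CONTRASTS = ("IF1:RM1", "IF2:RM2", "FF1:RM1", "FF2:RM2")


@dataclass
class PipelineConfig:
    abundance_path: str = "abundance.tsv"
    compounds_path: str = "compounds.tsv"
    samples_path: str = "samples.tsv"
    out_dir: str = "results"
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS
    vip_threshold: float = 1.0
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    roav_scope: str = "global"
    n_ortho: int = 1
    n_folds: int = 7
    n_perm: int = 200
    is_amount: float = 0.5      # µg spiked internal standard
    sample_mass: float = 0.5    # g tea per vial
    seed: int = 0

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        if "contrasts" in payload:
            payload["contrasts"] = tuple(payload["contrasts"])
        return cls(**payload)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    manifest: dict
    contrast_results: dict
    venn: object
    roav_table: object
    wheel: object
    artifacts: dict[str, Path]


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> PipelineResult:
    """Run the full stage-resolved aroma analysis.

    Stages: input validation → internal-standard normalization →
    relative content → per-contrast OPLS-DA/VIP + univariate screen →
    Venn partition → rOAV table → key-compound report → flavor wheel.
    Deterministic given (inputs, config, seed). Any stage failure
    aborts with the stage name in the exception message.
    """
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    out_dir = Path(config.out_dir)
    artifacts: dict[str, Path] = {}

    def _stage(name):
        def wrap(fn, *args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3)}
            return result
        return wrap

    table, compounds, samples = _stage("read_dataset")(
        read_dataset, config.abundance_path, config.compounds_path,
        config.samples_path)
    manifest["stages"]["read_dataset"].update(
        n_samples=table.n_samples, n_compounds=table.n_compounds)
    if dry_run:
        logger.info("dry run: inputs validated, stopping")
        return PipelineResult(manifest, {}, None, None, None, {})

    out_dir.mkdir(parents=True, exist_ok=True)

    if table.unit_tag is UnitTag.raw_area and table.internal_standard_id:
        table = _stage("is_normalization")(
            normalize_to_internal_standard, table,
            config.is_amount, config.sample_mass)
    contents = _stage("relative_content")(relative_content, table)

    contrast_objs = [Contrast.parse(c) for c in config.contrasts]
    known_groups = {(s.batch, s.stage) for s in samples}
    for c in contrast_objs:
        for g in (c.group_a, c.group_b):
            if g not in known_groups:
                raise ValidationError(
                    f"contrast {c.name!r}: unknown group ({g[0]}, {g[1].value})")

    contrast_results = {}
    for c in contrast_objs:
        res = _stage(f"screen:{c.name}")(
            run_contrast, contents, samples, c,
            vip_threshold=config.vip_threshold,
            p_threshold=config.p_threshold,
            fc_threshold=config.fc_threshold,
            n_ortho=config.n_ortho, n_folds=config.n_folds,
            n_perm=config.n_perm, seed=config.seed)
        contrast_results[c.name] = res
        manifest["stages"][f"screen:{c.name}"].update(
            n_selected=res.n_selected,
            r2y=round(res.model.r2y, 4),
            q2=round(res.model.q2, 4) if res.model.q2 is not None else None,
            perm_p=(res.model.permutation.p_value_q2
                    if res.model.permutation else None))
        path = out_dir / f"screen_{c.name}.tsv"
        write_results(res.table, path)
        artifacts[f"screen_{c.name}"] = path

    venn = _stage("venn")(venn_partition,
                          {n: r.selected_ids for n, r in contrast_results.items()})
    path = out_dir / "venn.json"
    write_results(venn.to_records(), path, format="json")
    artifacts["venn"] = path
    manifest["stages"]["venn"].update(n_common=len(venn.common))

    thresholds = {c.compound_id: c.odor_threshold for c in compounds
                  if c.odor_threshold is not None}
    roav_table = _stage("roav")(
        compute_roav, contents, thresholds, config.roav_scope, samples)
    path = out_dir / "roav.tsv"
    write_results(roav_table.summary, path)
    artifacts["roav"] = path
    manifest["stages"]["roav"].update(
        reference=roav_table.reference_compound_id)

    key_report = _stage("key_compounds")(
        key_compound_report, roav_table, list(contrast_results.values()))
    path = out_dir / "key_compounds.tsv"
    write_results(key_report, path)
    artifacts["key_compounds"] = path
    manifest["stages"]["key_compounds"].update(
        n_primary=int((key_report["status"] == "primary").sum())
        if len(key_report) else 0)

    wheel = _stage("wheel")(_build_full_wheel, roav_table, compounds, samples)
    path = out_dir / "wheel.json"
    wheel.to_json(path)
    artifacts["wheel"] = path

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["manifest"] = manifest_path

    return PipelineResult(manifest, contrast_results, venn, roav_table,
                          wheel, artifacts)


def _build_full_wheel(roav_table, compounds, samples: Sequence[SampleMeta]):
    membership = map_categories(compounds, roav_table)
    batches = sorted({s.batch for s in samples})
    stages = [s for s in Stage.ordered()
              if any(m.stage == s for m in samples)]
    cumulative = {}
    for b in batches:
        for st in stages:
            cumulative[f"{b}|{st.value}"] = cumulative_roav(
                membership, roav_table, (b, st))
    comparisons = {}
    if len(batches) == 2:
        ids_by_batch = {
            b: [s.sample_id for s in samples if s.batch == b] for b in batches}
        tot1 = replicate_category_totals(membership, roav_table,
                                         ids_by_batch[batches[0]])
        tot2 = replicate_category_totals(membership, roav_table,
                                         ids_by_batch[batches[1]])
        for cat in membership:
            comparisons[cat] = compare_category(tot1[cat], tot2[cat])
    return build_wheel(membership, roav_table, compounds, cumulative,
                       comparisons)
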