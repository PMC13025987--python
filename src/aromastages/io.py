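"""Reading, validating and writing the delimited-text tables.

Input is a trio of delimited files: ``abundance`` (samples × compounds,
first column ``sample_id``), ``compounds`` (annotations incl. odor
thresholds) and ``samples`` (batch/stage/replicate design). Tab is the
default delimiter — chemical names routinely contain commas
("phenol, 2-ethyl-") — with comma auto-detected from the header line.

Output writers are deterministic: fixed column order, rows sorted by
compound_id, floats at 6 significant digits, so re-running a pipeline
produces byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence, Union

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
    "read_dataset",
    "validate_dataset",
    "write_results",
    "write_dataset",
    "ValidationReport",
]

_FLOAT_FMT = "%.6g"


def _sniff_sep(path: Union[str, Path]) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sniff_sep(path), dtype={0: str})


def read_dataset(
    abundance_path: Union[str, Path],
    compounds_path: Union[str, Path],
    samples_path: Union[str, Path],
) -> tuple[AbundanceTable, list[CompoundInfo], list[SampleMeta]]:
    """Read and cross-validate the abundance/annotation/metadata trio.

    Raises :class:`ValidationError` naming the offending identifier or
    cell on any inconsistency.
    """
    ab_df = _read_table(abundance_path)
    if ab_df.columns[0] != "sample_id":
        raise ValidationError(
            f"{abundance_path}: first column must be 'sample_id', "
            f"got {ab_df.columns[0]!r}"
        )
    ab_df = ab_df.set_index("sample_id")
    ab_df = ab_df.astype(float)

    comp_df = _read_table(compounds_path)
    samp_df = _read_table(samples_path)

    compounds = _parse_compounds(comp_df)
    samples = _parse_samples(samp_df)

    unit_raw = None
    # unit tag and IS id travel in the compounds file via reserved rows? No:
    # they are properties of the matrix; default raw_area, IS detected by id.
    is_ids = [c.compound_id for c in compounds
              if c.chemical_class is ChemicalClass.other
              and c.compound_id.startswith("IS_")]
    internal_standard_id = is_ids[0] if len(is_ids) == 1 else None

    table = AbundanceTable(
        values=ab_df,
        unit_tag=UnitTag.raw_area,
        internal_standard_id=(
            internal_standard_id
            if internal_standard_id in ab_df.columns else None
        ),
    )

    report = validate_dataset(table, compounds, samples)
    if report.violations:
        raise ValidationError("; ".join(report.violations))
    return table, compounds, samples


def _parse_compounds(df: pd.DataFrame) -> list[CompoundInfo]:
    required = {"compound_id", "name", "chemical_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"compounds table missing columns: {sorted(missing)}")
    out: list[CompoundInfo] = []
    for _, row in df.iterrows():
        try:
            chem = ChemicalClass(str(row["chemical_class"]))
        except ValueError:
            raise ValidationError(
                f"compound {row['compound_id']!r}: unknown chemical_class "
                f"{row['chemical_class']!r}"
            ) from None
        cat = AromaCategory.none
        if "aroma_category" in df.columns and pd.notna(row.get("aroma_category")):
            try:
                cat = AromaCategory(str(row["aroma_category"]))
            except ValueError:
                raise ValidationError(
                    f"compound {row['compound_id']!r}: unknown aroma_category "
                    f"{row['aroma_category']!r}"
                ) from None
        thr = None
        if "odor_threshold" in df.columns and pd.notna(row.get("odor_threshold")):
            thr = float(row["odor_threshold"])
        desc: tuple[str, ...] = ()
        if "aroma_descriptors" in df.columns and pd.notna(row.get("aroma_descriptors")):
            desc = tuple(
                d.strip() for d in str(row["aroma_descriptors"]).split(";")
                if d.strip()
            )
        out.append(
            CompoundInfo(
                compound_id=str(row["compound_id"]),
                name=str(row["name"]),
                chemical_class=chem,
                aroma_descriptors=desc,
                aroma_category=cat,
                odor_threshold=thr,
                threshold_source=str(row.get("threshold_source", "") or ""),
            )
        )
    return out


def _parse_samples(df: pd.DataFrame) -> list[SampleMeta]:
    required = {"sample_id", "batch", "stage", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"samples table missing columns: {sorted(missing)}")
    out: list[SampleMeta] = []
    for _, row in df.iterrows():
        try:
            stage = Stage(str(row["stage"]))
        except ValueError:
            raise ValidationError(
                f"sample {row['sample_id']!r}: unknown stage {row['stage']!r}"
            ) from None
        out.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                batch=str(row["batch"]),
                stage=stage,
                replicate=int(row["replicate"]),
            )
        )
    return out


@dataclass
class ValidationReport:
    """Accumulated invariant violations; empty list means valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, msg: str) -> None:
        self.violations.append(msg)


def validate_dataset(
    table: AbundanceTable,
    compounds: Sequence[CompoundInfo],
    samples: Sequence[SampleMeta],
) -> ValidationReport:
    """Cross-check the trio; reports every violation, never raises."""
    rep = ValidationReport()

    comp_ids = [c.compound_id for c in compounds]
    if len(set(comp_ids)) != len(comp_ids):
        seen: set[str] = set()
        for cid in comp_ids:
            if cid in seen:
                rep.add(f"duplicated compound_id {cid!r} in compounds table")
            seen.add(cid)
    samp_ids = [s.sample_id for s in samples]
    if len(set(samp_ids)) != len(samp_ids):
        seen = set()
        for sid in samp_ids:
            if sid in seen:
                rep.add(f"duplicated sample_id {sid!r} in samples table")
            seen.add(sid)

    design = [(s.batch, s.stage, s.replicate) for s in samples]
    if len(set(design)) != len(design):
        seen_d: set[tuple] = set()
        for d in design:
            if d in seen_d:
                rep.add(f"duplicated (batch, stage, replicate) {d}")
            seen_d.add(d)

    known_comp = set(comp_ids)
    for cid in table.compound_ids:
        if cid not in known_comp:
            rep.add(f"abundance column {cid!r} has no compounds-table entry")
    matrix_comp = set(table.compound_ids)
    for cid in comp_ids:
        if cid not in matrix_comp:
            rep.add(f"compound {cid!r} annotated but absent from abundance matrix")

    known_samp = set(samp_ids)
    for sid in table.sample_ids:
        if sid not in known_samp:
            rep.add(f"abundance row {sid!r} has no samples-table entry")
    matrix_samp = set(table.sample_ids)
    for sid in samp_ids:
        if sid not in matrix_samp:
            rep.add(f"sample {sid!r} in metadata but absent from abundance matrix")

    for c in compounds:
        if c.odor_threshold is not None and not c.odor_threshold > 0:
            rep.add(
                f"compound {c.compound_id!r}: odor_threshold must be > 0, "
                f"got {c.odor_threshold}"
            )

    arr = table.values.to_numpy(dtype=float)
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        rep.add(
            f"negative abundance at sample {table.sample_ids[r]!r}, "
            f"compound {table.compound_ids[c]!r}"
        )
    return rep


def write_dataset(
    table: AbundanceTable,
    compounds: Sequence[CompoundInfo],
    samples: Sequence[SampleMeta],
    out_dir: Union[str, Path],
) -> dict[str, Path]:
    """Write the trio as abundance.tsv / compounds.tsv / samples.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": out_dir / "abundance.tsv",
        "compounds": out_dir / "compounds.tsv",
        "samples": out_dir / "samples.tsv",
    }
    ab = table.values.copy()
    ab.insert(0, "sample_id", ab.index)
    ab.to_csv(paths["abundance"], sep="\t", index=False,
              float_format=_FLOAT_FMT)

    comp_df = pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in compounds],
            "name": [c.name for c in compounds],
            "chemical_class": [c.chemical_class.value for c in compounds],
            "aroma_descriptors": [";".join(c.aroma_descriptors) for c in compounds],
            "aroma_category": [
                "" if c.aroma_category is AromaCategory.none
                else c.aroma_category.value
                for c in compounds
            ],
            "odor_threshold": [
                "" if c.odor_threshold is None else _FLOAT_FMT % c.odor_threshold
                for c in compounds
            ],
            "threshold_source": [c.threshold_source for c in compounds],
        }
    )
    comp_df.to_csv(paths["compounds"], sep="\t", index=False)

    samp_df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "batch": [s.batch for s in samples],
            "stage": [s.stage.value for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )
    samp_df.to_csv(paths["samples"], sep="\t", index=False)
    return paths


def write_results(
    result: Any,
    path: Union[str, Path],
    format: str = "tsv",
) -> None:
    """Write any result table deterministically.

    DataFrames are sorted by their first column (compound_id where
    applicable) and serialized at 6 significant digits; objects with a
    ``to_records()`` method are converted first; dict-like results are
    written as JSON with sorted keys.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if hasattr(result, "to_records") and not isinstance(result, pd.DataFrame):
        result = result.to_records()

    if format == "json" or (not isinstance(result, pd.DataFrame)
                            and isinstance(result, (dict, list))):
        payload = result
        if isinstance(result, pd.DataFrame):
            payload = json.loads(
                result.to_json(orient="records", double_precision=6)
            )
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        return

    if not isinstance(result, pd.DataFrame):
        raise TypeError(f"cannot write result of type {type(result).__name__}")
    df = result.copy()
    sort_cols = [c for c in df.columns[: 2] if df[c].dtype == object]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "value"):  # Enum
        return obj.value
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")
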