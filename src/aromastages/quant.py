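"""Semi-quantification and univariate statistics.

Covers the steps between raw peak areas and the differential screen:
internal-standard normalization to µg/g, per-sample relative content
(percent of total), chemical-class composition summaries, one-way
ANOVA with Duncan's multiple range test, log2 fold changes, and the
volcano increased/decreased partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    AbundanceTable,
    ChemicalClass,
    CompoundInfo,
    UnitTag,
    ValidationError,
)

__all__ = [
    "ClassComposition",
    "normalize_to_internal_standard",
    "relative_content",
    "class_composition",
    "one_way_anova",
    "duncan_mrt",
    "log2_fold_change",
    "volcano_classify",
    "univariate_table",
]

Regulation = Literal["increased", "decreased", "unchanged"]


def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits,
                                           rounding=ROUND_HALF_UP))


def normalize_to_internal_standard(
    table: AbundanceTable,
    is_amount: float = 0.5,
    sample_mass: float = 0.5,
) -> AbundanceTable:
    """Convert raw peak areas to µg/g via the spiked internal standard.

    value'(s, c) = value(s, c) / IS_area(s) × is_amount / sample_mass.

    Defaults reflect a 10 µL spike of a 50 µg/mL deuterated-hexanone
    solution (0.5 µg) into a 0.5 g tea aliquot. The IS column is
    consumed and removed; the result is tagged ``is_normalized``.
    """
    if table.unit_tag is not UnitTag.raw_area:
        raise ValidationError(
            f"expected raw_area table, got {table.unit_tag.value}")
    if table.internal_standard_id is None:
        raise ValidationError("table has no internal_standard_id set")
    if is_amount <= 0 or sample_mass <= 0:
        raise ValidationError("is_amount and sample_mass must be > 0")
    is_col = table.values[table.internal_standard_id]
    bad = is_col[is_col <= 0]
    if len(bad):
        raise ValidationError(
            f"internal-standard area <= 0 in sample {bad.index[0]!r}")
    analytes = table.values.drop(columns=[table.internal_standard_id])
    scaled = analytes.div(is_col, axis=0) * (is_amount / sample_mass)
    return AbundanceTable(values=scaled, unit_tag=UnitTag.is_normalized,
                          internal_standard_id=None)


def relative_content(table: AbundanceTable) -> AbundanceTable:
    """Per-sample percent-of-total content (rows sum to 100)."""
    totals = table.values.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(
            f"sample {zero.index[0]!r} has zero total abundance")
    pct = table.values.div(totals, axis=0) * 100.0
    return AbundanceTable(values=pct, unit_tag=UnitTag.percent,
                          internal_standard_id=None)


@dataclass(frozen=True)
class ClassComposition:
    """Per-class compound counts and percentage composition."""

    counts: dict[ChemicalClass, int]
    percentages: dict[ChemicalClass, float]
    total_count: int

    def to_records(self) -> list[dict]:
        return [
            {"chemical_class": cls.value, "count": self.counts[cls],
             "percentage": self.percentages[cls]}
            for cls in ChemicalClass if cls in self.counts
        ]


def class_composition(compounds: Sequence[CompoundInfo]) -> ClassComposition:
    """Count compounds per chemical class; percentages rounded half-up
    to two decimals (presentation convention of composition tables)."""
    if not compounds:
        raise ValidationError("empty compound list")
    counts: dict[ChemicalClass, int] = {}
    for c in compounds:
        counts[c.chemical_class] = counts.get(c.chemical_class, 0) + 1
    total = len(compounds)
    percentages = {
        cls: _round_half_up(100.0 * n / total) for cls, n in counts.items()
    }
    return ClassComposition(counts=counts, percentages=percentages,
                            total_count=total)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p).

    Degenerate all-constant input (zero between- and within-group
    variance) is defined as F = 0, p = 1 rather than NaN.
    """
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrs):
        if a.size < 2:
            raise ValidationError(f"group {i} has fewer than 2 observations")
        if not np.isfinite(a).all():
            raise ValidationError(f"group {i} contains non-finite values")
    n_total = sum(a.size for a in arrs)
    k = len(arrs)
    grand = sum(a.sum() for a in arrs) / n_total
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def duncan_mrt(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Optional[Sequence[str]] = None,
) -> dict[str, str]:
    """Duncan's multiple range test; returns letter codes per group.

    Means are ranked descending. For a stretch of p consecutive ranked
    means the critical range is

        R_p = q(1 - alpha_p, p, df_err) * sqrt(MSE / n_h)

    where alpha_p = 1 - (1 - alpha)^(p - 1) is Duncan's protection
    level, q the studentized-range quantile, MSE the ANOVA within-group
    mean square and n_h the harmonic mean group size. Ranges nested in
    a non-significant wider range are declared non-significant (the
    standard step-down rule). Groups sharing no letter differ at alpha.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValidationError("Duncan test needs at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValidationError("every group needs at least 2 observations")
    k = len(arrs)
    if labels is None:
        labels = [f"g{i + 1}" for i in range(k)]
    n_total = sum(a.size for a in arrs)
    df_err = n_total - k
    if df_err < 1:
        raise ValidationError("error degrees of freedom < 1")
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrs) / df_err
    n_h = k / sum(1.0 / a.size for a in arrs)

    means = np.array([a.mean() for a in arrs])
    order = np.argsort(-means, kind="mergesort")  # descending, stable
    sorted_means = means[order]

    # critical range per span
    crit = {}
    for p in range(2, k + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        q = stats.studentized_range.ppf(1.0 - alpha_p, p, df_err)
        crit[p] = q * math.sqrt(mse / n_h)

    # significance matrix over ranked positions, with step-down shielding
    nonsig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        nonsig[i, i] = True
    if mse == 0.0:
        # zero within-group variance: any mean difference separates
        for i in range(k):
            for j in range(i + 1, k):
                nonsig[i, j] = nonsig[j, i] = sorted_means[i] == sorted_means[j]
    else:
        for span in range(k, 1, -1):
            for i in range(0, k - span + 1):
                j = i + span - 1
                diff = sorted_means[i] - sorted_means[j]
                if diff <= crit[span] or nonsig[i, j]:
                    nonsig[i:j + 1, i:j + 1] = True

    letters = _assign_letters(nonsig)
    out = {}
    for rank, gi in enumerate(order):
        out[labels[gi]] = letters[rank]
    return out


def _assign_letters(nonsig: np.ndarray) -> list[str]:
    """Letter sweep over ranked means: one letter per maximal stretch of
    mutually non-separated groups (contiguous in rank order because the
    range-test non-significance pattern is interval-shaped)."""
    k = nonsig.shape[0]
    segments: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        segments.append((i, j))
    # drop segments contained in an earlier one
    maximal: list[tuple[int, int]] = []
    for seg in segments:
        if not any(o[0] <= seg[0] and seg[1] <= o[1] for o in maximal):
            maximal.append(seg)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for idx, (a, b) in enumerate(maximal):
        ch = alphabet[idx % len(alphabet)]
        for pos in range(a, b + 1):
            letters[pos] += ch
    return letters


def log2_fold_change(mean_a: float, mean_b: float, pseudo: float = 0.0) -> float:
    """log2((mean_b + pseudo) / (mean_a + pseudo)); b is the later stage."""
    if mean_a < 0 or mean_b < 0:
        raise ValidationError("means must be >= 0")
    if pseudo < 0:
        raise ValidationError("pseudo-count must be >= 0")
    num, den = mean_b + pseudo, mean_a + pseudo
    if num == 0.0 and den == 0.0:
        raise ValidationError(
            "log2 fold change undefined: both means zero with zero pseudo-count")
    if den == 0.0:
        return float("inf")
    if num == 0.0:
        return float("-inf")
    return float(np.log2(num / den))


def volcano_classify(
    log2fc: float,
    p: float,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> Regulation:
    """Volcano partition: increased / decreased / unchanged.

    Increased iff log2FC >= log2(fc_threshold) and p < p_threshold;
    decreased symmetric; everything else unchanged.
    """
    if not 0 <= p <= 1:
        raise ValidationError(f"p must be in [0, 1], got {p}")
    if fc_threshold < 1:
        raise ValidationError("fc_threshold must be >= 1")
    cut = math.log2(fc_threshold)
    if p < p_threshold and log2fc >= cut:
        return "increased"
    if p < p_threshold and log2fc <= -cut:
        return "decreased"
    return "unchanged"


def default_pseudocount(table: AbundanceTable) -> float:
    """Half the smallest positive value — the zero-handling offset."""
    arr = table.values.to_numpy(dtype=float)
    pos = arr[arr > 0]
    return float(pos.min() / 2.0) if pos.size else 0.0


def univariate_table(
    table: AbundanceTable,
    sample_ids_a: Sequence[str],
    sample_ids_b: Sequence[str],
    pseudo: Optional[float] = None,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Per-compound two-group ANOVA (= pooled t) + fold change + volcano.

    Returns a DataFrame with columns compound_id, mean_a, mean_b, F, p,
    log2fc, regulation. p-values are raw by default; ``bh_adjust``
    replaces them with Benjamini–Hochberg adjusted values.
    """
    if pseudo is None:
        pseudo = default_pseudocount(table)
    a = table.values.loc[list(sample_ids_a)].to_numpy(dtype=float)
    b = table.values.loc[list(sample_ids_b)].to_numpy(dtype=float)
    rows = []
    for j, cid in enumerate(table.compound_ids):
        f, p = one_way_anova([a[:, j], b[:, j]])
        l2fc = log2_fold_change(float(a[:, j].mean()),
                                float(b[:, j].mean()), pseudo)
        rows.append((cid, float(a[:, j].mean()), float(b[:, j].mean()),
                     f, p, l2fc))
    df = pd.DataFrame(rows, columns=["compound_id", "mean_a", "mean_b",
                                     "F", "p", "log2fc"])
    if bh_adjust:
        df["p"] = _benjamini_hochberg(df["p"].to_numpy())
    df["regulation"] = [
        volcano_classify(l, p, fc_threshold, p_threshold)
        for l, p in zip(df["log2fc"], df["p"])
    ]
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
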