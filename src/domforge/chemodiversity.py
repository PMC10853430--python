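"""Chemodiversity accounting: composition, set comparison, Venn partitions.

All accounting is over *unique* molecular formulas (set semantics): a
formula observed at several peaks within a sample counts once, matching
how ultrahigh-resolution MS inventories are summarized.  Percentages are
reported with half-away-from-zero rounding — 2 decimals for
compositions, 1 decimal for the degraded/remaining/produced split of a
two-condition comparison; full precision is retained internally and
rounded only at reporting time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .formulas import ElementGroup
from .vankrevelen import SEVEN_CLASSES, CompoundClass

logger = logging.getLogger(__name__)

#: Reporting order for class percentages (7 classes + unclassified).
CLASS_ORDER: tuple[str, ...] = tuple(c.value for c in SEVEN_CLASSES) + (
    CompoundClass.UNCLASSIFIED.value,
)
GROUP_ORDER: tuple[str, ...] = tuple(g.value for g in ElementGroup)

FormulaKey = tuple[int, int, int, int, int]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (so 0.125 -> 0.13)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _unique_formula_frame(annotated: pd.DataFrame) -> pd.DataFrame:
    """Deduplicate an annotated table to one row per assigned formula."""
    present = annotated[annotated["C"].notna()]
    return present.drop_duplicates(subset=["C", "H", "O", "N", "S"])


@dataclass(frozen=True)
class SampleComposition:
    """Per-sample chemodiversity summary over unique assigned formulas."""

    sample_id: str
    n_formulas: int
    class_counts: dict[str, int]
    class_pct: dict[str, float]
    group_counts: dict[str, int]
    group_pct: dict[str, float]


def composition(annotated: pd.DataFrame, sample_id: str = "sample") -> SampleComposition:
    """Count and percent unique formulas by compound class and element group.

    Rows without an assigned formula are excluded from the accounting; an
    empty sample logs a warning and returns all-zero counts.
    """
    uniq = _unique_formula_frame(annotated)
    n = len(uniq)
    if n == 0:
        logger.warning("sample %s has no assigned formulas", sample_id)
        return SampleComposition(
            sample_id,
            0,
            {c: 0 for c in CLASS_ORDER},
            {c: 0.0 for c in CLASS_ORDER},
            {g: 0 for g in GROUP_ORDER},
            {g: 0.0 for g in GROUP_ORDER},
        )
    ccounts = uniq["compound_class"].value_counts()
    gcounts = uniq["element_group"].value_counts()
    class_counts = {c: int(ccounts.get(c, 0)) for c in CLASS_ORDER}
    group_counts = {g: int(gcounts.get(g, 0)) for g in GROUP_ORDER}
    class_pct = {c: round_half_up(100.0 * v / n, 2) for c, v in class_counts.items()}
    n_grouped = sum(group_counts.values())
    group_pct = {
        g: round_half_up(100.0 * v / n_grouped, 2) if n_grouped else 0.0
        for g, v in group_counts.items()
    }
    return SampleComposition(sample_id, n, class_counts, class_pct, group_counts, group_pct)


def composition_frame(comps: list[SampleComposition]) -> pd.DataFrame:
    """Tidy long-format table of several compositions."""
    rows = []
    for comp in comps:
        for name in CLASS_ORDER:
            rows.append(
                {
                    "sample_id": comp.sample_id,
                    "kind": "compound_class",
                    "name": name,
                    "count": comp.class_counts[name],
                    "pct": comp.class_pct[name],
                }
            )
        for name in GROUP_ORDER:
            rows.append(
                {
                    "sample_id": comp.sample_id,
                    "kind": "element_group",
                    "name": name,
                    "count": comp.group_counts[name],
                    "pct": comp.group_pct[name],
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonResult:
    """Degraded / remaining / produced partition of two formula inventories.

    ``degraded`` are formulas present only in the earlier condition A,
    ``remaining`` in both, ``produced`` only in the later condition B.
    ``overall_pct`` expresses the three blocks as percentages of the
    union; ``per_class`` and ``per_group`` give, within each compound
    class / element group of the pooled union, the same three-way split.
    """

    degraded: frozenset[FormulaKey]
    remaining: frozenset[FormulaKey]
    produced: frozenset[FormulaKey]
    overall_pct: dict[str, float]
    per_class: pd.DataFrame
    per_group: pd.DataFrame


def _formula_keys(annotated: pd.DataFrame) -> dict[FormulaKey, tuple[str, str]]:
    """Map each unique formula to its (class, group) annotation."""
    uniq = _unique_formula_frame(annotated)
    out: dict[FormulaKey, tuple[str, str]] = {}
    for row in uniq.itertuples(index=False):
        key = (int(row.C), int(row.H), int(row.O), int(row.N), int(row.S))
        out[key] = (row.compound_class, row.element_group)
    return out


def _drp_table(
    members: dict[FormulaKey, tuple[str, str]],
    degraded: frozenset[FormulaKey],
    remaining: frozenset[FormulaKey],
    which: int,
    order: tuple[str, ...],
) -> pd.DataFrame:
    rows = []
    for name in order:
        keys = [k for k, ann in members.items() if ann[which] == name]
        total = len(keys)
        d = sum(1 for k in keys if k in degraded)
        r = sum(1 for k in keys if k in remaining)
        p = total - d - r
        rows.append(
            {
                "name": name,
                "total": total,
                "degraded": d,
                "remaining": r,
                "produced": p,
                "degraded_pct": round_half_up(100.0 * d / total, 2) if total else 0.0,
                "remaining_pct": round_half_up(100.0 * r / total, 2) if total else 0.0,
                "produced_pct": round_half_up(100.0 * p / total, 2) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def compare_two(
    annotated_a: pd.DataFrame, annotated_b: pd.DataFrame
) -> ComparisonResult:
    """Exact set algebra between two annotated formula tables.

    Identity is the (C, H, O, N, S) tuple — the finest identity exact
    mass can resolve.  Raises if both inventories are empty.
    """
    mem_a = _formula_keys(annotated_a)
    mem_b = _formula_keys(annotated_b)
    if not mem_a and not mem_b:
        raise ValueError("cannot compare two empty formula inventories")
    set_a, set_b = set(mem_a), set(mem_b)
    degraded = frozenset(set_a - set_b)
    remaining = frozenset(set_a & set_b)
    produced = frozenset(set_b - set_a)
    union = len(degraded) + len(remaining) + len(produced)
    # full precision here; reports round to 1 d.p. at write time
    overall_pct = {
        "degraded": 100.0 * len(degraded) / union,
        "remaining": 100.0 * len(remaining) / union,
        "produced": 100.0 * len(produced) / union,
    }
    members = dict(mem_b)
    members.update(mem_a)  # annotation is a function of the formula anyway
    per_class = _drp_table(members, degraded, remaining, 0, CLASS_ORDER)
    per_group = _drp_table(members, degraded, remaining, 1, GROUP_ORDER)
    return ComparisonResult(degraded, remaining, produced, overall_pct, per_class, per_group)


@dataclass(frozen=True, slots=True)
class VennPartition:
    """Counts of items found only in A, in both, and only in B."""

    only_a: int
    shared: int
    only_b: int

    def __post_init__(self) -> None:
        if min(self.only_a, self.shared, self.only_b) < 0:
            raise ValueError("Venn counts must be >= 0")

    @property
    def total(self) -> int:
        return self.only_a + self.shared + self.only_b


def venn_percentages(v: VennPartition) -> tuple[float, float, float]:
    """Percentages (only_a, shared, only_b) of the union, to 2 decimals."""
    if v.total == 0:
        raise ValueError("empty Venn partition has no percentages")
    return (
        round_half_up(100.0 * v.only_a / v.total, 2),
        round_half_up(100.0 * v.shared / v.total, 2),
        round_half_up(100.0 * v.only_b / v.total, 2),
    )


def build_venn_from_tables(
    abundance_a: pd.Series,
    abundance_b: pd.Series,
    presence_threshold: float = 0.0,
) -> VennPartition:
    """Two-condition presence/absence Venn from taxon abundance vectors.

    A taxon is *present* in a condition iff its abundance is strictly
    above ``presence_threshold`` there.  Taxon identifiers are the Series
    indexes; duplicates are rejected.
    """
    for name, series in (("A", abundance_a), ("B", abundance_b)):
        if series.index.has_duplicates:
            dups = series.index[series.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated taxon identifiers in table {name}: {dups}")
    present_a = set(abundance_a.index[abundance_a > presence_threshold])
    present_b = set(abundance_b.index[abundance_b > presence_threshold])
    return VennPartition(
        only_a=len(present_a - present_b),
        shared=len(present_a & present_b),
        only_b=len(present_b - present_a),
    )
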