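"""Van Krevelen classification of DOM formulas.

Each formula maps to one of seven biochemical compound classes by where
its (O/C, H/C) point falls in the van Krevelen plane.  The default
boundary boxes are the ones conventionally used for soil and aquatic DOM:

=======================  ===========  ===========
class                    O/C          H/C
=======================  ===========  ===========
lipids                   0 - 0.3      1.5 - 2.0
aliphatic/proteins       0.3 - 0.67   1.5 - 2.2
lignin/CRAM-like         0.1 - 0.67   0.7 - 1.5
carbohydrates            0.67 - 1.2   1.5 - 2.3
unsaturated hydrocarbons 0 - 0.1      0.5 - 1.5
condensed aromatics      0 - 0.67     0.1 - 0.7
tannins                  0.67 - 1.2   0.5 - 1.5
=======================  ===========  ===========

The printed boxes overlap (e.g. condensed aromatics vs. unsaturated
hydrocarbons for O/C < 0.1, H/C 0.5-0.7), so classification is
first-match-wins in the table order above; intervals are half-open
[low, high) so shared edges belong to the higher box.  Both the boxes and
their precedence are configurable (YAML), letting users replicate other
conventions.  Formulas falling in no box are ``unclassified``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .formulas import ElementGroup, MolecularFormula, elemental_ratios


class CompoundClass(enum.Enum):
    LIPIDS = "lipids"
    ALIPHATIC_PROTEINS = "aliphatic_proteins"
    LIGNIN_CRAM = "lignin_cram"
    CARBOHYDRATES = "carbohydrates"
    UNSATURATED_HC = "unsaturated_hc"
    CONDENSED_AROMATICS = "condensed_aromatics"
    TANNINS = "tannins"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The seven real classes, in default precedence order.
SEVEN_CLASSES: tuple[CompoundClass, ...] = (
    CompoundClass.LIPIDS,
    CompoundClass.ALIPHATIC_PROTEINS,
    CompoundClass.LIGNIN_CRAM,
    CompoundClass.CARBOHYDRATES,
    CompoundClass.UNSATURATED_HC,
    CompoundClass.CONDENSED_AROMATICS,
    CompoundClass.TANNINS,
)


@dataclass(frozen=True, slots=True)
class ClassBox:
    """One van Krevelen box: half-open in both O/C and H/C."""

    compound_class: CompoundClass
    oc_low: float
    oc_high: float
    hc_low: float
    hc_high: float

    def __post_init__(self) -> None:
        if not (self.oc_low < self.oc_high and self.hc_low < self.hc_high):
            raise ValueError(f"degenerate box for {self.compound_class}")

    def contains(self, o_c: float, h_c: float) -> bool:
        return (
            self.oc_low <= o_c < self.oc_high
            and self.hc_low <= h_c < self.hc_high
        )


DEFAULT_BOUNDARIES: tuple[ClassBox, ...] = (
    ClassBox(CompoundClass.LIPIDS, 0.0, 0.3, 1.5, 2.0),
    ClassBox(CompoundClass.ALIPHATIC_PROTEINS, 0.3, 0.67, 1.5, 2.2),
    ClassBox(CompoundClass.LIGNIN_CRAM, 0.1, 0.67, 0.7, 1.5),
    ClassBox(CompoundClass.CARBOHYDRATES, 0.67, 1.2, 1.5, 2.3),
    ClassBox(CompoundClass.UNSATURATED_HC, 0.0, 0.1, 0.5, 1.5),
    ClassBox(CompoundClass.CONDENSED_AROMATICS, 0.0, 0.67, 0.1, 0.7),
    ClassBox(CompoundClass.TANNINS, 0.67, 1.2, 0.5, 1.5),
)


def classify_ratios(
    o_c: float, h_c: float, table: tuple[ClassBox, ...] = DEFAULT_BOUNDARIES
) -> CompoundClass:
    """First box (in table order) containing the (O/C, H/C) point."""
    for box in table:
        if box.contains(o_c, h_c):
            return box.compound_class
    return CompoundClass.UNCLASSIFIED


def classify_formula(
    f: MolecularFormula, table: tuple[ClassBox, ...] = DEFAULT_BOUNDARIES
) -> CompoundClass:
    """Van Krevelen class of a formula; depends only on its element counts."""
    h_c, o_c = elemental_ratios(f)
    return classify_ratios(o_c, h_c, table)


def classify_arrays(
    o_c: np.ndarray, h_c: np.ndarray, table: tuple[ClassBox, ...] = DEFAULT_BOUNDARIES
) -> np.ndarray:
    """Vectorized :func:`classify_ratios`; returns an array of class names."""
    o_c = np.asarray(o_c, dtype=float)
    h_c = np.asarray(h_c, dtype=float)
    out = np.full(o_c.shape, CompoundClass.UNCLASSIFIED.value, dtype=object)
    unset = np.ones(o_c.shape, dtype=bool)
    for box in table:
        hit = (
            unset
            & (box.oc_low <= o_c)
            & (o_c < box.oc_high)
            & (box.hc_low <= h_c)
            & (h_c < box.hc_high)
        )
        out[hit] = box.compound_class.value
        unset &= ~hit
    return out


def classify_table(
    assigned: pd.DataFrame, table: tuple[ClassBox, ...] = DEFAULT_BOUNDARIES
) -> pd.DataFrame:
    """Append ``compound_class`` and ``element_group`` columns.

    ``assigned`` must carry nullable element-count columns C, H, O, N, S
    (as produced by :func:`domforge.assignment.assigned_to_frame`); rows
    without a formula become ``unclassified`` with a missing group.  The
    row count never changes.
    """
    df = assigned.copy()
    n = len(df)
    cls = np.full(n, CompoundClass.UNCLASSIFIED.value, dtype=object)
    grp = np.full(n, pd.NA, dtype=object)
    has = df["C"].notna().to_numpy() if n else np.array([], dtype=bool)
    if has.any():
        c = df.loc[has, "C"].to_numpy(dtype=float)
        h = df.loc[has, "H"].to_numpy(dtype=float)
        o = df.loc[has, "O"].to_numpy(dtype=float)
        nn = df.loc[has, "N"].to_numpy(dtype=float)
        s = df.loc[has, "S"].to_numpy(dtype=float)
        cls[has] = classify_arrays(o / c, h / c, table)
        g = np.where(
            (nn > 0) & (s > 0),
            ElementGroup.CHONS.value,
            np.where(nn > 0, ElementGroup.CHON.value, np.where(s > 0, ElementGroup.CHOS.value, ElementGroup.CHO.value)),
        )
        grp[has] = g
    df["compound_class"] = cls
    df["element_group"] = grp
    return df


def load_boundary_table(path: str | Path) -> tuple[ClassBox, ...]:
    """Read a boundary table override from YAML.

    Expected format: a list of mappings with keys ``class``, ``oc_low``,
    ``oc_high``, ``hc_low``, ``hc_high``, in precedence order.
    """
    raw = yaml.safe_load(Path(path).read_text())
    boxes = []
    for row in raw:
        boxes.append(
            ClassBox(
                CompoundClass(row["class"]),
                float(row["oc_low"]),
                float(row["oc_high"]),
                float(row["hc_low"]),
                float(row["hc_high"]),
            )
        )
    return tuple(boxes)


def dump_boundary_table(table: tuple[ClassBox, ...], path: str | Path) -> None:
    rows = [
        {
            "class": b.compound_class.value,
            "oc_low": b.oc_low,
            "oc_high": b.oc_high,
            "hc_low": b.hc_low,
            "hc_high": b.hc_high,
        }
        for b in table
    ]
    Path(path).write_text(yaml.safe_dump(rows, sort_keys=False))
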