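"""CHNOS molecular formula assignment for FT-ICR-MS peak lists.

A peak list (m/z, intensity, S/N) measured in negative ESI mode is
filtered on signal-to-noise and on the instrument m/z window, each
surviving m/z is converted to a neutral mass ([M-H]-), and every
elemental composition C_c H_h O_o N_(0-3) S_(0-1) whose exact mass falls
within a ppm tolerance is enumerated.  Candidates must pass the standard
DOM plausibility screen:

* H/C < 2.4 and O/C < 1.2,
* integer, non-negative double bond equivalents (even-electron neutral),
* valence feasibility H <= 2C + N + 2,
* configurable element caps (defaults cover m/z <= 1000 with margin).

The unique best candidate (smallest |mass error|, deterministic
tie-breaking) is reported per peak; peaks with no surviving candidate are
retained unassigned so assignment rates stay reportable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .formulas import (
    MASS_C,
    MASS_H,
    MASS_N,
    MASS_O,
    MASS_S,
    MODE_M_MINUS_H,
    MolecularFormula,
    dbe,
    neutral_mass_from_mz,
)

logger = logging.getLogger(__name__)

#: Columns of the flat assigned-peak table written by the pipeline.
ASSIGNED_COLUMNS = [
    "mz",
    "intensity",
    "snr",
    "C",
    "H",
    "O",
    "N",
    "S",
    "error_ppm",
    "n_candidates",
]


@dataclass(frozen=True, slots=True)
class Peak:
    """One observed mass peak: m/z (Da), intensity (a.u.), S/N ratio."""

    mz: float
    intensity: float
    snr: float


@dataclass(frozen=True)
class AssignmentParams:
    """Tunable constraints of the formula-assignment step.

    ``tol_ppm``
        Mass tolerance in ppm of the neutral mass (default 1.0; a 15 T
        FT-ICR instrument is routinely sub-ppm).
    ``snr_min``
        Minimum signal-to-noise ratio; peaks below are discarded (default 4).
    ``mz_min, mz_max``
        Instrument examination window (default 200-1000 Da).
    ``max_c, max_h, max_o, max_n, max_s``
        Element caps; N <= 3 and S <= 1 follow standard DOM practice, the
        C/H/O caps are sized to cover the window with margin.
    ``hc_max, oc_max``
        Strict elemental-ratio ceilings H/C < 2.4, O/C < 1.2.
    """

    tol_ppm: float = 1.0
    snr_min: float = 4.0
    mz_min: float = 200.0
    mz_max: float = 1000.0
    max_c: int = 60
    max_h: int = 122
    max_o: int = 40
    max_n: int = 3
    max_s: int = 1
    hc_max: float = 2.4
    oc_max: float = 1.2

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be > 0")
        if self.snr_min < 0:
            raise ValueError("snr_min must be >= 0")
        if self.mz_min >= self.mz_max:
            raise ValueError("mz window is empty")
        for name in ("max_c", "max_h", "max_o", "max_n", "max_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AssignedPeak:
    """A peak with its (possibly absent) best formula.

    ``formula`` is None iff no candidate survived all filters
    (``n_candidates == 0``); otherwise ``error_ppm`` is the signed mass
    error of the chosen candidate, (observed - exact)/exact * 1e6.
    """

    peak: Peak
    formula: MolecularFormula | None
    error_ppm: float | None
    n_candidates: int

    def __post_init__(self) -> None:
        if (self.formula is None) != (self.n_candidates == 0):
            raise ValueError("formula must be None exactly when n_candidates == 0")


def filter_peaks(peaks: list[Peak], params: AssignmentParams) -> list[Peak]:
    """Keep peaks with S/N >= ``snr_min`` inside the m/z window, in order."""
    return [
        p
        for p in peaks
        if p.snr >= params.snr_min and params.mz_min <= p.mz <= params.mz_max
    ]


def formula_is_valid(f: MolecularFormula, params: AssignmentParams) -> bool:
    """Apply the DOM plausibility screen to a single formula.

    Note DBE >= 0 and the valence bound H <= 2C + N + 2 are the same
    inequality; DBE integrality additionally demands H and N of equal
    parity.
    """
    if f.c < 1 or f.h < 1:
        return False
    if f.c > params.max_c or f.h > params.max_h or f.o > params.max_o:
        return False
    if f.n > params.max_n or f.s > params.max_s:
        return False
    if not (f.h < params.hc_max * f.c):
        return False
    if not (f.o < params.oc_max * f.c):
        return False
    d = dbe(f)
    if d < 0 or d != int(d):
        return False
    if f.h > 2 * f.c + f.n + 2:
        return False
    return True


@lru_cache(maxsize=8)
def _combo_grid(max_c: int, max_o: int, max_n: int, max_s: int, oc_max: float):
    """Pre-tabulated (C, O, N, S) combinations sorted by their partial mass.

    H is solved per query mass, so the grid stays small (~2e4 rows at the
    defaults) and a binary search restricts each lookup to the ~122 Da
    slice that can complete to the target with 1 <= H <= max_h.
    """
    c, o, n, s = np.meshgrid(
        np.arange(1, max_c + 1, dtype=np.int64),
        np.arange(0, max_o + 1, dtype=np.int64),
        np.arange(0, max_n + 1, dtype=np.int64),
        np.arange(0, max_s + 1, dtype=np.int64),
        indexing="ij",
    )
    c, o, n, s = (a.ravel() for a in (c, o, n, s))
    keep = o < oc_max * c
    c, o, n, s = c[keep], o[keep], n[keep], s[keep]
    base = c * MASS_C + o * MASS_O + n * MASS_N + s * MASS_S
    order = np.argsort(base, kind="stable")
    return SimpleNamespace(
        c=c[order], o=o[order], n=n[order], s=s[order], base=base[order]
    )


def enumerate_candidates(
    neutral_mass: float, params: AssignmentParams
) -> list[tuple[MolecularFormula, float]]:
    """All valid formulas within ±``tol_ppm`` of ``neutral_mass``.

    Returns ``(formula, error_ppm)`` pairs sorted by |error| ascending,
    with deterministic tie-breaking (fewer N+S, lower DBE, element
    counts).  ``error_ppm`` is signed: (observed - exact)/exact * 1e6.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    g = _combo_grid(params.max_c, params.max_o, params.max_n, params.max_s, params.oc_max)
    tol = neutral_mass * params.tol_ppm * 1e-6
    lo = neutral_mass - (params.max_h + 1.5) * MASS_H - tol
    hi = neutral_mass - 0.5 * MASS_H + tol
    i0, i1 = np.searchsorted(g.base, (lo, hi))
    if i0 == i1:
        return []
    c, o, n, s, base = (a[i0:i1] for a in (g.c, g.o, g.n, g.s, g.base))

    out: list[tuple[MolecularFormula, float]] = []
    h0 = np.rint((neutral_mass - base) / MASS_H).astype(np.int64)
    for dh in (-1, 0, 1):
        h = h0 + dh
        mass = base + h * MASS_H
        ok = (
            (np.abs(mass - neutral_mass) <= tol)
            & (h >= 1)
            & (h <= params.max_h)
            & (h < params.hc_max * c)
            & ((h + n) % 2 == 0)  # integer DBE for an even-electron neutral
            & (h <= 2 * c + n + 2)  # valence bound, equivalently DBE >= 0
        )
        for i in np.nonzero(ok)[0]:
            f = MolecularFormula(int(c[i]), int(h[i]), int(o[i]), int(n[i]), int(s[i]))
            err_ppm = (neutral_mass - mass[i]) / mass[i] * 1e6
            out.append((f, float(err_ppm)))
    out.sort(key=lambda t: (abs(t[1]), t[0].n + t[0].s, dbe(t[0]), t[0].as_tuple()))
    return out


def select_formula(
    candidates: list[tuple[MolecularFormula, float]],
) -> tuple[MolecularFormula, float] | None:
    """Pick the unique best candidate from an |error|-sorted list.

    Ties in |error_ppm| (to 1e-9 ppm) break deterministically by fewer
    heteroatoms (N+S), then lower DBE, then element-count order.
    """
    if not candidates:
        return None
    best = abs(candidates[0][1])
    tied = [fc for fc in candidates if abs(fc[1]) <= best + 1e-9]
    return min(tied, key=lambda t: (t[0].n + t[0].s, dbe(t[0]), t[0].as_tuple()))


def assign_peaklist(
    peaks: list[Peak],
    params: AssignmentParams | None = None,
    mode: str = MODE_M_MINUS_H,
) -> list[AssignedPeak]:
    """Filter a peak list and assign each surviving peak its best formula."""
    if params is None:
        params = AssignmentParams()
    kept = filter_peaks(peaks, params)
    out: list[AssignedPeak] = []
    n_assigned = 0
    for p in kept:
        neutral = neutral_mass_from_mz(p.mz, mode)
        cands = enumerate_candidates(neutral, params)
        chosen = select_formula(cands)
        if chosen is None:
            out.append(AssignedPeak(p, None, None, 0))
        else:
            out.append(AssignedPeak(p, chosen[0], chosen[1], len(cands)))
            n_assigned += 1
    logger.info(
        "assigned %d/%d peaks (%d filtered out, %d unassigned)",
        n_assigned,
        len(kept),
        len(peaks) - len(kept),
        len(kept) - n_assigned,
    )
    return out


def assigned_to_frame(
    assigned: list[AssignedPeak], sample_id: str | None = None
) -> pd.DataFrame:
    """Flatten assigned peaks to the tabular interchange format.

    Element counts of unassigned peaks are left missing (nullable Int64).
    """
    rows = []
    for a in assigned:
        f = a.formula
        rows.append(
            {
                "mz": a.peak.mz,
                "intensity": a.peak.intensity,
                "snr": a.peak.snr,
                "C": f.c if f else pd.NA,
                "H": f.h if f else pd.NA,
                "O": f.o if f else pd.NA,
                "N": f.n if f else pd.NA,
                "S": f.s if f else pd.NA,
                "error_ppm": a.error_ppm if a.error_ppm is not None else np.nan,
                "n_candidates": a.n_candidates,
            }
        )
    df = pd.DataFrame(rows, columns=ASSIGNED_COLUMNS)
    for col in "CHONS":
        df[col] = df[col].astype("Int64")
    if sample_id is not None:
        df.insert(0, "sample_id", sample_id)
    return df
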