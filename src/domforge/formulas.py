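"""Exact-mass CHNOS chemistry primitives.

Everything downstream — formula assignment, van Krevelen classification,
chemodiversity accounting — rests on the five-element molecular formula
(C, H, O, N, S) and its monoisotopic neutral mass.  Negative-mode
electrospray of dissolved organic matter yields singly deprotonated
[M-H]- ions, so the only ion<->neutral conversion supported is adding or
removing one proton.

Monoisotopic masses are the IUPAC/CODATA recommended values (AME/CODATA
compilations, truncated past the 11th decimal); they are module constants
and never mutated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

# Monoisotopic atomic masses in Da.  12C is exact by definition.
MASS_C = 12.0
MASS_H = 1.00782503207
MASS_O = 15.99491461956
MASS_N = 14.0030740048
MASS_S = 31.97207100

#: Mass of the proton in Da.  The [M-H]- convention used here folds the
#: electron mass into this constant: neutral M = m/z + MASS_PROTON.
MASS_PROTON = 1.007276466812
MASS_ELECTRON = 0.00054857990946

#: The only ionization mode supported: singly deprotonated, negative ESI.
MODE_M_MINUS_H = "[M-H]-"


class ElementGroup(enum.Enum):
    """Heteroatom group of a DOM formula: CHO, CHON, CHOS, or CHONS.

    Membership is decided solely by the presence of N and S; the C, H and
    (in practice always present) O backbone gives the groups their names.
    """

    CHO = "CHO"
    CHON = "CHON"
    CHOS = "CHOS"
    CHONS = "CHONS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True, slots=True)
class MolecularFormula:
    """An elemental composition C_c H_h O_o N_n S_s.

    Formulas are value objects: equality and hashing are over the five
    integer counts, which is exactly the identity FT-ICR-MS can resolve
    (structural isomers are indistinguishable).
    """

    c: int = 0
    h: int = 0
    o: int = 0
    n: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "o", "n", "s"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"element count {name!r} must be an int, got {v!r}")
            if v < 0:
                raise ValueError(f"element count {name!r} must be >= 0, got {v}")

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return MolecularFormula(
            self.c + other.c,
            self.h + other.h,
            self.o + other.o,
            self.n + other.n,
            self.s + other.s,
        )

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.c, self.h, self.o, self.n, self.s)

    def __str__(self) -> str:
        parts = []
        for sym, v in zip("CHONS", self.as_tuple()):
            if v == 1:
                parts.append(sym)
            elif v > 1:
                parts.append(f"{sym}{v}")
        return "".join(parts) or "(empty)"


def exact_neutral_mass(f: MolecularFormula) -> float:
    """Monoisotopic neutral mass of ``f`` in Da."""
    return (
        f.c * MASS_C
        + f.h * MASS_H
        + f.o * MASS_O
        + f.n * MASS_N
        + f.s * MASS_S
    )


def dbe(f: MolecularFormula) -> float:
    """Double bond equivalents (rings + pi bonds): 1 + C - H/2 + N/2.

    Uses the standard CHNOS valence model (tetravalent C, monovalent H,
    trivalent N, divalent O and S; O and S therefore drop out).  The value
    can be half-integer, in which case the formula cannot be an
    even-electron neutral and is rejected by the assignment filters.
    """
    return 1.0 + f.c - f.h / 2.0 + f.n / 2.0


def elemental_ratios(f: MolecularFormula) -> tuple[float, float]:
    """Return ``(h_c, o_c)`` = (H/C, O/C); requires at least one carbon."""
    if f.c < 1:
        raise ValueError(f"elemental ratios undefined for carbon-free formula {f}")
    return f.h / f.c, f.o / f.c


def element_group(f: MolecularFormula) -> ElementGroup:
    """CHO/CHON/CHOS/CHONS membership from the presence of N and S."""
    if f.c < 1 or f.h < 1:
        raise ValueError(f"element group undefined without a CH backbone: {f}")
    if f.n > 0 and f.s > 0:
        return ElementGroup.CHONS
    if f.n > 0:
        return ElementGroup.CHON
    if f.s > 0:
        return ElementGroup.CHOS
    return ElementGroup.CHO


def neutral_mass_from_mz(mz: float, mode: str = MODE_M_MINUS_H) -> float:
    """Neutral monoisotopic mass from a measured m/z.

    Only singly deprotonated negative ions are supported: M = m/z + proton.
    """
    if mode != MODE_M_MINUS_H:
        raise ValueError(f"unsupported ionization mode {mode!r}; only {MODE_M_MINUS_H} is implemented")
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    return mz + MASS_PROTON


def mz_from_neutral_mass(mass: float, mode: str = MODE_M_MINUS_H) -> float:
    """Theoretical [M-H]- m/z of a neutral mass (inverse of
    :func:`neutral_mass_from_mz`)."""
    if mode != MODE_M_MINUS_H:
        raise ValueError(f"unsupported ionization mode {mode!r}; only {MODE_M_MINUS_H} is implemented")
    if mass <= MASS_PROTON:
        raise ValueError(f"neutral mass {mass} too small to deprotonate")
    return mass - MASS_PROTON
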