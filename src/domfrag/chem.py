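"""Elemental formula arithmetic for small-molecule mass spectrometry.

Formulas over C, H, N, O, S, P with optional single-atom isotope
substitutions (one or more ``13C`` / ``15N``), exact monoisotopic masses,
double-bond equivalents (DBE), the modified aromaticity index (AI_mod) and
the molecular-category scheme used for dissolved organic matter (DOM).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from types import MappingProxyType

__all__ = [
    "ElementalFormula",
    "MASSES",
    "CompoundClass",
    "neutral_mass",
    "ion_mass",
    "dbe",
    "ai_mod",
    "classify",
    "parse_formula",
]

# CODATA / IUPAC monoisotopic masses (Da), immutable after load.
MASSES = MappingProxyType(
    {
        "C": 12.0,
        "H": 1.00782503207,
        "N": 14.0030740048,
        "O": 15.9949146196,
        "S": 31.97207100,
        "P": 30.97376163,
        "proton": 1.00727646688,
        "electron": 0.00054857990907,
        # isotope mass differences
        "13C-12C": 1.0033548378,
        "15N-14N": 0.9970348934,
    }
)


class InvalidIonError(ValueError):
    """Raised when an ion species cannot be formed from a formula."""


@dataclass(frozen=True, order=True)
class ElementalFormula:
    """Integer element counts; the atom of all mass/DBE/AI computations.

    ``c13`` and ``n15`` count heavy-isotope substitutions and are included
    in ``c`` / ``n`` totals (i.e. ``c`` is the total carbon count of which
    ``c13`` atoms are ¹³C).
    """

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0
    c13: int = 0
    n15: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s", "p", "c13", "n15"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"element count {name}={v!r} must be a non-negative int")
        if self.c13 > self.c:
            raise ValueError(f"c13={self.c13} exceeds total carbon c={self.c}")
        if self.n15 > self.n:
            raise ValueError(f"n15={self.n15} exceeds total nitrogen n={self.n}")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            self.c + other.c, self.h + other.h, self.n + other.n,
            self.o + other.o, self.s + other.s, self.p + other.p,
            self.c13 + other.c13, self.n15 + other.n15,
        )

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        try:
            return ElementalFormula(
                self.c - other.c, self.h - other.h, self.n - other.n,
                self.o - other.o, self.s - other.s, self.p - other.p,
                self.c13 - other.c13, self.n15 - other.n15,
            )
        except ValueError as exc:
            raise ValueError(f"cannot subtract {other} from {self}: {exc}") from exc

    def contains(self, other: "ElementalFormula") -> bool:
        """Whether every atom of ``other`` is available in this formula."""
        return (
            self.c >= other.c and self.h >= other.h and self.n >= other.n
            and self.o >= other.o and self.s >= other.s and self.p >= other.p
            and self.c13 >= other.c13 and self.n15 >= other.n15
        )

    @property
    def heteroatoms(self) -> int:
        return self.n + self.s + self.p

    def hill(self) -> str:
        """Hill-order string, isotope substitutions as prefix tokens.

        ``C18H22O8``; with one ¹³C: ``[13C]1C17H22O8`` (the plain ``C``
        count is the remaining ¹²C).
        """
        parts = []
        if self.c13:
            parts.append(f"[13C]{self.c13}")
        if self.n15:
            parts.append(f"[15N]{self.n15}")
        light = [
            ("C", self.c - self.c13),
            ("H", self.h),
            ("N", self.n - self.n15),
            ("O", self.o),
            ("P", self.p),
            ("S", self.s),
        ]
        for sym, count in light:
            if count == 0:
                continue
            parts.append(sym if count == 1 else f"{sym}{count}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


_TOKEN = re.compile(r"\[13C\](\d+)|\[15N\](\d+)|([CHNOPS])(\d*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse the Hill-order serialization produced by :meth:`ElementalFormula.hill`."""
    counts = {"c": 0, "h": 0, "n": 0, "o": 0, "s": 0, "p": 0, "c13": 0, "n15": 0}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"unparseable formula {text!r} at position {pos}")
        pos = m.end()
        if m.group(1) is not None:
            counts["c13"] += int(m.group(1))
        elif m.group(2) is not None:
            counts["n15"] += int(m.group(2))
        else:
            sym, num = m.group(3), m.group(4)
            counts[sym.lower()] += int(num) if num else 1
    if pos != len(text):
        raise ValueError(f"unparseable formula {text!r} at position {pos}")
    counts["c"] += counts["c13"]
    counts["n"] += counts["n15"]
    return ElementalFormula(**counts)


def neutral_mass(f: ElementalFormula) -> float:
    """Exact monoisotopic mass of the neutral molecule in Da."""
    return (
        f.c * MASSES["C"]
        + f.h * MASSES["H"]
        + f.n * MASSES["N"]
        + f.o * MASSES["O"]
        + f.s * MASSES["S"]
        + f.p * MASSES["P"]
        + f.c13 * MASSES["13C-12C"]
        + f.n15 * MASSES["15N-14N"]
    )


def ion_mass(f: ElementalFormula, electron_correction: bool = False) -> float:
    """m/z of the singly deprotonated anion [M-H]⁻.

    By default the abstracted hydrogen is treated as a proton
    (m/z = M − 1.00727646688).  With ``electron_correction`` the neutral
    loses a hydrogen atom and gains an electron
    (m/z = M − 1.00782503207 + m_e); the 0.00055 Da difference matters at
    sub-ppm accuracy, so downstream writers log which convention was used.
    """
    if f.h < 1:
        raise InvalidIonError(f"{f.hill() or 'empty formula'} has no hydrogen to abstract")
    if electron_correction:
        return neutral_mass(f) - MASSES["H"] + MASSES["electron"]
    return neutral_mass(f) - MASSES["proton"]


def dbe(f: ElementalFormula, n_valence: int = 3, p_valence: int = 3) -> float:
    """Double-bond equivalents, N and P trivalent by default.

    DBE = 1 + C − H/2 + N/2 + P/2.  May be negative; the caller decides
    chemical plausibility.  Pentavalent N or P can be selected via the
    valence arguments (each unit of valence above 3 adds one bond site).
    """
    n_term = f.n * (n_valence - 2) / 2.0
    p_term = f.p * (p_valence - 2) / 2.0
    return 1.0 + f.c - f.h / 2.0 + n_term + p_term


def ai_mod(f: ElementalFormula) -> float:
    """Modified aromaticity index.

    AI_mod = (1 + C − 0.5·O − S − 0.5·(N + P + H)) / (C − 0.5·O − S − N − P),
    with the convention that a non-positive numerator or denominator
    yields 0 (prevents spurious aromatic labels for O-rich aliphatics).
    """
    num = 1.0 + f.c - 0.5 * f.o - f.s - 0.5 * (f.n + f.p + f.h)
    den = f.c - 0.5 * f.o - f.s - f.n - f.p
    if den <= 0 or num <= 0:
        return 0.0
    return num / den


class CompoundClass(str, Enum):
    """Mutually exclusive DOM molecular categories."""

    BLACK_CARBON = "black_carbon"
    POLYPHENOL_O_RICH = "polyphenol_o_rich"
    POLYPHENOL_O_POOR = "polyphenol_o_poor"
    HIGHLY_UNSATURATED = "highly_unsaturated"
    ALIPHATIC = "aliphatic"
    OTHER = "other"


def classify(f: ElementalFormula) -> CompoundClass:
    """Assign the molecular category of a formula.

    First matching rule wins: combustion-derived polycyclic aromatics
    (black carbon: AI_mod ≥ 0.666 with no N, S or P), O-rich and O-poor
    polyphenols (0.5 ≤ AI_mod < 0.666 split at O/C = 0.5), highly
    unsaturated compounds (AI_mod < 0.5, H/C < 1.5, O/C < 0.9),
    aliphatics (1.5 ≤ H/C ≤ 2.0, O/C < 0.9, no N), else ``other``.
    """
    if f.c < 1:
        raise ValueError("classification requires at least one carbon")
    ai = ai_mod(f)
    hc = f.h / f.c
    oc = f.o / f.c
    if ai >= 0.666 and f.n == 0 and f.s == 0 and f.p == 0:
        return CompoundClass.BLACK_CARBON
    if 0.5 <= ai < 0.666 and oc > 0.5:
        return CompoundClass.POLYPHENOL_O_RICH
    if 0.5 <= ai < 0.666 and oc <= 0.5:
        return CompoundClass.POLYPHENOL_O_POOR
    if ai < 0.5 and hc < 1.5 and oc < 0.9:
        return CompoundClass.HIGHLY_UNSATURATED
    if 1.5 <= hc <= 2.0 and oc < 0.9 and f.n == 0:
        return CompoundClass.ALIPHATIC
    return CompoundClass.OTHER
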