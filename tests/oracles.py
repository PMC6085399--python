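"""Independent oracles used to cross-check the implementation.

These deliberately avoid the package's own mass constants and search
code: masses come from pyteomics, loops are plain Python.
"""

from __future__ import annotations

from math import ceil

import numpy as np
from pyteomics.mass import nist_mass

# pyteomics NIST monoisotopic masses — independent of domfrag.chem.MASSES
_M = {el: nist_mass[el][0][0] for el in ("C", "H", "N", "O", "S", "P")}
_PROTON = nist_mass["H+"][0][0]


def oracle_ion_mass(c: int, h: int, n: int, o: int, s: int, p: int) -> float:
    neutral = (
        c * _M["C"] + h * _M["H"] + n * _M["N"]
        + o * _M["O"] + s * _M["S"] + p * _M["P"]
    )
    return neutral - _PROTON


def oracle_candidates(
    mz: float,
    tol_ppm: float,
    c_max: int = 60,
    n_max: int = 4,
    s_max: int = 2,
    p_max: int = 1,
    oc_max: float = 1.0,
    hc_min: float = 0.3,
) -> set[tuple[int, int, int, int, int, int]]:
    """Exhaustive enumeration of (c, h, n, o, s, p) [M−H]⁻ candidates.

    Same constraint box as the implementation (O/C <= 1, H/C >= 0.3,
    h <= 2c+n+p+2, integer DBE >= 0) but written as nested plain loops
    over a narrow hydrogen window around the mass-implied value, which is
    exhaustive because the ppm tolerance is far below the H spacing.
    """
    out = set()
    tol_da = mz * tol_ppm / 1e6
    for c in range(1, c_max + 1):
        for n in range(0, n_max + 1):
            for s in range(0, s_max + 1):
                for p in range(0, p_max + 1):
                    for o in range(0, int(oc_max * c) + 1):
                        base = oracle_ion_mass(c, 0, n, o, s, p)
                        h_guess = int(round((mz - base) / _M["H"]))
                        for h in range(max(1, h_guess - 2), h_guess + 3):
                            if h < hc_min * c - 1e-9 or h > 2 * c + n + p + 2:
                                continue
                            if (h + n + p) % 2 == 1:  # non-integer DBE
                                continue
                            if 2 + 2 * c - h + n + p < 0:  # DBE < 0
                                continue
                            if abs(oracle_ion_mass(c, h, n, o, s, p) - mz) <= tol_da:
                                out.add((c, h, n, o, s, p))
    return out


def oracle_bray_curtis(x, y) -> float:
    """Element-wise Bray–Curtis, written out long-hand."""
    num = 0.0
    den = 0.0
    for xi, yi in zip(x, y):
        num += abs(xi - yi)
        den += xi + yi
    return num / den
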