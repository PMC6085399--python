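"""Molecular formula assignment for calibrated full-range spectra.

Every peak is matched against an exhaustive enumeration of elemental
compositions inside a constraint box (element ranges, O/C and H/C limits,
integer non-negative DBE) under a ppm tolerance, following standard
dissolved-organic-matter assignment criteria.  Heavy-isotope peaks
(¹³C1, ¹⁵N1) are verified afterwards against already-assigned parents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem import (
    MASSES,
    CompoundClass,
    ElementalFormula,
    classify,
    ion_mass,
)
from .peaks import Peak, PeakList

__all__ = [
    "AssignmentConstraints",
    "AssignedPeak",
    "enumerate_candidates",
    "assign",
    "verify_isotopologues",
    "common_formulae",
]

logger = logging.getLogger(__name__)

C13_ABUNDANCE = 0.0107  # natural 13C fraction


@dataclass(frozen=True)
class AssignmentConstraints:
    """Element ranges and ratio limits for candidate enumeration.

    Defaults follow the common DOM criteria: C 1–60, N 0–4, S 0–2, P 0–1,
    O/C <= 1, H/C >= 0.3, singly deprotonated even-electron ions, integer
    DBE >= 0.  Hydrogen is implicitly bounded by h <= 2c + n + p + 2
    (DBE >= 0), which closes the nominally unbounded H range.
    """

    c_max: int = 60
    n_max: int = 4
    s_max: int = 2
    p_max: int = 1
    oc_max: float = 1.0
    hc_min: float = 0.3
    tolerance_ppm: float = 0.5
    mass_min: float = 150.0
    mass_max: float = 2000.0
    electron_correction: bool = False


@dataclass
class AssignedPeak:
    """A peak joined to its molecular formula."""

    peak: Peak
    formula: ElementalFormula
    error_ppm: float
    compound_class: CompoundClass
    is_isotopologue: bool = False
    parent_formula: ElementalFormula | None = None


# ---------------------------------------------------------------------------
# candidate enumeration

_GRID_CACHE: dict[tuple, tuple[np.ndarray, ...]] = {}


def _base_grid(constraints: AssignmentConstraints) -> tuple[np.ndarray, ...]:
    """Flat arrays (c, n, s, p, o, base_mass) over the CNSPO constraint box.

    Hydrogen is resolved per target mass, so it is not part of the grid.
    The grid is cached per constraint box (a few 1e5 rows at defaults).
    """
    key = (
        constraints.c_max,
        constraints.n_max,
        constraints.s_max,
        constraints.p_max,
        constraints.oc_max,
    )
    if key in _GRID_CACHE:
        return _GRID_CACHE[key]
    c = np.arange(1, constraints.c_max + 1)
    n = np.arange(0, constraints.n_max + 1)
    s = np.arange(0, constraints.s_max + 1)
    p = np.arange(0, constraints.p_max + 1)
    o_max_abs = int(np.floor(constraints.oc_max * constraints.c_max))
    o = np.arange(0, o_max_abs + 1)
    C, N, S, P, O = np.meshgrid(c, n, s, p, o, indexing="ij")
    C, N, S, P, O = (a.ravel() for a in (C, N, S, P, O))
    keep = O <= np.floor(constraints.oc_max * C)
    C, N, S, P, O = (a[keep] for a in (C, N, S, P, O))
    base = (
        C * MASSES["C"]
        + N * MASSES["N"]
        + S * MASSES["S"]
        + P * MASSES["P"]
        + O * MASSES["O"]
    )
    grid = (C, N, S, P, O, base)
    _GRID_CACHE[key] = grid
    return grid


def enumerate_candidates(
    mz: float,
    constraints: AssignmentConstraints = AssignmentConstraints(),
) -> list[tuple[ElementalFormula, float]]:
    """All formulas whose [M−H]⁻ ion mass falls within tolerance of ``mz``.

    Candidates satisfy the element ranges, O/C <= oc_max, H/C >= hc_min,
    h <= 2c + n + p + 2 and integer DBE >= 0; sorted by |error_ppm|.
    """
    C, N, S, P, O, base = _base_grid(constraints)
    if constraints.electron_correction:
        target_neutral = mz + MASSES["H"] - MASSES["electron"]
    else:
        target_neutral = mz + MASSES["proton"]
    h_float = (target_neutral - base) / MASSES["H"]
    H = np.rint(h_float).astype(int)
    neutral = base + H * MASSES["H"]
    ion = neutral - (target_neutral - mz)
    err_ppm = (ion - mz) / mz * 1e6
    dbe2 = 2 + 2 * C - H + N + P  # 2*DBE; integrality <=> H+N+P even
    ok = (
        (H >= 1)
        & (H >= np.ceil(constraints.hc_min * C) - 1e-9)
        & (H <= 2 * C + N + P + 2)
        & (dbe2 >= 0)
        & (dbe2 % 2 == 0)
        & (np.abs(err_ppm) <= constraints.tolerance_ppm)
    )
    idx = np.nonzero(ok)[0]
    out = [
        (
            ElementalFormula(
                c=int(C[i]), h=int(H[i]), n=int(N[i]),
                o=int(O[i]), s=int(S[i]), p=int(P[i]),
            ),
            float(err_ppm[i]),
        )
        for i in idx
    ]
    out.sort(key=lambda t: (abs(t[1]), t[0].heteroatoms, t[0].hill()))
    return out


# ---------------------------------------------------------------------------
# assignment

def _isotopologue_confirmed(
    formula: ElementalFormula,
    peak_mz: float,
    spectrum_mz: np.ndarray,
    tol_ppm: float,
) -> bool:
    """Whether a ¹³C1 companion of this candidate exists in the spectrum."""
    target = peak_mz + MASSES["13C-12C"]
    if spectrum_mz.size == 0 or formula.c < 1:
        return False
    nearest = spectrum_mz[np.argmin(np.abs(spectrum_mz - target))]
    return abs(nearest - target) / target * 1e6 <= tol_ppm


def assign(
    pl: PeakList,
    constraints: AssignmentConstraints = AssignmentConstraints(),
    tie_ppm: float | None = None,
) -> list[AssignedPeak]:
    """Assign the best candidate formula to every peak of a calibrated list.

    Candidates within ``tie_ppm`` of the best |error| (default: the whole
    tolerance window) compete by (1) a confirming ¹³C1 isotopologue in
    the same spectrum, (2) fewest heteroatoms N+S+P, (3) smallest
    |error_ppm|, (4) Hill string — fully deterministic.  Heteroatom
    parsimony over the full window is essential at DOM mass accuracy: the
    C5H5 ↔ N4PS2 substitution leaves candidates ~0.35 ppm apart near
    370 Da, so a pure nearest-mass rule flips on sub-tolerance jitter.
    Peaks with no in-tolerance candidate stay unassigned (not returned).
    """
    if tie_ppm is None:
        tie_ppm = constraints.tolerance_ppm
    spectrum_mz = pl.mz
    assigned: list[AssignedPeak] = []
    n_ambiguous = 0
    for peak in pl.peaks:
        if not (constraints.mass_min <= peak.mz <= constraints.mass_max):
            continue
        cands = enumerate_candidates(peak.mz, constraints)
        if not cands:
            continue
        best_err = abs(cands[0][1])
        tied = [c for c in cands if abs(c[1]) <= best_err + tie_ppm]
        if len(tied) > 1:
            n_ambiguous += 1
            tied.sort(
                key=lambda t: (
                    not _isotopologue_confirmed(
                        t[0], peak.mz, spectrum_mz, constraints.tolerance_ppm
                    ),
                    t[0].heteroatoms,
                    abs(t[1]),
                    t[0].hill(),
                )
            )
        formula, err = tied[0]
        assigned.append(
            AssignedPeak(
                peak=peak,
                formula=formula,
                error_ppm=err,
                compound_class=classify(formula),
            )
        )
    logger.info(
        "assigned %d/%d peaks (%d ambiguous ties broken)",
        len(assigned), len(pl), n_ambiguous,
    )
    return assigned


# ---------------------------------------------------------------------------
# isotopologue verification

def verify_isotopologues(
    assigned: list[AssignedPeak],
    pl: PeakList,
    tol_ppm: float = 0.5,
    abundance_factor: float = 3.0,
) -> list[AssignedPeak]:
    """Flag unassigned peaks that are ¹³C1 / ¹⁵N1 companions of parents.

    A candidate isotopologue peak must sit at parent m/z + the isotope
    mass difference within ``tol_ppm``; its intensity is checked against
    the binomial expectation (¹³C1: parent intensity × c·0.0107/(1−0.0107))
    within a multiplicative ``abundance_factor``.  Peaks failing the
    abundance check are left unflagged with a warning.
    """
    out = list(assigned)
    taken = {id(a.peak) for a in assigned}
    parents = [(a.peak, a.formula) for a in assigned if not a.is_isotopologue]
    for peak in pl.peaks:
        if id(peak) in taken:
            continue
        for parent_peak, parent_formula in parents:
            for diff_key, element_count, heavy_field in (
                ("13C-12C", parent_formula.c, "c13"),
                ("15N-14N", parent_formula.n, "n15"),
            ):
                if element_count < 1:
                    continue
                target = parent_peak.mz + MASSES[diff_key]
                if abs(peak.mz - target) / target * 1e6 > tol_ppm:
                    continue
                if diff_key == "13C-12C":
                    expected = (
                        parent_peak.intensity
                        * element_count * C13_ABUNDANCE / (1 - C13_ABUNDANCE)
                    )
                    if not (
                        expected / abundance_factor
                        <= peak.intensity
                        <= expected * abundance_factor
                    ):
                        logger.warning(
                            "peak %.5f matches 13C1 of %s but intensity %.3g "
                            "is outside x%g of binomial expectation %.3g",
                            peak.mz, parent_formula.hill(), peak.intensity,
                            abundance_factor, expected,
                        )
                        continue
                heavy = replace(
                    parent_formula, **{heavy_field: 1}
                )
                out.append(
                    AssignedPeak(
                        peak=peak,
                        formula=heavy,
                        error_ppm=(peak.mz - target) / target * 1e6,
                        compound_class=classify(parent_formula),
                        is_isotopologue=True,
                        parent_formula=parent_formula,
                    )
                )
                taken.add(id(peak))
                break
            if id(peak) in taken:
                break
    return out


# ---------------------------------------------------------------------------
# cross-sample intersection

def common_formulae(
    samples: Mapping[str, Iterable[ElementalFormula]] | Sequence[Iterable[ElementalFormula]],
    allow_single: bool = False,
) -> tuple[set[ElementalFormula], dict[str, float]]:
    """Formulas present in every sample, with per-sample shares (%).

    Share of a sample = |intersection| / |its formula set| × 100.
    """
    if isinstance(samples, Mapping):
        sets = {k: set(v) for k, v in samples.items()}
    else:
        sets = {f"sample{i}": set(v) for i, v in enumerate(samples)}
    if len(sets) < 2 and not allow_single:
        raise ValueError("need >= 2 samples for an intersection (allow_single=False)")
    common: set[ElementalFormula] | None = None
    for s in sets.values():
        common = set(s) if common is None else common & s
    common = common or set()
    shares = {
        k: (100.0 * len(common) / len(s) if s else 0.0) for k, s in sets.items()
    }
    return common, shares
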