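"""Isomeric diversity from paired carboxyl-group estimates.

Each molecular formula in DOM hides an unknown number of structural
isomers.  The number of carboxyl groups per formula can be estimated two
independent ways: from the CO2-loss fragmentation series
(intensity-weighted decarboxylation multiplicity) and from elemental
composition alone.  Because the fragmentation estimate averages over all
isomers behind a formula, the agreement between the two estimates grows
with the number of isomers (central-limit averaging): the correlation
serves as a diversity index, and the residual dispersion yields a
minimum isomer number n_min = ceil((σ_single/σ_residual)²).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from .chem import ElementalFormula, dbe
from .fragmentation import MAJOR_LOSSES, PRECURSOR_LABEL, FragmentProfile

__all__ = [
    "CarboxylModel",
    "CarboxylEstimates",
    "DiversityEstimate",
    "CO2_MULTIPLICITY",
    "carboxyl_from_fragments",
    "carboxyl_from_formula",
    "fit_carboxyl_model",
    "diversity_index",
    "min_isomers",
    "min_compounds",
]

logger = logging.getLogger(__name__)

#: CO2 units per major loss; only decarboxylation events count toward
#: carboxyl number (H2O- and CH3OH-only losses carry 0).
CO2_MULTIPLICITY: dict[str, int] = {
    loss.label: loss.co2_multiplicity for loss in MAJOR_LOSSES
}
CO2_MULTIPLICITY[PRECURSOR_LABEL] = 0

MAX_CO2_MULTIPLICITY = max(CO2_MULTIPLICITY.values())

DEFAULT_MIN_ISOMER_CAP = 10**6


@dataclass
class CarboxylModel:
    """Linear composition model c_formula = a·O + b·DBE + c0.

    The functional form is deliberately simple and pluggable; parameters
    are either user-supplied or calibrated against known carboxyl counts
    (synthetic ground truth).  Provenance is carried in ``source``.
    """

    a: float = 0.5
    b: float = 0.0
    c0: float = 0.0
    source: str = "default (a=0.5, b=0, c0=0)"

    def predict(self, f: ElementalFormula) -> float:
        return self.a * f.o + self.b * dbe(f) + self.c0


@dataclass
class CarboxylEstimates:
    """The two independent carboxyl estimates for one formula."""

    formula: ElementalFormula
    c_frag: float
    c_formula: float

    def __post_init__(self) -> None:
        if not (0 <= self.c_frag <= MAX_CO2_MULTIPLICITY + 1e-9):
            raise ValueError(
                f"c_frag={self.c_frag} outside [0, {MAX_CO2_MULTIPLICITY}]"
            )
        if not np.isfinite(self.c_formula) or self.c_formula < 0:
            raise ValueError(f"c_formula={self.c_formula} must be finite and >= 0")


@dataclass
class DiversityEstimate:
    """Per-sample isomer-diversity summary."""

    sample_id: str
    r_estimates: float
    n_min_isomers: int
    n_min_compounds: int
    sigma_single: float = float("nan")
    sigma_residual: float = float("nan")
    model: CarboxylModel = field(default_factory=CarboxylModel)


def carboxyl_from_fragments(
    profile: FragmentProfile | Mapping[str, float],
) -> float:
    """Intensity-weighted carboxyl count from the CO2-loss series.

    c_frag = Σ_k k·I_k / Σ_k I_k, where k is the CO2 multiplicity of each
    major loss (the precursor counts at k = 0) and I_k the relative
    intensity at that multiplicity.
    """
    if isinstance(profile, FragmentProfile):
        weights = dict(profile.rel)
        weights[PRECURSOR_LABEL] = profile.precursor_share
    else:
        weights = dict(profile)
    unknown = set(weights) - set(CO2_MULTIPLICITY)
    if unknown:
        raise KeyError(f"unknown loss labels {sorted(unknown)}")
    total = float(sum(weights.values()))
    if total <= 0:
        raise ValueError("all intensities are zero")
    return sum(CO2_MULTIPLICITY[lbl] * w for lbl, w in weights.items()) / total


def carboxyl_from_formula(
    f: ElementalFormula, model: CarboxylModel | None = None
) -> float:
    """Carboxyl count predicted from elemental composition alone."""
    model = model or CarboxylModel()
    value = model.predict(f)
    return max(0.0, float(value))


def fit_carboxyl_model(
    formulas: Sequence[ElementalFormula],
    carboxyl_counts: Sequence[float],
    fit_dbe_term: bool = True,
) -> CarboxylModel:
    """Least-squares calibration of the composition model on known counts."""
    if len(formulas) != len(carboxyl_counts) or len(formulas) < 3:
        raise ValueError("need >= 3 (formula, count) pairs of equal length")
    o = np.array([f.o for f in formulas], dtype=float)
    d = np.array([dbe(f) for f in formulas])
    y = np.asarray(carboxyl_counts, dtype=float)
    cols = [o, d, np.ones_like(o)] if fit_dbe_term else [o, np.ones_like(o)]
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    if fit_dbe_term:
        a, b, c0 = (float(v) for v in coef)
    else:
        a, c0 = (float(v) for v in coef)
        b = 0.0
    return CarboxylModel(
        a=a, b=b, c0=c0,
        source=f"least-squares fit on {len(formulas)} formulas",
    )


def diversity_index(estimates: Sequence[CarboxylEstimates]) -> float:
    """Pearson correlation between the two carboxyl estimates.

    Higher correlation indicates more isomers per formula: with n isomers
    the fragmentation estimate is an n-fold average and its scatter
    around the composition prediction shrinks as 1/√n.
    """
    if len(estimates) < 10:
        raise ValueError(f"need >= 10 formulas with both estimates, got {len(estimates)}")
    x = np.array([e.c_frag for e in estimates])
    y = np.array([e.c_formula for e in estimates])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the estimates")
    r, _ = scipy.stats.pearsonr(x, y)
    return float(r)


def min_isomers(
    estimates: Sequence[CarboxylEstimates],
    sigma_single: float,
    cap: int = DEFAULT_MIN_ISOMER_CAP,
) -> tuple[int, float]:
    """Minimum isomer number per formula from residual dispersion.

    Averaging n isomers shrinks the per-isomer dispersion σ_single of the
    fragmentation estimate by √n, so the residual standard deviation
    σ_residual of (c_frag − c_formula) across formulas bounds n from
    below: n_min = ceil((σ_single/σ_residual)²).  Returns
    (n_min, σ_residual); a zero residual yields the configured cap with
    a warning.
    """
    if sigma_single <= 0:
        raise ValueError("sigma_single must be positive")
    resid = np.array([e.c_frag - e.c_formula for e in estimates])
    sigma_residual = float(np.std(resid, ddof=1)) if len(resid) > 1 else 0.0
    if sigma_residual == 0:
        logger.warning("zero residual dispersion; returning cap %d", cap)
        return cap, 0.0
    n_min = max(1, math.ceil((sigma_single / sigma_residual) ** 2))
    return n_min, sigma_residual


def min_compounds(n_min_isomers: int, n_common_formulae: int) -> int:
    """Minimum number of universal compounds.

    The minimum isomer number multiplied by the number of molecular
    formulas common to the most degraded samples.
    """
    if n_min_isomers < 1:
        raise ValueError("n_min_isomers must be >= 1")
    if n_common_formulae < 1:
        raise ValueError("need at least one common formula")
    return n_min_isomers * n_common_formulae
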