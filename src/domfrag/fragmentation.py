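"""Neutral-loss fragment prediction, attribution and relative intensities.

DOM precursor ions isolated in narrow (0.4 Da) windows fragment almost
exclusively by losing CO2 (decarboxylation), H2O (dehydration), CH3OH and
combinations thereof.  This module predicts fragment m/z values from a
neutral-loss table, uses the predictions for internal calibration of
fragmentation spectra, attributes observed fragments to their precursor
formulas by exact mass difference, and computes relative fragment
intensities I_F/I_Tot over the nine major losses plus the precursor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem import ElementalFormula, ion_mass, neutral_mass
from .peaks import (
    CalibrationResult,
    PeakList,
    internal_calibrate,
)

__all__ = [
    "NeutralLoss",
    "IsolationWindow",
    "FragmentRecord",
    "FragmentProfile",
    "MAJOR_LOSSES",
    "MINOR_LOSSES",
    "ALL_LOSSES",
    "predict_fragments",
    "calibrate_fragment_spectrum",
    "attribute_fragments",
    "relative_intensities",
    "common_detection_limit",
    "apply_common_detection_limit",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NeutralLoss:
    """A neutral molecule (or combination) lost during fragmentation."""

    label: str
    formula: ElementalFormula
    is_major: bool = True
    co2_multiplicity: int = 0  # number of CO2 units; carboxyl bookkeeping

    @property
    def exact_mass(self) -> float:
        return neutral_mass(self.formula)


_CO2 = ElementalFormula(c=1, o=2)
_H2O = ElementalFormula(h=2, o=1)
_CH3OH = ElementalFormula(c=1, h=4, o=1)
_CO = ElementalFormula(c=1, o=1)

#: The nine major losses entering I_Tot, in the conventional order.
MAJOR_LOSSES: tuple[NeutralLoss, ...] = (
    NeutralLoss("CO2", _CO2, True, 1),
    NeutralLoss("2CO2", _CO2 + _CO2, True, 2),
    NeutralLoss("3CO2", _CO2 + _CO2 + _CO2, True, 3),
    NeutralLoss("H2O", _H2O, True, 0),
    NeutralLoss("CO2+H2O", _CO2 + _H2O, True, 1),
    NeutralLoss("2CO2+H2O", _CO2 + _CO2 + _H2O, True, 2),
    NeutralLoss("CH3OH", _CH3OH, True, 0),
    NeutralLoss("CO2+CH3OH", _CO2 + _CH3OH, True, 1),
    NeutralLoss("2CO2+CH3OH", _CO2 + _CO2 + _CH3OH, True, 2),
)

#: Losses observed but excluded from I_Tot.
MINOR_LOSSES: tuple[NeutralLoss, ...] = (
    NeutralLoss("CO", _CO, False, 0),
)

ALL_LOSSES: tuple[NeutralLoss, ...] = MAJOR_LOSSES + MINOR_LOSSES

PRECURSOR_LABEL = "precursor"


@dataclass(frozen=True)
class IsolationWindow:
    """Quadrupole isolation window around a nominal mass."""

    center: float
    width: float = 0.4

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("isolation width must be positive")

    def contains(self, mz: float) -> bool:
        return abs(mz - self.center) <= self.width / 2.0


@dataclass
class FragmentRecord:
    """A fragment peak attributed to (precursor formula, neutral loss)."""

    precursor_formula: ElementalFormula
    loss: NeutralLoss
    fragment_mz: float
    intensity: float
    rel_intensity: float = float("nan")
    ambiguous: bool = False

    @property
    def fragment_formula(self) -> ElementalFormula:
        return self.precursor_formula - self.loss.formula


@dataclass
class FragmentProfile:
    """Relative intensities I_F/I_Tot per major loss for one precursor.

    ``rel[label]`` plus ``precursor_share`` sum to exactly 1; losses with
    no detected fragment carry 0.
    """

    precursor_formula: ElementalFormula
    precursor_share: float
    rel: dict[str, float] = field(default_factory=dict)
    precursor_snr: float = float("nan")

    def as_vector(self, labels: Sequence[str] | None = None) -> np.ndarray:
        labels = labels or [l.label for l in MAJOR_LOSSES]
        return np.array([self.rel.get(lbl, 0.0) for lbl in labels])


def predict_fragments(
    precursor: ElementalFormula,
    losses: Sequence[NeutralLoss] = ALL_LOSSES,
    electron_correction: bool = False,
) -> list[tuple[NeutralLoss, float]]:
    """Fragment ion m/z per applicable loss.

    Fragment ion m/z = precursor [M−H]⁻ m/z − exact loss mass.  Losses
    whose atoms are not available in the precursor (or that would strip
    the charge-carrying hydrogen) are skipped.
    """
    pmz = ion_mass(precursor, electron_correction=electron_correction)
    out = []
    for loss in losses:
        if not precursor.contains(loss.formula):
            logger.debug(
                "loss %s skipped for %s: insufficient atoms", loss.label, precursor.hill()
            )
            continue
        frag = precursor - loss.formula
        if frag.h < 1:  # deprotonated fragment needs a hydrogen left
            logger.debug(
                "loss %s skipped for %s: no H left on fragment", loss.label, precursor.hill()
            )
            continue
        out.append((loss, pmz - loss.exact_mass))
    return out


def calibrate_fragment_spectrum(
    frag: PeakList,
    precursors: Sequence[ElementalFormula],
    losses: Sequence[NeutralLoss] = ALL_LOSSES,
    match_tol_ppm: float = 1.0,
    max_ppm: float = 0.06,
    order: int = 1,
    electron_correction: bool = False,
) -> tuple[PeakList, CalibrationResult]:
    """Internally calibrate a fragmentation spectrum.

    Reference masses are the predicted fragment ions of all precursors in
    the isolation window plus the precursor ions themselves — the standard
    trick when no external calibrant survives precursor isolation.
    """
    refs: set[float] = set()
    for prec in precursors:
        refs.add(ion_mass(prec, electron_correction=electron_correction))
        for _, mz in predict_fragments(prec, losses, electron_correction):
            refs.add(mz)
    return internal_calibrate(
        frag, sorted(refs), match_tol_ppm=match_tol_ppm, max_ppm=max_ppm, order=order
    )


def attribute_fragments(
    frag: PeakList,
    precursors: Sequence[ElementalFormula],
    losses: Sequence[NeutralLoss] = ALL_LOSSES,
    tol_ppm: float = 1.0,
    ambiguous_policy: str = "exclude",
    electron_correction: bool = False,
) -> tuple[list[FragmentRecord], list[float]]:
    """Match fragment peaks to (precursor, loss) pairs by exact mass.

    Each peak is compared against every predicted fragment m/z of every
    precursor in the window.  A single explanation within ``tol_ppm``
    attributes the peak; multiple explanations mark it ambiguous and,
    under the default ``exclude`` policy, drop it from statistics, while
    the ``split`` policy divides its intensity equally among the
    explanations.  Returns the records and the m/z of unattributed peaks.
    """
    if ambiguous_policy not in ("exclude", "split"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    predictions: list[tuple[ElementalFormula, NeutralLoss, float]] = []
    for prec in precursors:
        for loss, mz in predict_fragments(prec, losses, electron_correction):
            predictions.append((prec, loss, mz))
    pred_mz = np.array([p[2] for p in predictions]) if predictions else np.empty(0)

    records: list[FragmentRecord] = []
    unattributed: list[float] = []
    precursor_ion_mz = {
        prec: ion_mass(prec, electron_correction=electron_correction)
        for prec in precursors
    }
    for peak in frag.peaks:
        # precursor ions themselves are handled by relative_intensities
        if any(
            abs(peak.mz - pmz) / pmz * 1e6 <= tol_ppm
            for pmz in precursor_ion_mz.values()
        ):
            continue
        if pred_mz.size == 0:
            unattributed.append(peak.mz)
            continue
        d_ppm = np.abs(pred_mz - peak.mz) / peak.mz * 1e6
        hits = np.nonzero(d_ppm <= tol_ppm)[0]
        if hits.size == 0:
            unattributed.append(peak.mz)
            continue
        ambiguous = hits.size > 1
        if ambiguous and ambiguous_policy == "exclude":
            for i in hits:
                prec, loss, _ = predictions[i]
                records.append(
                    FragmentRecord(prec, loss, peak.mz, peak.intensity, ambiguous=True)
                )
            logger.warning(
                "fragment %.5f ambiguous between %d (precursor, loss) pairs; excluded",
                peak.mz, hits.size,
            )
            continue
        share = peak.intensity / hits.size
        for i in hits:
            prec, loss, _ = predictions[i]
            records.append(
                FragmentRecord(prec, loss, peak.mz, share, ambiguous=ambiguous)
            )
    return records, unattributed


def relative_intensities(
    records: Iterable[FragmentRecord],
    precursor_formula: ElementalFormula,
    precursor_peak_intensity: float,
    precursor_snr: float = float("nan"),
    include_ambiguous: bool = False,
) -> FragmentProfile:
    """Relative fragment intensities I_F/I_Tot for one precursor.

    I_Tot = precursor intensity + Σ intensities of the nine major-loss
    fragments attributed to that precursor (minor losses and, by default,
    ambiguous attributions are excluded).  rel intensities plus the
    precursor share sum to 1.
    """
    if precursor_peak_intensity < 0:
        raise ValueError("precursor intensity must be >= 0")
    per_loss: dict[str, float] = {l.label: 0.0 for l in MAJOR_LOSSES}
    for rec in records:
        if rec.precursor_formula != precursor_formula:
            continue
        if rec.ambiguous and not include_ambiguous:
            continue
        if not rec.loss.is_major:
            continue
        per_loss[rec.loss.label] += rec.intensity
    i_tot = precursor_peak_intensity + sum(per_loss.values())
    if i_tot <= 0:
        raise ValueError(
            f"I_Tot is zero for precursor {precursor_formula.hill()}"
        )
    rel = {lbl: v / i_tot for lbl, v in per_loss.items()}
    for rec in records:
        if rec.precursor_formula == precursor_formula and rec.loss.label in rel:
            rec.rel_intensity = rel[rec.loss.label]
    return FragmentProfile(
        precursor_formula=precursor_formula,
        precursor_share=precursor_peak_intensity / i_tot,
        rel=rel,
        precursor_snr=precursor_snr,
    )


def common_detection_limit(precursor_snr_by_sample: Mapping[str, float]) -> float:
    """The cross-sample common detection limit of one precursor.

    Defined as the minimum precursor S/N across the samples being
    compared; fragment signals below the relative threshold implied by it
    are censored symmetrically (see :func:`apply_common_detection_limit`).
    """
    if not precursor_snr_by_sample:
        raise ValueError("no samples given")
    return min(precursor_snr_by_sample.values())


def apply_common_detection_limit(
    profiles_by_sample: Mapping[str, FragmentProfile],
    noise_units: float = 1.0,
) -> dict[str, FragmentProfile]:
    """Censor fragment intensities below the common detection limit.

    The relative threshold is ``noise_units / min precursor S/N`` across
    samples (one noise-equivalent relative to the weakest precursor by
    default).  A rel intensity below the threshold in ANY sample is set to
    0 in ALL samples before comparison, so that between-sample statistics
    never compare a detected fragment with one that could not have been
    detected.  Precursor shares are left untouched.
    """
    snrs = {
        k: p.precursor_snr
        for k, p in profiles_by_sample.items()
        if np.isfinite(p.precursor_snr)
    }
    if len(snrs) < len(profiles_by_sample):
        missing = sorted(set(profiles_by_sample) - set(snrs))
        raise ValueError(f"precursor S/N missing for samples {missing}")
    limit = common_detection_limit(snrs)
    threshold = noise_units / limit if limit > 0 else float("inf")
    labels = [l.label for l in MAJOR_LOSSES]
    censor = {
        lbl
        for lbl in labels
        if any(p.rel.get(lbl, 0.0) < threshold for p in profiles_by_sample.values())
        and any(p.rel.get(lbl, 0.0) > 0 for p in profiles_by_sample.values())
    }
    if censor:
        logger.warning(
            "common detection limit %.3g (threshold_rel %.3g) censors losses %s",
            limit, threshold, sorted(censor),
        )
    out = {}
    for k, p in profiles_by_sample.items():
        rel = {lbl: (0.0 if lbl in censor else v) for lbl, v in p.rel.items()}
        out[k] = FragmentProfile(
            precursor_formula=p.precursor_formula,
            precursor_share=p.precursor_share,
            rel=rel,
            precursor_snr=p.precursor_snr,
        )
    return out
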