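"""End-to-end orchestration: filter → calibrate → assign → fragment →
statistics → diversity, with a reproducible machine-readable report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .assignment import (
    AssignedPeak,
    AssignmentConstraints,
    assign,
    common_formulae,
    verify_isotopologues,
)
from .chem import ElementalFormula, ion_mass
from .diversity import (
    CarboxylEstimates,
    CarboxylModel,
    DiversityEstimate,
    carboxyl_from_fragments,
    diversity_index,
    fit_carboxyl_model,
    min_compounds,
    min_isomers,
)
from .fragmentation import (
    MAJOR_LOSSES,
    FragmentProfile,
    IsolationWindow,
    apply_common_detection_limit,
    attribute_fragments,
    calibrate_fragment_spectrum,
    relative_intensities,
)
from .peaks import CalibrationError, PeakList, internal_calibrate, snr_filter
from .stats import DissimilarityMatrix, dissimilarity_levels, paired_regression

__all__ = ["PipelineSettings", "RunReport", "run_arrays", "select_windows"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineSettings:
    """Tunable knobs of the full analysis, with the conventional defaults."""

    min_snr: float = 5.0
    constraints: AssignmentConstraints = field(default_factory=AssignmentConstraints)
    calibration_refs: tuple[float, ...] | None = None
    max_ppm: float = 0.06
    abort_on_calibration_failure: bool = False
    attr_tol_ppm: float = 1.0
    k_windows: int = 6
    window_width: float = 0.4
    mass_region: tuple[float, float] = (350.0, 400.0)
    noise_units: float = 1.0
    renormalize_common: bool = True
    carboxyl_model: CarboxylModel | None = None  # None -> self-calibrated
    sigma_single: float | None = None  # required for minimum-isomer numbers


@dataclass
class RunReport:
    """Every result surface of one pipeline run."""

    settings_echo: dict
    version: str
    assignment_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    n_common: int = 0
    common_shares: dict[str, float] = field(default_factory=dict)
    windows: list[float] = field(default_factory=list)
    regressions: pd.DataFrame | None = None
    dissimilarity: dict[str, DissimilarityMatrix] = field(default_factory=dict)
    diversity: dict[str, DiversityEstimate] = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "settings": self.settings_echo,
            "assignment_counts": self.assignment_counts,
            "n_common": self.n_common,
            "common_shares": self.common_shares,
            "windows": self.windows,
            "regressions": (
                self.regressions.to_dict(orient="records")
                if self.regressions is not None
                else []
            ),
            "dissimilarity": {
                level: m.data.round(10).to_dict() for level, m in self.dissimilarity.items()
            },
            "diversity": {
                s: {
                    "r_estimates": d.r_estimates,
                    "n_min_isomers": d.n_min_isomers,
                    "n_min_compounds": d.n_min_compounds,
                    "sigma_single": d.sigma_single,
                    "sigma_residual": d.sigma_residual,
                    "carboxyl_model": d.model.source,
                }
                for s, d in self.diversity.items()
            },
            "notices": self.notices,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=str)


def select_windows(
    assigned_by_sample: Mapping[str, Sequence[AssignedPeak]],
    k_windows: int = 6,
    mass_region: tuple[float, float] = (350.0, 400.0),
    width: float = 0.4,
) -> list[IsolationWindow]:
    """Pick nominal masses for fragmentation experiments.

    Candidates are nominal masses in the region carrying formulas common
    to all samples; they are ranked by summed common-formula intensity
    (ties to the lower nominal mass), then greedily reordered so that
    unrepresented compound classes and CH2 series gain priority — the
    selection should span the molecular diversity of the mixture, not
    one homologous series.
    """
    if k_windows == 0:
        return []
    lo, hi = mass_region
    common, _ = common_formulae(
        {s: [a.formula for a in asn if not a.is_isotopologue]
         for s, asn in assigned_by_sample.items()},
        allow_single=True,
    )
    per_nominal: dict[int, dict] = {}
    for s, asn in assigned_by_sample.items():
        for a in asn:
            if a.is_isotopologue or a.formula not in common:
                continue
            if not (lo <= a.peak.mz <= hi):
                continue
            nom = int(round(a.peak.mz))
            rec = per_nominal.setdefault(
                nom, {"intensity": 0.0, "classes": set(), "series": set(), "mz": []}
            )
            rec["intensity"] += a.peak.intensity
            rec["mz"].append(a.peak.mz)
            rec["classes"].add(a.compound_class)
            # CH2-series identity: fixed (o, DBE-equivalent h-2c) signature
            rec["series"].add((a.formula.o, a.formula.h - 2 * a.formula.c))
    if not per_nominal:
        raise ValueError(f"no common formulas with peaks in region {mass_region}")
    ranked = sorted(per_nominal, key=lambda n: (-per_nominal[n]["intensity"], n))
    chosen: list[int] = []
    seen_classes: set = set()
    seen_series: set = set()
    for nom in ranked:
        if len(chosen) >= k_windows:
            break
        rec = per_nominal[nom]
        adds_new = (rec["classes"] - seen_classes) or (rec["series"] - seen_series)
        if adds_new or len(ranked) - ranked.index(nom) <= k_windows - len(chosen):
            chosen.append(nom)
            seen_classes |= rec["classes"]
            seen_series |= rec["series"]
    for nom in ranked:  # fill up by rank if coverage pass left slots
        if len(chosen) >= k_windows:
            break
        if nom not in chosen:
            chosen.append(nom)
    # centre each window on its ion cluster, not the integer nominal mass
    return [
        IsolationWindow(center=float(np.mean(per_nominal[n]["mz"])), width=width)
        for n in sorted(chosen)
    ]


def _assignment_stage(
    fullrange: Mapping[str, PeakList], settings: PipelineSettings, report: RunReport
) -> dict[str, list[AssignedPeak]]:
    assigned_by_sample: dict[str, list[AssignedPeak]] = {}
    for s, pl in fullrange.items():
        filtered = snr_filter(pl, settings.min_snr)
        if settings.calibration_refs:
            try:
                filtered, calib = internal_calibrate(
                    filtered, settings.calibration_refs, max_ppm=settings.max_ppm
                )
                if not calib.passed:
                    msg = (
                        f"{s}: calibration residual {calib.max_abs_ppm:.4f} ppm "
                        f"exceeds {settings.max_ppm}"
                    )
                    if settings.abort_on_calibration_failure:
                        raise CalibrationError(msg)
                    report.notices.append(msg)
            except CalibrationError:
                if settings.abort_on_calibration_failure:
                    raise
                report.notices.append(f"{s}: calibration failed; using raw m/z")
        asn = assign(filtered, settings.constraints)
        asn = verify_isotopologues(
            asn, filtered, tol_ppm=settings.constraints.tolerance_ppm
        )
        n_iso = sum(a.is_isotopologue for a in asn)
        report.assignment_counts[s] = {
            "peaks_after_snr": len(filtered),
            "assigned": len(asn) - n_iso,
            "isotopologues": n_iso,
            "unassigned": len(filtered) - len(asn),
        }
        assigned_by_sample[s] = asn
    return assigned_by_sample


def _fragment_stage(
    frag_scans: Mapping[tuple[str, float], PeakList],
    assigned_by_sample: Mapping[str, Sequence[AssignedPeak]],
    common: set[ElementalFormula],
    settings: PipelineSettings,
    report: RunReport,
) -> dict[str, dict[ElementalFormula, FragmentProfile]]:
    """Attribute fragments window by window and build censored profiles."""
    samples = sorted(assigned_by_sample)
    centers = sorted({c for (_, c) in frag_scans})
    report.windows = centers
    peak_by_formula = {
        s: {
            a.formula: a.peak
            for a in assigned_by_sample[s]
            if not a.is_isotopologue
        }
        for s in samples
    }
    profiles: dict[str, dict[ElementalFormula, FragmentProfile]] = {
        s: {} for s in samples
    }
    for center in centers:
        window = IsolationWindow(center=center, width=settings.window_width)
        # precursor list: every assigned formula in the window, any sample
        precursors = sorted(
            {
                f
                for s in samples
                for f in peak_by_formula[s]
                if window.contains(ion_mass(f))
            },
            key=ion_mass,
        )
        if not precursors:
            report.notices.append(f"window {center}: no assigned precursors; skipped")
            continue
        for s in samples:
            pl = frag_scans.get((s, center))
            if pl is None:
                report.notices.append(f"window {center}: no scan for {s}")
                continue
            pl = snr_filter(pl, settings.min_snr)
            try:
                pl, _ = calibrate_fragment_spectrum(
                    pl, precursors, match_tol_ppm=settings.attr_tol_ppm
                )
            except CalibrationError as exc:
                report.notices.append(f"window {center} / {s}: {exc}; using raw m/z")
            records, unattributed = attribute_fragments(
                pl, precursors, tol_ppm=settings.attr_tol_ppm
            )
            if unattributed:
                logger.info(
                    "window %s / %s: %d unattributed fragment peaks",
                    center, s, len(unattributed),
                )
            for f in precursors:
                peak = peak_by_formula[s].get(f)
                if peak is None:
                    continue
                pmz = ion_mass(f)
                hit = [
                    p for p in pl.peaks
                    if abs(p.mz - pmz) / pmz * 1e6 <= settings.attr_tol_ppm
                ]
                if not hit:
                    continue
                prec_peak = max(hit, key=lambda p: p.intensity)
                profiles[s][f] = relative_intensities(
                    records, f, prec_peak.intensity, precursor_snr=prec_peak.snr
                )
    # symmetric censoring, per precursor detected in all samples
    fragmented_common = [
        f
        for f in sorted(common, key=ion_mass)
        if all(f in profiles[s] for s in samples)
    ]
    dropped = {
        f for s in samples for f in profiles[s] if f not in fragmented_common
    }
    if dropped:
        report.notices.append(
            f"{len(dropped)} fragmented formulas missing in >=1 sample; "
            "excluded from comparison"
        )
    censored: dict[str, dict[ElementalFormula, FragmentProfile]] = {
        s: {} for s in samples
    }
    for f in fragmented_common:
        by_sample = {s: profiles[s][f] for s in samples}
        by_sample = apply_common_detection_limit(
            by_sample, noise_units=settings.noise_units
        )
        for s in samples:
            censored[s][f] = by_sample[s]
    return censored


def _diversity_stage(
    profiles: Mapping[str, Mapping[ElementalFormula, FragmentProfile]],
    n_common: int,
    settings: PipelineSettings,
    report: RunReport,
) -> None:
    for s in sorted(profiles):
        formulas = sorted(profiles[s], key=ion_mass)
        if len(formulas) < 10:
            report.notices.append(
                f"{s}: only {len(formulas)} fragmented formulas; diversity skipped"
            )
            continue
        c_frag = [carboxyl_from_fragments(profiles[s][f]) for f in formulas]
        model = settings.carboxyl_model
        if model is None:
            model = fit_carboxyl_model(formulas, c_frag)
            model.source = f"self-calibrated on {len(formulas)} fragmented formulas"
        estimates = [
            CarboxylEstimates(f, cf, max(0.0, model.predict(f)))
            for f, cf in zip(formulas, c_frag)
        ]
        try:
            r = diversity_index(estimates)
        except ValueError as exc:
            report.notices.append(f"{s}: diversity index unavailable ({exc})")
            continue
        if settings.sigma_single is None:
            report.notices.append(
                f"{s}: sigma_single not supplied; minimum isomer number omitted"
            )
            report.diversity[s] = DiversityEstimate(
                sample_id=s, r_estimates=r, n_min_isomers=1,
                n_min_compounds=n_common if n_common else 1, model=model,
            )
            continue
        n_min, sigma_resid = min_isomers(estimates, settings.sigma_single)
        report.diversity[s] = DiversityEstimate(
            sample_id=s,
            r_estimates=r,
            n_min_isomers=n_min,
            n_min_compounds=min_compounds(n_min, max(1, n_common)),
            sigma_single=settings.sigma_single,
            sigma_residual=sigma_resid,
            model=model,
        )


def run_arrays(
    fullrange: Mapping[str, PeakList],
    frag_scans: Mapping[tuple[str, float], PeakList] | None = None,
    settings: PipelineSettings | None = None,
) -> RunReport:
    """Run the complete analysis on in-memory peak lists.

    ``frag_scans`` maps (sample_id, window center) to fragmentation
    scans; when omitted, fragment-level statistics and diversity are
    skipped with notices.  Re-running with identical inputs reproduces
    the report bit-for-bit.
    """
    settings = settings or PipelineSettings()
    report = RunReport(
        settings_echo={
            "min_snr": settings.min_snr,
            "tolerance_ppm": settings.constraints.tolerance_ppm,
            "attr_tol_ppm": settings.attr_tol_ppm,
            "ion_convention": (
                "[M-H]- = M - 1.00782503207 + m_e"
                if settings.constraints.electron_correction
                else "[M-H]- = M - 1.00727646688"
            ),
            "renormalize_common": settings.renormalize_common,
        },
        version=__version__,
    )
    assigned_by_sample = _assignment_stage(fullrange, settings, report)
    samples = sorted(assigned_by_sample)

    formula_intensity: dict[str, dict[str, float]] = {}
    for s in samples:
        formula_intensity[s] = {
            a.formula.hill(): a.peak.intensity
            for a in assigned_by_sample[s]
            if not a.is_isotopologue
        }

    if len(samples) < 2:
        report.notices.append(
            "single sample: intersection, regression and dissimilarity skipped"
        )
        return report

    common, shares = common_formulae(
        {
            s: [a.formula for a in asn if not a.is_isotopologue]
            for s, asn in assigned_by_sample.items()
        }
    )
    report.n_common = len(common)
    report.common_shares = {s: round(v, 4) for s, v in shares.items()}

    fragment_vectors: dict[str, dict] = {}
    if frag_scans:
        profiles = _fragment_stage(
            frag_scans, assigned_by_sample, common, settings, report
        )
        for s in samples:
            vec = {}
            for f, prof in profiles[s].items():
                for lbl, v in prof.rel.items():
                    vec[(f.hill(), lbl)] = v
            fragment_vectors[s] = vec
        rows = []
        for i, a in enumerate(samples):
            for b in samples[i + 1:]:
                keys = sorted(set(fragment_vectors[a]) & set(fragment_vectors[b]))
                if len(keys) < 3:
                    report.notices.append(
                        f"{a}/{b}: <3 shared fragments; regression skipped"
                    )
                    continue
                res = paired_regression(
                    {k: fragment_vectors[a][k] for k in keys},
                    {k: fragment_vectors[b][k] for k in keys},
                )
                rows.append(
                    {
                        "sample_a": a,
                        "sample_b": b,
                        "slope": res.slope,
                        "intercept": res.intercept,
                        "r": res.r,
                        "p_value": res.p_value,
                        "n": res.n,
                        "delta_sl": res.delta_sl,
                        "excluded_outliers": ";".join(map(str, res.excluded_outliers)),
                    }
                )
        report.regressions = pd.DataFrame(rows)
        report.dissimilarity = dissimilarity_levels(
            formula_intensity,
            fragment_vectors,
            renormalize_common=settings.renormalize_common,
        )
        _diversity_stage(profiles, report.n_common, settings, report)
    else:
        report.notices.append("no fragmentation scans: fragment statistics omitted")
        report.dissimilarity = dissimilarity_levels(
            formula_intensity, None, renormalize_common=settings.renormalize_common
        )
    return report


def write_report(report: RunReport, outdir: str | Path) -> Path:
    """Serialize the report (JSON + regression/dissimilarity TSVs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json())
    if report.regressions is not None and len(report.regressions):
        report.regressions.to_csv(outdir / "regressions.tsv", sep="\t", index=False)
    long_rows = [m.to_long() for m in report.dissimilarity.values()]
    if long_rows:
        pd.concat(long_rows, ignore_index=True).to_csv(
            outdir / "dissimilarity.tsv", sep="\t", index=False
        )
    return outdir / "report.json"
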