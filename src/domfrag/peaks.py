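"""Peak-list containers, TSV I/O, S/N filtering and internal mass calibration.

A centroided FT-ICR-MS scan is represented as a :class:`PeakList` — an
ordered collection of (m/z, intensity, S/N) triples with sample metadata.
Peak lists travel as tab-separated text with a commented header carrying
the ion-mass convention and calibration summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Peak",
    "PeakList",
    "CalibrationResult",
    "CalibrationError",
    "PeakListParseError",
    "read_peaklist",
    "write_peaklist",
    "snr_filter",
    "internal_calibrate",
    "normalize_intensities",
]

DEFAULT_MAX_PPM = 0.06  # post-calibration residual limit
DEFAULT_MATCH_TOL_PPM = 1.0  # reference-match window before calibration


def default_reference_masses(n_min: int = 0, n_max: int = 25) -> list[float]:
    """[M−H]⁻ masses of a CH2-homologous series of CRAM-like formulas.

    C(14+n)H(18+2n)O8 for n in [n_min, n_max] — oxygen-rich, highly
    unsaturated compositions ubiquitous in solid-phase-extracted DOM,
    usable as a fallback internal-calibration list.  Real instruments
    should supply their own curated list.
    """
    from .chem import ElementalFormula, ion_mass

    return [
        ion_mass(ElementalFormula(c=14 + n, h=18 + 2 * n, o=8))
        for n in range(n_min, n_max + 1)
    ]


class PeakListParseError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Peak:
    """One detected ion: measured m/z (Da), intensity (detector units), S/N."""

    mz: float
    intensity: float
    snr: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")
        if self.snr < 0:
            raise ValueError(f"snr must be >= 0, got {self.snr}")


@dataclass
class PeakList:
    """A scan-level peak collection, strictly ascending in m/z."""

    sample_id: str
    peaks: list[Peak] = field(default_factory=list)
    scan_type: str = "full_range"  # full_range | isolation | fragmentation
    isolation_center: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scan_type not in ("full_range", "isolation", "fragmentation"):
            raise ValueError(f"unknown scan_type {self.scan_type!r}")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        mz = self.mz
        if len(mz) > 1 and np.min(np.diff(mz)) < 1e-6:
            i = int(np.argmin(np.diff(mz)))
            raise ValueError(
                f"duplicate m/z within 1e-6 Da at index {i}: {mz[i]:.7f} / {mz[i + 1]:.7f}"
            )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    @property
    def snr(self) -> np.ndarray:
        return np.array([p.snr for p in self.peaks])


@dataclass
class CalibrationResult:
    """Fitted m/z correction and its residual quality.

    The correction model is linear on the ppm scale:
    measured = true * (1 + (a + b*true)/1e6), so ``a`` is a constant ppm
    offset and ``b`` a ppm-per-Da slope (zero when ``order=0``).
    """

    offset_ppm: float
    slope_ppm_per_da: float
    residual_ppm: dict[float, float]  # reference mass -> residual ppm after correction
    max_abs_ppm: float
    passed: bool
    max_ppm_threshold: float = DEFAULT_MAX_PPM
    n_matched: int = 0

    def correct(self, mz: np.ndarray) -> np.ndarray:
        """Invert the fitted distortion on measured m/z values."""
        mz = np.asarray(mz, dtype=float)
        # measured = true*(1 + (a + b*true)/1e6); to first order in ppm the
        # inverse uses the measured mass in place of the true mass.
        return mz / (1.0 + (self.offset_ppm + self.slope_ppm_per_da * mz) / 1e6)

    def to_json(self) -> str:
        return json.dumps(
            {
                "offset_ppm": self.offset_ppm,
                "slope_ppm_per_da": self.slope_ppm_per_da,
                "max_abs_ppm": self.max_abs_ppm,
                "passed": self.passed,
                "max_ppm_threshold": self.max_ppm_threshold,
                "n_matched": self.n_matched,
                "residual_ppm": {f"{k:.6f}": v for k, v in self.residual_ppm.items()},
            },
            indent=2,
        )


_COLUMNS = ("mz", "intensity", "snr")


def read_peaklist(path: str | Path, sample_id: str | None = None) -> PeakList:
    """Read a tab-separated peak list (columns mz, intensity, snr).

    Comment lines start with ``#``; the first non-comment line must be the
    header.  Malformed rows raise :class:`PeakListParseError` naming the
    line number.
    """
    path = Path(path)
    metadata: dict = {}
    peaks: list[Peak] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("# ").partition("=")
                    metadata[key.strip()] = val.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = [c.strip().lower() for c in fields]
                missing = [c for c in _COLUMNS if c not in header]
                if missing:
                    raise PeakListParseError(
                        f"{path}:{lineno}: missing column(s) {missing}; got {header}"
                    )
                continue
            row = dict(zip(header, fields))
            try:
                peak = Peak(
                    mz=float(row["mz"]),
                    intensity=float(row["intensity"]),
                    snr=float(row["snr"]),
                )
            except (KeyError, ValueError) as exc:
                raise PeakListParseError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(peak)
    if header is None:
        raise PeakListParseError(f"{path}: no header line found")
    sid = sample_id or metadata.get("sample_id", path.stem)
    scan_type = metadata.get("scan_type", "full_range")
    center = metadata.get("isolation_center")
    try:
        return PeakList(
            sample_id=sid,
            peaks=peaks,
            scan_type=scan_type,
            isolation_center=float(center) if center is not None else None,
            metadata=metadata,
        )
    except ValueError as exc:
        raise PeakListParseError(f"{path}: {exc}") from exc


def write_peaklist(
    pl: PeakList,
    path: str | Path,
    calibration: CalibrationResult | None = None,
    ion_convention: str = "[M-H]- = M - 1.00727646688",
) -> None:
    """Write a peak list as TSV with a commented metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_id = {pl.sample_id}\n")
        fh.write(f"# scan_type = {pl.scan_type}\n")
        if pl.isolation_center is not None:
            fh.write(f"# isolation_center = {pl.isolation_center:.4f}\n")
        fh.write(f"# ion_convention = {ion_convention}\n")
        if calibration is not None:
            fh.write(
                f"# calibration = offset {calibration.offset_ppm:+.4f} ppm, "
                f"slope {calibration.slope_ppm_per_da:+.3e} ppm/Da, "
                f"max |residual| {calibration.max_abs_ppm:.4f} ppm\n"
            )
        for key, val in pl.metadata.items():
            if key in ("sample_id", "scan_type", "isolation_center"):
                continue
            fh.write(f"# {key} = {val}\n")
        fh.write("mz\tintensity\tsnr\n")
        for p in pl.peaks:
            fh.write(f"{p.mz:.7f}\t{p.intensity:.7g}\t{p.snr:.7g}\n")


def snr_filter(pl: PeakList, min_snr: float = 5.0) -> PeakList:
    """Keep peaks with S/N >= ``min_snr`` (inclusive); order preserved."""
    kept = [p for p in pl.peaks if p.snr >= min_snr]
    return replace(pl, peaks=kept)


def _match_references(
    mz: np.ndarray, references: np.ndarray, tol_ppm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-peak match for each reference mass within ``tol_ppm``."""
    matched_meas, matched_ref = [], []
    for ref in references:
        if len(mz) == 0:
            break
        i = int(np.argmin(np.abs(mz - ref)))
        if abs(mz[i] - ref) / ref * 1e6 <= tol_ppm:
            matched_meas.append(mz[i])
            matched_ref.append(ref)
    return np.array(matched_meas), np.array(matched_ref)


def internal_calibrate(
    pl: PeakList,
    reference_masses: Sequence[float] | Iterable[float],
    match_tol_ppm: float = DEFAULT_MATCH_TOL_PPM,
    max_ppm: float = DEFAULT_MAX_PPM,
    order: int = 1,
) -> tuple[PeakList, CalibrationResult]:
    """Internally calibrate a spectrum against a reference mass list.

    A systematic ppm error, linear in m/z (``order=1``; ``order=0`` fits a
    constant offset only), is least-squares fitted to the matched
    references and inverted on every peak.  Requires >= 3 matched
    references (>= 2 for ``order=0``); the result is flagged ``passed``
    when the residual max |ppm| stays within ``max_ppm``.
    """
    if order not in (0, 1):
        raise ValueError("calibration order must be 0 or 1")
    refs = np.sort(np.asarray(list(reference_masses), dtype=float))
    meas, ref = _match_references(pl.mz, refs, match_tol_ppm)
    min_needed = 3 if order == 1 else 2
    if len(meas) < min_needed:
        raise CalibrationError(
            f"only {len(meas)} reference masses matched within {match_tol_ppm} ppm "
            f"(need >= {min_needed})"
        )
    err_ppm = (meas - ref) / ref * 1e6
    if order == 1:
        design = np.column_stack([np.ones_like(ref), ref])
    else:
        design = np.ones((len(ref), 1))
    coef, *_ = np.linalg.lstsq(design, err_ppm, rcond=None)
    if not np.all(np.isfinite(coef)):
        raise CalibrationError("calibration fit diverged")
    a = float(coef[0])
    b = float(coef[1]) if order == 1 else 0.0

    result = CalibrationResult(
        offset_ppm=a,
        slope_ppm_per_da=b,
        residual_ppm={},
        max_abs_ppm=0.0,
        passed=False,
        max_ppm_threshold=max_ppm,
        n_matched=len(meas),
    )
    corrected_refs = result.correct(meas)
    residual = (corrected_refs - ref) / ref * 1e6
    result.residual_ppm = {float(r): float(e) for r, e in zip(ref, residual)}
    result.max_abs_ppm = float(np.max(np.abs(residual)))
    result.passed = result.max_abs_ppm <= max_ppm

    new_mz = result.correct(pl.mz)
    new_peaks = [
        Peak(mz=float(m), intensity=p.intensity, snr=p.snr)
        for m, p in zip(new_mz, pl.peaks)
    ]
    corrected = replace(pl, peaks=new_peaks)
    corrected.metadata = dict(pl.metadata, calibrated="true")
    return corrected, result


def normalize_intensities(
    pl: PeakList, subset: Sequence[int] | None = None
) -> np.ndarray:
    """Relative intensities of ``subset`` peaks (indices into ``pl``).

    Each value is intensity / sum of subset intensities; the result sums
    to 1.  With ``subset=None`` all peaks are used.
    """
    idx = np.arange(len(pl)) if subset is None else np.asarray(list(subset), dtype=int)
    if idx.size == 0:
        raise ValueError("cannot normalize an empty subset")
    inten = pl.intensity[idx]
    total = float(inten.sum())
    if total <= 0:
        raise ValueError("total intensity of subset is zero")
    return inten / total
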