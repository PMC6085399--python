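"""Cross-sample comparison statistics.

Two complementary views of molecular universality:

* paired linear regression of relative fragment intensities between two
  samples — a slope of 1 is expected when the samples contain identical
  compounds; the deviation Δsl = |1 − slope| quantifies structural
  difference;
* Bray–Curtis compositional dissimilarity at three levels: all assigned
  formulas, the common-formula intersection, and fragment intensities of
  fragmented common formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "RegressionResult",
    "DissimilarityMatrix",
    "paired_regression",
    "bray_curtis",
    "dissimilarity_levels",
    "replicate_variability",
]

OUTLIER_STUDENTIZED_THRESHOLD = 4.0


@dataclass
class RegressionResult:
    """OLS fit of relative fragment intensities of sample B on sample A."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int
    delta_sl: float
    excluded_outliers: list[Hashable] = field(default_factory=list)
    raw_slope: float = float("nan")
    raw_delta_sl: float = float("nan")


def paired_regression(
    rel_a: Mapping[Hashable, float] | pd.Series,
    rel_b: Mapping[Hashable, float] | pd.Series,
    outlier_threshold: float = OUTLIER_STUDENTIZED_THRESHOLD,
) -> RegressionResult:
    """Regress sample B's relative fragment intensities on sample A's.

    Both inputs must be keyed by the same fragment identifiers (fragments
    of common molecular formulas).  The first sample is the abscissa.  At
    most one outlier — the point with the largest externally studentized
    residual, if it exceeds ``outlier_threshold`` — is excluded and the
    fit repeated; both the raw and the screened fit are reported.
    """
    a = pd.Series(dict(rel_a), dtype=float).sort_index()
    b = pd.Series(dict(rel_b), dtype=float).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("fragment keys differ between the two samples")
    if len(a) < 3:
        raise ValueError(f"need >= 3 fragment pairs, got {len(a)}")
    if np.ptp(a.values) == 0:
        raise ValueError("degenerate regression: all abscissa values equal")

    def _fit(x: pd.Series, y: pd.Series):
        model = sm.OLS(y.values, sm.add_constant(x.values)).fit()
        slope = float(model.params[1])
        intercept = float(model.params[0])
        r, p = scipy.stats.pearsonr(x.values, y.values)
        return model, slope, intercept, float(r), float(p)

    model, slope, intercept, r, p = _fit(a, b)
    raw_slope, raw_delta = slope, abs(1.0 - slope)

    excluded: list[Hashable] = []
    # a (numerically) perfect fit has no outliers to screen
    if len(a) > 3 and model.ssr > 1e-12 * float(np.sum(np.square(b.values))):
        with np.errstate(divide="ignore", invalid="ignore"):
            student = np.nan_to_num(
                OLSInfluence(model).resid_studentized_external
            )
        worst = int(np.argmax(np.abs(student)))
        if abs(student[worst]) > outlier_threshold:
            excluded = [a.index[worst]]
            keep = a.index.delete(worst)
            a2, b2 = a.loc[keep], b.loc[keep]
            if np.ptp(a2.values) > 0:
                model, slope, intercept, r, p = _fit(a2, b2)

    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r=r,
        p_value=p,
        n=len(a) - len(excluded),
        delta_sl=abs(1.0 - slope),
        excluded_outliers=excluded,
        raw_slope=raw_slope,
        raw_delta_sl=raw_delta,
    )


def bray_curtis(x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray) -> float:
    """Bray–Curtis dissimilarity Σ|x−y| / Σ(x+y) on aligned vectors.

    Inputs are non-negative composition vectors over a shared key set
    (keys absent in one sample enter as 0).  0 means identical, 1 means
    disjoint support.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must be aligned over the same key set")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("Bray-Curtis requires non-negative intensities")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.sum(np.abs(x - y)) / denom)


@dataclass
class DissimilarityMatrix:
    """Symmetric Bray–Curtis matrix for one compositional level."""

    level: str  # all_formulae | common_formulae | fragments
    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if not np.allclose(d.values, d.values.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(d.values), 0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")

    def value(self, a: str, b: str) -> float:
        return float(self.data.loc[a, b])

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"sample_a": a, "sample_b": b, "level": self.level, "value": self.value(a, b)}
            for a, b in combinations(self.data.index, 2)
        ]
        return pd.DataFrame(rows)


def _bc_matrix(vectors: Mapping[str, Mapping[Hashable, float]], level: str) -> DissimilarityMatrix:
    labels = sorted(vectors)
    keys = sorted({k for v in vectors.values() for k in v})
    mat = pd.DataFrame(
        {lbl: [vectors[lbl].get(k, 0.0) for k in keys] for lbl in labels},
        index=pd.Index(keys),
    )
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        v = bray_curtis(mat[a].values, mat[b].values)
        out.loc[a, b] = out.loc[b, a] = v
    return DissimilarityMatrix(level=level, data=out)


def _normalize(d: Mapping[Hashable, float]) -> dict[Hashable, float]:
    total = float(sum(d.values()))
    if total <= 0:
        raise ValueError("cannot normalize an all-zero intensity vector")
    return {k: v / total for k, v in d.items()}


def dissimilarity_levels(
    formula_intensities: Mapping[str, Mapping[Hashable, float]],
    fragment_intensities: Mapping[str, Mapping[Hashable, float]] | None = None,
    renormalize_common: bool = True,
) -> dict[str, DissimilarityMatrix]:
    """Bray–Curtis matrices at up to three compositional levels.

    * ``all_formulae`` — normalized intensities of all assigned formulas;
    * ``common_formulae`` — restricted to formulas present in every
      sample and (by default) renormalized over that subset;
    * ``fragments`` — normalized relative fragment intensities of
      fragmented common formulas (omitted with a warning when no
      fragmentation data are given).
    """
    if len(formula_intensities) < 2:
        raise ValueError("need >= 2 samples")
    level1 = {k: _normalize(v) for k, v in formula_intensities.items()}
    out = {"all_formulae": _bc_matrix(level1, "all_formulae")}

    common: set[Hashable] | None = None
    for v in formula_intensities.values():
        keys = {k for k, val in v.items() if val > 0}
        common = keys if common is None else common & keys
    if not common:
        raise ValueError("no common formulas across samples; level 2 undefined")
    level2 = {}
    for k, v in formula_intensities.items():
        sub = {key: v[key] for key in common}
        level2[k] = _normalize(sub) if renormalize_common else {
            key: level1[k][key] for key in common
        }
    out["common_formulae"] = _bc_matrix(level2, "common_formulae")

    if fragment_intensities is not None:
        level3 = {k: _normalize(v) for k, v in fragment_intensities.items()}
        out["fragments"] = _bc_matrix(level3, "fragments")
    else:
        import logging

        logging.getLogger(__name__).warning(
            "no fragmentation data: fragments-level dissimilarity omitted"
        )
    return out


def replicate_variability(
    rep_a: Mapping[Hashable, float],
    rep_b: Mapping[Hashable, float],
) -> float:
    """Fragment-level Bray–Curtis between two runs of the same sample.

    This is the analytical noise floor against which between-sample
    fragment dissimilarities are interpreted.
    """
    keys = sorted(set(rep_a) | set(rep_b))
    x = np.array([rep_a.get(k, 0.0) for k in keys])
    y = np.array([rep_b.get(k, 0.0) for k in keys])
    return bray_curtis(x, y)
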