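"""Age/sex normalization of region features against a healthy reference.

Two schemes, both fitted on healthy-control scans only (per sex, so male
and female thinning trajectories are modeled separately); patient scans
are only ever corrected, never used for fitting.

Proportional: per sex, ordinary least squares of whole-brain mean
thickness on age, Cth = a*age + b. A scan's features are rescaled to the
reference age of 20 years through the scalar

    Cth20 = a*20 + Cth - a*age,    alpha = Cth20 / Cth,

applied as x_i' = (alpha*mu_i, alpha*sigma_i, gamma_i, k_i): the unitless
shape moments are left untouched.

Residual: per sex, per region and per statistic (mu, sigma, gamma, k), OLS
of the statistic on age; the corrected feature is the residual of the
healthy model, r = predicted - observed (sign convention kept as such;
``flip_sign`` gives the conventional observed - predicted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import ScanRecord
from .features import (
    FEATURE_COLUMNS,
    FeatureMatrix,
    Parcellation,
    build_feature_matrix,
    whole_brain_mean_thickness,
)

__all__ = [
    "ProportionalModel",
    "ResidualModel",
    "AdjustedFeatureMatrix",
    "fit_proportional",
    "apply_proportional",
    "fit_residual",
    "apply_residual",
    "REFERENCE_AGE",
]

REFERENCE_AGE = 20.0
SEXES = ("F", "M")


@dataclass(frozen=True)
class AdjustedFeatureMatrix:
    """Feature matrix after age/sex correction."""

    values: np.ndarray
    parcellation: Parcellation
    scan_id: str
    mode: str  # none | proportional | residual
    provenance: str = ""

    @property
    def n_regions(self) -> int:
        return self.parcellation.n_regions


def _check_healthy_per_sex(scans: Sequence[ScanRecord], min_per_sex: int):
    ages = {s: [] for s in SEXES}
    for scan in scans:
        if scan.label != "HC":
            raise ValueError(
                f"normalization models are fitted on HC scans only; got "
                f"label {scan.label!r} for {scan.scan_id}"
            )
        ages[scan.sex].append(scan.age_years)
    for sex in SEXES:
        if len(ages[sex]) < min_per_sex:
            raise ValueError(
                f"need >= {min_per_sex} healthy scans of sex {sex}, "
                f"got {len(ages[sex])}"
            )
        if np.var(ages[sex]) == 0:
            raise ValueError(f"age is constant among sex-{sex} healthy scans")
    return ages


@dataclass(frozen=True)
class ProportionalModel:
    """Per-sex linear age model of whole-brain mean thickness,
    Cth = a*age + b (a in mm/year, b in mm)."""

    coefficients: Mapping[str, tuple]  # sex -> (a, b)
    n_fit: Mapping[str, int] = field(default_factory=dict)

    def slope_intercept(self, sex: str) -> tuple:
        try:
            return self.coefficients[sex]
        except KeyError:
            raise ValueError(f"model has no coefficients for sex {sex!r}") from None

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": "proportional",
                "coefficients": {s: list(c) for s, c in self.coefficients.items()},
                "n_fit": dict(self.n_fit),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ProportionalModel":
        d = json.loads(text)
        if d.get("mode") != "proportional":
            raise ValueError("not a proportional model file")
        return cls(
            coefficients={s: tuple(c) for s, c in d["coefficients"].items()},
            n_fit={s: int(n) for s, n in d.get("n_fit", {}).items()},
        )


def fit_proportional(
    healthy_scans: Sequence[ScanRecord], min_per_sex: int = 10
) -> ProportionalModel:
    """Per-sex OLS of whole-brain mean thickness on age, on HC scans."""
    _check_healthy_per_sex(healthy_scans, min_per_sex)
    coef, n_fit = {}, {}
    for sex in SEXES:
        sub = [s for s in healthy_scans if s.sex == sex]
        age = np.array([s.age_years for s in sub])
        cth = np.array([whole_brain_mean_thickness(s) for s in sub])
        A = np.column_stack([age, np.ones_like(age)])
        (a, b), *_ = np.linalg.lstsq(A, cth, rcond=None)
        coef[sex] = (float(a), float(b))
        n_fit[sex] = len(sub)
    return ProportionalModel(coefficients=coef, n_fit=n_fit)


def apply_proportional(
    X: FeatureMatrix,
    scan: ScanRecord,
    model: ProportionalModel,
    reference_age: float = REFERENCE_AGE,
) -> AdjustedFeatureMatrix:
    """Rescale mu and sigma to the reference age; gamma and k pass through."""
    if scan.age_years is None or not np.isfinite(scan.age_years):
        raise ValueError(f"scan {scan.scan_id} has no age")
    a, _b = model.slope_intercept(scan.sex)
    cth = whole_brain_mean_thickness(scan)
    if cth <= 0:
        raise ValueError(f"scan {scan.scan_id}: non-positive Cth {cth}")
    cth_ref = a * reference_age + cth - a * scan.age_years
    alpha = cth_ref / cth
    values = X.values.copy()
    values[:, 0] *= alpha
    values[:, 1] *= alpha
    return AdjustedFeatureMatrix(
        values=values, parcellation=X.parcellation, scan_id=X.scan_id,
        mode="proportional", provenance=f"alpha={alpha:.6g}",
    )


@dataclass(frozen=True)
class ResidualModel:
    """Per sex, per region, per statistic linear age coefficients.

    ``slopes`` and ``intercepts`` map sex -> (N, 4) arrays ordered like the
    parcellation's regions and the (mu, sigma, gamma, k) columns — 2*N*4
    coefficient pairs in total.
    """

    slopes: Mapping[str, np.ndarray]
    intercepts: Mapping[str, np.ndarray]
    parcellation: Parcellation
    n_fit: Mapping[str, int] = field(default_factory=dict)

    @property
    def n_coefficient_pairs(self) -> int:
        return sum(v.size for v in self.slopes.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": "residual",
                "atlas": self.parcellation.name,
                "n_regions": self.parcellation.n_regions,
                "region_ids": list(self.parcellation.region_ids),
                "statistics": list(FEATURE_COLUMNS),
                "slopes": {s: v.tolist() for s, v in self.slopes.items()},
                "intercepts": {s: v.tolist() for s, v in self.intercepts.items()},
                "n_fit": dict(self.n_fit),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ResidualModel":
        d = json.loads(text)
        if d.get("mode") != "residual":
            raise ValueError("not a residual model file")
        parc = Parcellation(
            name=d.get("atlas", "custom"), n_regions=int(d["n_regions"]),
            region_ids=tuple(d["region_ids"]),
        )
        return cls(
            slopes={s: np.asarray(v) for s, v in d["slopes"].items()},
            intercepts={s: np.asarray(v) for s, v in d["intercepts"].items()},
            parcellation=parc,
            n_fit={s: int(n) for s, n in d.get("n_fit", {}).items()},
        )


def fit_residual(
    healthy_scans: Sequence[ScanRecord],
    parc: Parcellation,
    features: Optional[Sequence[FeatureMatrix]] = None,
    min_per_sex: int = 10,
) -> ResidualModel:
    """Per sex x region x statistic OLS of the statistic on age (HC only).

    ``features`` may carry precomputed feature matrices aligned with
    ``healthy_scans``; otherwise they are computed from vertex data.
    """
    _check_healthy_per_sex(healthy_scans, min_per_sex)
    if features is None:
        features = [build_feature_matrix(s, parc) for s in healthy_scans]
    if len(features) != len(healthy_scans):
        raise ValueError("features must align one-to-one with healthy_scans")
    slopes, intercepts, n_fit = {}, {}, {}
    for sex in SEXES:
        idx = [i for i, s in enumerate(healthy_scans) if s.sex == sex]
        age = np.array([healthy_scans[i].age_years for i in idx])
        Y = np.stack([features[i].values for i in idx])  # (n, N, 4)
        n = len(idx)
        A = np.column_stack([age, np.ones(n)])
        coef, *_ = np.linalg.lstsq(A, Y.reshape(n, -1), rcond=None)
        slopes[sex] = coef[0].reshape(parc.n_regions, 4)
        intercepts[sex] = coef[1].reshape(parc.n_regions, 4)
        n_fit[sex] = n
    return ResidualModel(slopes=slopes, intercepts=intercepts,
                         parcellation=parc, n_fit=n_fit)


def apply_residual(
    X: FeatureMatrix,
    scan: ScanRecord,
    model: ResidualModel,
    flip_sign: bool = False,
) -> AdjustedFeatureMatrix:
    """Residual features r_i = predicted - observed under the healthy model
    for the scan's sex and age (``flip_sign`` gives observed - predicted)."""
    if X.parcellation.region_ids != model.parcellation.region_ids:
        raise ValueError(
            f"region mismatch: features have {X.n_regions} regions "
            f"({X.parcellation.name}), model has {model.parcellation.n_regions} "
            f"({model.parcellation.name})"
        )
    if scan.sex not in model.slopes:
        raise ValueError(f"model not fitted for sex {scan.sex!r}")
    predicted = model.slopes[scan.sex] * scan.age_years + model.intercepts[scan.sex]
    r = predicted - X.values
    if flip_sign:
        r = -r
    return AdjustedFeatureMatrix(
        values=r, parcellation=X.parcellation, scan_id=X.scan_id,
        mode="residual", provenance=f"sex={scan.sex},age={scan.age_years:.3f}",
    )
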