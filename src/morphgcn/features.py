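"""Per-region moment features of cortical thickness.

Each cortical region's thickness distribution is summarized by four
moments, x_i = (mu_i, sigma_i, gamma_i, k_i): the mean (mm), the standard
deviation (mm), the skewness and the (non-excess) kurtosis. Stacking the N
region vectors gives the per-scan feature matrix X in R^{N x 4}, whose row
order follows the parcellation and is reused everywhere downstream (graph
node i <-> region_ids[i]).

Moments are population (divide-by-n) moments by default: sigma = sqrt(m2),
gamma = m3 / m2^{3/2}, k = m4 / m2^2, with the convention gamma = k = 0
when m2 = 0 so that X stays finite for distance computations. Sample
(bias-adjusted) estimators are available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import ScanRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Parcellation",
    "RegionFeatureVector",
    "FeatureMatrix",
    "summarize_region",
    "build_feature_matrix",
    "build_feature_matrices",
    "whole_brain_mean_thickness",
    "read_vertex_table",
    "read_region_table",
    "read_aparc_stats",
]

ATLAS_SIZES = {"desikan-killiany": 68, "destrieux": 148, "glasser": 360}

FEATURE_COLUMNS = ("mu", "sigma", "gamma", "k")


@dataclass(frozen=True)
class Parcellation:
    """A fixed ordered partition of the cortex into labeled regions."""

    name: str
    n_regions: int
    region_ids: tuple
    region_names: Optional[tuple] = None

    def __post_init__(self):
        if len(self.region_ids) != self.n_regions:
            raise ValueError("region_ids length must equal n_regions")
        if len(set(self.region_ids)) != self.n_regions:
            raise ValueError("region_ids must be unique")
        if self.name in ATLAS_SIZES and ATLAS_SIZES[self.name] != self.n_regions:
            raise ValueError(
                f"atlas {self.name!r} has {ATLAS_SIZES[self.name]} regions, "
                f"got {self.n_regions}"
            )

    @classmethod
    def from_name(cls, name: str) -> "Parcellation":
        """One of the three named atlases: desikan-killiany (68),
        destrieux (148), glasser (360)."""
        try:
            n = ATLAS_SIZES[name]
        except KeyError:
            raise ValueError(
                f"unknown atlas {name!r}; choose from {sorted(ATLAS_SIZES)}"
            ) from None
        return cls(name=name, n_regions=n, region_ids=tuple(range(1, n + 1)))

    @classmethod
    def custom(cls, n_regions: int, name: str = "custom") -> "Parcellation":
        return cls(name=name, n_regions=n_regions,
                   region_ids=tuple(range(1, n_regions + 1)))


class RegionFeatureVector(NamedTuple):
    mu: float
    sigma: float
    gamma: float
    k: float


def summarize_region(
    values: Sequence[float],
    sample_adjusted: bool = False,
    region: object = None,
) -> RegionFeatureVector:
    """Four-moment summary of one region's thickness values.

    Parameters
    ----------
    values : non-empty sequence of finite positive thickness values (mm).
    sample_adjusted : use unbiased variance and bias-corrected
        skewness/kurtosis instead of plain population moments.
    region : optional region identifier used in error messages.
    """
    v = np.asarray(values, dtype=float)
    where = f" in region {region}" if region is not None else ""
    if v.size == 0:
        raise ValueError(f"empty thickness vector{where}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"non-finite thickness value{where}")
    n = v.size
    mu = float(v.mean())
    d = v - mu
    m2 = float(np.mean(d**2))
    # zero-variance convention, robust to ulp-level rounding of the mean
    if m2 <= (16 * np.finfo(float).eps * max(1.0, abs(mu))) ** 2:
        return RegionFeatureVector(mu, 0.0, 0.0, 0.0)
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    g = m3 / m2**1.5
    k = m4 / m2**2
    if sample_adjusted and n > 3:
        sigma = float(np.sqrt(m2 * n / (n - 1)))
        g = np.sqrt(n * (n - 1)) / (n - 2) * g
        k = (n - 1) / ((n - 2) * (n - 3)) * ((n + 1) * (k - 3.0) + 6.0) + 3.0
    else:
        sigma = float(np.sqrt(m2))
    return RegionFeatureVector(mu, sigma, float(g), float(k))


@dataclass(frozen=True)
class FeatureMatrix:
    """N x 4 per-scan matrix of region moment vectors (rows follow the
    parcellation's region order; columns are mu, sigma, gamma, k)."""

    values: np.ndarray
    parcellation: Parcellation
    scan_id: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape != (self.parcellation.n_regions, 4):
            raise ValueError(
                f"feature matrix must be {self.parcellation.n_regions}x4, "
                f"got {v.shape}"
            )
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.parcellation.n_regions

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(FEATURE_COLUMNS))
        df.insert(0, "region_id", list(self.parcellation.region_ids))
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def build_feature_matrix(
    scan: ScanRecord,
    parc: Parcellation,
    min_vertices: int = 10,
    sample_adjusted: bool = False,
) -> FeatureMatrix:
    """Per-scan feature matrix X from vertex-level thickness.

    Every region of the parcellation must be present with at least
    ``min_vertices`` vertices; otherwise the scan is rejected with an
    informative error (a sparse region makes the 4th moment meaningless,
    and a mu-only fallback would silently change the feature space).
    """
    if scan.vertices is None:
        if isinstance(scan.features, FeatureMatrix):
            return scan.features
        raise ValueError(f"scan {scan.scan_id} has no vertex data")
    df = scan.vertices
    present = df.groupby("region_id")["thickness_mm"]
    groups = {rid: g.to_numpy() for rid, g in present}
    missing = [r for r in parc.region_ids if r not in groups]
    if missing:
        raise ValueError(
            f"scan {scan.scan_id}: missing regions {missing}"
        )
    sparse = [r for r in parc.region_ids if groups[r].size < min_vertices]
    if sparse:
        raise ValueError(
            f"scan {scan.scan_id}: regions {sparse} have fewer than "
            f"{min_vertices} vertices; scan rejected"
        )
    rows = np.empty((parc.n_regions, 4))
    for i, rid in enumerate(parc.region_ids):
        rows[i] = summarize_region(
            groups[rid], sample_adjusted=sample_adjusted, region=rid
        )
    return FeatureMatrix(values=rows, parcellation=parc, scan_id=scan.scan_id)


def build_feature_matrices(
    scans: Sequence[ScanRecord], parc: Parcellation, **kwargs
) -> list:
    return [build_feature_matrix(s, parc, **kwargs) for s in scans]


def whole_brain_mean_thickness(scan: ScanRecord) -> float:
    """Vertex-weighted mean thickness over the whole cortex (mm).

    With vertex data this is the plain mean over all cortical vertices.
    For region-level input the fallback is an unweighted mean of the
    region means (logged), since per-region vertex counts are unknown.
    """
    if scan.vertices is not None:
        return float(scan.vertices["thickness_mm"].mean())
    if isinstance(scan.features, FeatureMatrix):
        logger.warning(
            "scan %s: no vertex data; whole-brain thickness falls back to "
            "the unweighted mean of region means", scan.scan_id,
        )
        return float(scan.features.values[:, 0].mean())
    raise ValueError(f"scan {scan.scan_id} has no thickness data")


# ---------------------------------------------------------------------------
# Readers

def read_vertex_table(path, scan_id=None, **meta) -> ScanRecord:
    """Long-format TSV (vertex_id, region_id, thickness_mm) -> ScanRecord."""
    df = pd.read_csv(path, sep="\t")
    required = {"vertex_id", "region_id", "thickness_mm"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: vertex table must have columns {sorted(required)}"
        )
    meta.setdefault("age_years", float("nan"))
    meta.setdefault("sex", "F")
    meta.setdefault("label", "HC")
    return ScanRecord(
        scan_id=scan_id or Path(path).stem,
        patient_id=meta.pop("patient_id", scan_id or Path(path).stem),
        vertices=df, **meta,
    )


def read_region_table(path, parc: Parcellation, scan_id=None) -> FeatureMatrix:
    """Pre-summarized region TSV (region_id, mu, sigma, gamma, k)."""
    df = pd.read_csv(path, sep="\t")
    required = {"region_id", *FEATURE_COLUMNS}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: region table must have columns {sorted(required)}"
        )
    df = df.set_index("region_id")
    missing = [r for r in parc.region_ids if r not in df.index]
    if missing:
        raise ValueError(f"{path}: missing regions {missing}")
    values = df.loc[list(parc.region_ids), list(FEATURE_COLUMNS)].to_numpy(float)
    return FeatureMatrix(values=values, parcellation=parc,
                         scan_id=scan_id or Path(path).stem)


def read_aparc_stats(path) -> pd.DataFrame:
    """Parse a FreeSurfer ``aparc.stats``-style plain-text table.

    Returns the tabular section as a DataFrame. Note these tables carry
    only mean and SD of thickness (ThickAvg/ThickStd) — they cannot yield
    the skewness/kurtosis features, so they are not convertible to a
    FeatureMatrix without externally supplied higher moments.
    """
    col_names = None
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("# ColHeaders"):
            col_names = line.split()[2:]
        elif line.startswith("#") or not line.strip():
            continue
        else:
            rows.append(line.split())
    if col_names is None:
        raise ValueError(f"{path}: no '# ColHeaders' line found")
    df = pd.DataFrame(rows, columns=col_names)
    for c in df.columns:
        if c != "StructName":
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return df
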