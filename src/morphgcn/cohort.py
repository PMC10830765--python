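"""Synthetic cortical-thickness cohort simulator.

Generates scan cohorts with the statistical structure the downstream
pipeline assumes: healthy age-related cortical thinning with sex-specific
slopes, class-specific regional atrophy for the three MS clinical forms
(relapsing-remitting RR, primary-progressive PP, secondary-progressive SP),
longitudinal repeated scans per patient, and realistic class imbalance.

Thickness is simulated at the vertex level so that the per-region summary
statistics (mean, SD, skewness, kurtosis) are all non-degenerate: vertex
noise is drawn from a centred skew-normal, which puts genuine signal in the
third and fourth moments.

The generative model for one vertex in region ``r`` of a scan is::

    t = baseline[r] + slope[sex] * age + sex_offset[sex]
        - class_effect[label][r] + patient_intercept + scan_shift + noise

truncated below at 0.5 mm to keep thickness physical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "ScanRecord",
    "simulate_cohort",
    "simulate_healthy_reference",
    "default_class_effect",
    "scan_schedule_ages",
    "cohort_to_tables",
    "write_cohort",
    "read_cohort",
]

CLASSES = ("RR", "PP", "SP", "HC")

# Age-at-scan ranges (years) per clinical form, mirroring the study cohort.
AGE_RANGES = {
    "RR": (20.5, 53.1),
    "PP": (27.8, 51.6),
    "SP": (28.9, 52.2),
    "HC": (21.6, 56.5),
    "HC_IXI": (20.1, 86.2),
}

# Female fraction per class (study cohort: RR 30/42, PP 12/21, SP 11/28,
# HC-AMSEP 14/21, HC-IXI 175/314).
FEMALE_FRACTION = {
    "RR": 30 / 42,
    "PP": 12 / 21,
    "SP": 11 / 28,
    "HC": 14 / 21,
    "HC_IXI": 175 / 314,
}


@dataclass(frozen=True)
class ScanRecord:
    """One scan: metadata plus vertex-level thickness data.

    ``vertices`` is a DataFrame with columns ``vertex_id``, ``region_id``
    (1-based, in ``[1, N]``) and ``thickness_mm``. ``features`` may hold a
    pre-summarized region feature matrix instead (see
    :mod:`morphgcn.features`).
    """

    scan_id: str
    patient_id: str
    age_years: float
    sex: str  # "F" or "M"
    label: str  # RR / SP / PP / HC
    vertices: Optional[pd.DataFrame] = None
    features: Optional[object] = None  # features.FeatureMatrix

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")
        if not self.age_years > 0:
            raise ValueError("age_years must be positive")


#: Clinical severity gradient of gray-matter atrophy across MS forms:
#: relapsing-remitting is the mildest, the progressive forms accumulate
#: substantially more cortical thinning (SP carries the longest disease
#: duration). Multiplies the base effect size.
CLASS_SEVERITY = {"RR": 1.0, "PP": 2.0, "SP": 3.0, "HC": 0.0}


def default_class_effect(
    n_regions: int,
    effect_mm: float = 0.06,
    fraction: float = 0.10,
    severity: Mapping[str, float] = None,
) -> dict:
    """Disjoint per-class atrophy patterns with a severity gradient.

    Each MS form thins a distinct contiguous subset of ``fraction * N``
    regions by ``severity[class] * effect_mm`` millimetres; healthy
    controls are unaffected. Disjoint subsets and graded severities make
    every pairwise form comparison informative.
    """
    if severity is None:
        severity = CLASS_SEVERITY
    k = max(1, int(round(fraction * n_regions)))
    if 3 * k > n_regions:
        raise ValueError("affected fraction too large for disjoint class subsets")
    effect = {}
    for c, cls in enumerate(("RR", "PP", "SP")):
        regions = range(1 + c * k, 1 + (c + 1) * k)  # 1-based region ids
        effect[cls] = {r: float(severity[cls] * effect_mm) for r in regions}
    effect["HC"] = {}
    return effect


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study's cohort composition: 42 RR / 21 PP /
    28 SP / 21 HC patients with 299 / 143 / 218 / 21 scans, plus an
    independent 314-subject wide-age healthy reference for
    :func:`simulate_healthy_reference`.
    """

    atlas_size: int = 68
    vertices_per_region: int = 200
    n_patients_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"RR": 42, "PP": 21, "SP": 28, "HC": 21}
    )
    #: None -> allocate scans so class totals match ``class_scan_totals``;
    #: an int gives every patient that many scans; a (lo, hi) tuple samples
    #: uniformly per patient.
    scans_per_patient: Union[None, int, tuple] = None
    class_scan_totals: Mapping[str, int] = field(
        default_factory=lambda: {"RR": 299, "PP": 143, "SP": 218, "HC": 21}
    )
    #: per-region baseline mean thickness (mm); None -> drawn once,
    #: uniform on ``baseline_range``.
    baseline_mean_mm: Optional[np.ndarray] = None
    baseline_range: tuple = (2.0, 3.0)
    healthy_slope_mm_per_year: Mapping[str, float] = field(
        default_factory=lambda: {"F": -0.004, "M": -0.005}
    )
    #: additive offset for male scans (mm); females are the reference.
    sex_offset_mm: float = -0.02
    #: label -> {region_id -> thinning in mm}; None -> default_class_effect
    #: at a base effect of one between-subject SD.
    class_effect: Optional[Mapping[str, Mapping[int, float]]] = None
    #: fraction of an affected region's vertices carrying its thinning
    #: (each by delta/fraction, so the region-mean thinning stays delta).
    #: Cortical atrophy is focal: thinning concentrates in a sub-region,
    #: which also perturbs the region's variance and shape moments.
    focal_fraction: float = 0.5
    patient_intercept_sd_mm: float = 0.05
    within_patient_sd_mm: float = 0.02
    vertex_noise_sd_mm: float = 0.40
    #: skew-normal shape of vertex noise (0 -> gaussian).
    vertex_noise_skew: float = 4.0
    n_ixi_subjects: int = 314
    truncation_mm: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for cls, n in self.n_patients_per_class.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown class key {cls!r}")
            if n <= 0:
                raise ValueError(f"non-positive patient count for {cls}: {n}")
        if self.atlas_size <= 0 or self.vertices_per_region <= 0:
            raise ValueError("atlas_size and vertices_per_region must be positive")
        if self.class_effect is not None:
            for cls in self.class_effect:
                if cls not in CLASSES:
                    raise ValueError(f"unknown class key in class_effect: {cls!r}")

    def resolved_class_effect(self) -> Mapping[str, Mapping[int, float]]:
        if self.class_effect is None:
            return default_class_effect(
                self.atlas_size, effect_mm=self.expected_subject_sd()
            )
        return self.class_effect

    def expected_subject_sd(self) -> float:
        """Predicted between-subject SD of a region's mean-thickness feature.

        Combines the patient intercept, the scan-to-scan shift and the
        standard error of the vertex-noise mean over a region.
        """
        v = self.vertices_per_region
        return float(
            np.sqrt(
                self.patient_intercept_sd_mm**2
                + self.within_patient_sd_mm**2
                + self.vertex_noise_sd_mm**2 / v
            )
        )

    def class_effect_standardized(
        self, size_sd: float, fraction: float = 0.10
    ) -> dict:
        """Per-class effect whose base magnitude is ``size_sd``
        between-subject SDs (the per-class severity gradient multiplies
        this base)."""
        return default_class_effect(
            self.atlas_size, effect_mm=size_sd * self.expected_subject_sd(),
            fraction=fraction,
        )


def scan_schedule_ages(first_age: float, n_scans: int) -> np.ndarray:
    """Ages of a longitudinal series: 6-month spacing for the first six
    scans, yearly afterwards."""
    offsets = [0.5 * i for i in range(min(n_scans, 6))]
    t = offsets[-1] if offsets else 0.0
    for _ in range(n_scans - 6):
        t += 1.0
        offsets.append(t)
    return first_age + np.asarray(offsets[:n_scans])


def _allocate_scan_counts(n_patients: int, total: int) -> np.ndarray:
    """Per-patient scan counts summing exactly to ``total``."""
    base, extra = divmod(total, n_patients)
    counts = np.full(n_patients, base, dtype=int)
    counts[:extra] += 1
    if base == 0:
        raise ValueError(
            f"cannot allocate {total} scans to {n_patients} patients"
        )
    return counts


def _skew_normal_noise(rng: np.random.Generator, size, sd: float, shape: float):
    """Centred, variance-``sd**2`` skew-normal draws (shape=0 -> gaussian)."""
    if sd == 0:
        return np.zeros(size)
    delta = shape / np.sqrt(1.0 + shape**2)
    u0 = np.abs(rng.standard_normal(size))
    u1 = rng.standard_normal(size)
    z = delta * u0 + np.sqrt(1.0 - delta**2) * u1
    mean = delta * np.sqrt(2.0 / np.pi)
    std = np.sqrt(1.0 - 2.0 * delta**2 / np.pi)
    return (z - mean) / std * sd


def _sexes(n: int, female_fraction: float) -> list:
    n_f = int(round(n * female_fraction))
    return ["F"] * n_f + ["M"] * (n - n_f)


def _simulate_patient_scans(
    rng: np.random.Generator,
    config: SimulationConfig,
    baselines: np.ndarray,
    patient_id: str,
    label: str,
    sex: str,
    ages: np.ndarray,
    effect: Mapping[int, float],
) -> list:
    N, V = config.atlas_size, config.vertices_per_region
    slope = config.healthy_slope_mm_per_year[sex]
    sex_off = config.sex_offset_mm if sex == "M" else 0.0
    intercept = rng.normal(0.0, config.patient_intercept_sd_mm)
    region_ids = np.repeat(np.arange(1, N + 1), V)
    vertex_ids = np.arange(N * V)
    # Focal atrophy: a fixed sub-region (first focal_fraction of vertices)
    # carries the whole thinning delta/f, keeping the region mean at
    # baseline - delta while variance and shape moments shift too.
    vertex_delta = np.zeros(N * V)
    f = config.focal_fraction
    n_focal = max(1, int(round(f * V)))
    for r, d in effect.items():
        lo = (r - 1) * V
        vertex_delta[lo:lo + n_focal] = d * V / n_focal
    base_vertex = np.repeat(baselines, V) - vertex_delta
    scans = []
    for j, age in enumerate(ages):
        scan_shift = rng.normal(0.0, config.within_patient_sd_mm)
        noise = _skew_normal_noise(
            rng, N * V, config.vertex_noise_sd_mm, config.vertex_noise_skew
        )
        t = (
            base_vertex
            + slope * age
            + sex_off
            + intercept
            + scan_shift
            + noise
        )
        np.maximum(t, config.truncation_mm, out=t)
        df = pd.DataFrame(
            {"vertex_id": vertex_ids, "region_id": region_ids, "thickness_mm": t}
        )
        scans.append(
            ScanRecord(
                scan_id=f"{patient_id}_s{j:02d}",
                patient_id=patient_id,
                age_years=float(age),
                sex=sex,
                label=label,
                vertices=df,
            )
        )
    return scans


def _resolve_baselines(config: SimulationConfig, rng: np.random.Generator):
    if config.baseline_mean_mm is not None:
        b = np.asarray(config.baseline_mean_mm, dtype=float)
        if b.shape != (config.atlas_size,):
            raise ValueError("baseline_mean_mm must have length atlas_size")
        return b
    lo, hi = config.baseline_range
    return rng.uniform(lo, hi, size=config.atlas_size)


def _patient_scan_counts(config: SimulationConfig, cls: str, n: int, rng):
    spp = config.scans_per_patient
    if spp is None:
        total = config.class_scan_totals.get(cls)
        if total is None:
            raise ValueError(f"no scan total configured for class {cls}")
        return _allocate_scan_counts(n, total)
    if isinstance(spp, int):
        return np.full(n, spp, dtype=int)
    lo, hi = spp
    return rng.integers(lo, hi + 1, size=n)


def simulate_cohort(config: SimulationConfig) -> list:
    """Generate the full longitudinal cohort (all classes in the config).

    Returns a list of :class:`ScanRecord`. Identical ``(seed, config)``
    yield byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    baselines = _resolve_baselines(config, rng)
    effect = config.resolved_class_effect()
    scans: list = []
    for cls in CLASSES:  # fixed order for determinism
        if cls not in config.n_patients_per_class:
            continue
        n = config.n_patients_per_class[cls]
        counts = _patient_scan_counts(config, cls, n, rng)
        sexes = _sexes(n, FEMALE_FRACTION[cls])
        lo, hi = AGE_RANGES[cls]
        for p in range(n):
            n_scans = int(counts[p])
            span = scan_schedule_ages(0.0, n_scans)[-1]
            first_age = rng.uniform(lo, max(lo + 1e-6, hi - span))
            ages = scan_schedule_ages(first_age, n_scans)
            scans.extend(
                _simulate_patient_scans(
                    rng, config, baselines,
                    patient_id=f"{cls}{p:03d}", label=cls, sex=sexes[p],
                    ages=ages, effect=effect.get(cls, {}),
                )
            )
    return scans


def simulate_healthy_reference(config: SimulationConfig) -> list:
    """Healthy reference cohort: the HC subjects of the study protocol plus
    a wide-age single-scan reference group, one scan per subject.

    With default counts this yields 21 + 314 = 335 scans spanning ages
    ~20-86, suitable for fitting the age/sex normalization models.
    """
    rng = np.random.default_rng(config.seed + 1)
    baselines = _resolve_baselines(
        dataclasses.replace(config, seed=config.seed),
        np.random.default_rng(config.seed),
    )
    scans: list = []
    groups = [
        ("HCA", config.n_patients_per_class.get("HC", 21), AGE_RANGES["HC"],
         FEMALE_FRACTION["HC"]),
        ("HCI", config.n_ixi_subjects, AGE_RANGES["HC_IXI"],
         FEMALE_FRACTION["HC_IXI"]),
    ]
    for prefix, n, (lo, hi), f_frac in groups:
        if n <= 0:
            raise ValueError(f"non-positive subject count for {prefix}")
        sexes = _sexes(n, f_frac)
        for p in range(n):
            age = rng.uniform(lo, hi)
            scans.extend(
                _simulate_patient_scans(
                    rng, config, baselines,
                    patient_id=f"{prefix}{p:03d}", label="HC", sex=sexes[p],
                    ages=np.array([age]), effect={},
                )
            )
    return scans


# ---------------------------------------------------------------------------
# Tabular I/O

def cohort_to_tables(scans: Sequence[ScanRecord]):
    """(metadata, thickness) long-format DataFrames for a scan collection."""
    meta = pd.DataFrame(
        [
            {
                "scan_id": s.scan_id,
                "patient_id": s.patient_id,
                "age_years": s.age_years,
                "sex": s.sex,
                "label": s.label,
            }
            for s in scans
        ]
    )
    thick = pd.concat(
        [s.vertices.assign(scan_id=s.scan_id) for s in scans if s.vertices is not None],
        ignore_index=True,
    )[["scan_id", "vertex_id", "region_id", "thickness_mm"]]
    return meta, thick


def write_cohort(scans: Sequence[ScanRecord], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta, thick = cohort_to_tables(scans)
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
    thick.to_csv(out / "thickness.tsv", sep="\t", index=False,
                 float_format="%.17g")


def read_cohort(in_dir) -> list:
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "metadata.tsv", sep="\t")
    thick = pd.read_csv(in_dir / "thickness.tsv", sep="\t")
    by_scan = dict(tuple(thick.groupby("scan_id", sort=False)))
    scans = []
    for row in meta.itertuples(index=False):
        df = by_scan[row.scan_id][["vertex_id", "region_id", "thickness_mm"]]
        scans.append(
            ScanRecord(
                scan_id=row.scan_id, patient_id=row.patient_id,
                age_years=float(row.age_years), sex=row.sex, label=row.label,
                vertices=df.reset_index(drop=True),
            )
        )
    return scans
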