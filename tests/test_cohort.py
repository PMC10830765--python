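"""Synthetic cohort simulator: counts, determinism, and signal structure."""

import numpy as np
import pytest
from scipy import stats

from morphgcn import SimulationConfig, simulate_cohort, simulate_healthy_reference
from morphgcn.cohort import (
    cohort_to_tables,
    default_class_effect,
    read_cohort,
    scan_schedule_ages,
    write_cohort,
)


def _counts_by_label(scans):
    out = {}
    for s in scans:
        out[s.label] = out.get(s.label, 0) + 1
    return out


class TestCohortComposition:
    def test_default_scan_counts_match_study_cohort(self):
        """Default composition: 299 RR / 143 PP / 218 SP / 21 HC scans."""
        cfg = SimulationConfig(vertices_per_region=5, seed=0)
        scans = simulate_cohort(cfg)
        counts = _counts_by_label(scans)
        assert counts == {"RR": 299, "PP": 143, "SP": 218, "HC": 21}
        patients = {}
        for s in scans:
            patients.setdefault(s.label, set()).add(s.patient_id)
        assert {k: len(v) for k, v in patients.items()} == {
            "RR": 42, "PP": 21, "SP": 28, "HC": 21,
        }

    def test_healthy_reference_has_335_single_scan_subjects(self):
        cfg = SimulationConfig(vertices_per_region=5, seed=0)
        scans = simulate_healthy_reference(cfg)
        assert len(scans) == 335
        assert all(s.label == "HC" for s in scans)
        assert len({s.patient_id for s in scans}) == 335

    def test_ages_within_simulated_range(self):
        cfg = SimulationConfig(vertices_per_region=5, seed=3)
        for s in simulate_cohort(cfg) + simulate_healthy_reference(cfg):
            assert 20.0 < s.age_years < 87.0

    def test_longitudinal_schedule_six_monthly_then_yearly(self):
        ages = scan_schedule_ages(30.0, 8)
        assert np.allclose(np.diff(ages), [0.5] * 5 + [1.0, 1.0])

    def test_repeated_scans_share_patient_metadata(self, small_cohort):
        by_patient = {}
        for s in small_cohort:
            by_patient.setdefault(s.patient_id, []).append(s)
        for pid, scans in by_patient.items():
            assert len({(s.sex, s.label) for s in scans}) == 1
            ages = sorted(s.age_years for s in scans)
            assert ages[0] < ages[-1] or len(ages) == 1

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            SimulationConfig(n_patients_per_class={"RR": 0})
        with pytest.raises(ValueError, match="unknown class"):
            SimulationConfig(n_patients_per_class={"XX": 3})


class TestThicknessModel:
    def test_thickness_strictly_positive_after_truncation(self, small_cohort):
        for s in small_cohort:
            assert (s.vertices["thickness_mm"] >= 0.5).all()
            assert s.vertices["region_id"].between(1, 20).all()

    def test_seed_determinism_byte_identical_tables(self, tmp_path):
        cfg = SimulationConfig(
            atlas_size=10, vertices_per_region=10,
            n_patients_per_class={"RR": 3, "HC": 3},
            class_scan_totals={"RR": 6, "HC": 3}, seed=7,
        )
        for d in ("a", "b"):
            write_cohort(simulate_cohort(cfg), tmp_path / d)
        for name in ("metadata.tsv", "thickness.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_cohort_tsv_round_trip(self, tmp_path):
        cfg = SimulationConfig(
            atlas_size=5, vertices_per_region=8,
            n_patients_per_class={"RR": 2}, class_scan_totals={"RR": 4}, seed=1,
        )
        scans = simulate_cohort(cfg)
        write_cohort(scans, tmp_path)
        back = read_cohort(tmp_path)
        assert [s.scan_id for s in back] == [s.scan_id for s in scans]
        for a, b in zip(scans, back):
            np.testing.assert_allclose(
                a.vertices["thickness_mm"], b.vertices["thickness_mm"]
            )

    def test_null_effect_leaves_region_means_exchangeable(self):
        """With zero class effect, per-region two-sample t-tests between
        classes reject at about the nominal rate."""
        cfg = SimulationConfig(
            atlas_size=40, vertices_per_region=50,
            n_patients_per_class={"RR": 20, "PP": 20},
            scans_per_patient=1, class_effect={}, seed=5,
        )
        scans = simulate_cohort(cfg)
        mu = {
            cls: np.stack([
                s.vertices.groupby("region_id")["thickness_mm"].mean().to_numpy()
                for s in scans if s.label == cls
            ])
            for cls in ("RR", "PP")
        }
        _, p = stats.ttest_ind(mu["RR"], mu["PP"], axis=0)
        assert (p > 0.01).mean() >= 0.95

    def test_effect_size_monotonically_increases_separation(self):
        """Larger atrophy effects increase the standardized RR-vs-HC
        difference in affected regions' mean thickness."""
        seps = []
        for size in (0.0, 1.0, 3.0):
            cfg = SimulationConfig(
                atlas_size=20, vertices_per_region=50,
                n_patients_per_class={"RR": 15, "HC": 15},
                scans_per_patient=1, seed=9,
            )
            cfg.class_effect = cfg.class_effect_standardized(size)
            scans = simulate_cohort(cfg)
            affected = sorted(cfg.class_effect["RR"])
            mu = {
                cls: np.stack([
                    s.vertices.groupby("region_id")["thickness_mm"].mean()
                    .loc[affected].to_numpy()
                    for s in scans if s.label == cls
                ])
                for cls in ("RR", "HC")
            }
            pooled_sd = np.sqrt(
                (mu["RR"].var(axis=0) + mu["HC"].var(axis=0)) / 2
            )
            seps.append(
                float(np.mean((mu["HC"].mean(0) - mu["RR"].mean(0)) / pooled_sd))
            )
        assert seps[0] < seps[1] < seps[2]

    def test_focal_thinning_perturbs_higher_moments(self):
        """Focal atrophy changes the affected region's spread, not just
        its mean."""
        base = SimulationConfig(
            atlas_size=10, vertices_per_region=400,
            n_patients_per_class={"SP": 8}, scans_per_patient=1,
            patient_intercept_sd_mm=0.0, within_patient_sd_mm=0.0, seed=2,
        )
        base.class_effect = {"SP": {1: 0.15}}
        scans = simulate_cohort(base)
        sig = np.mean([
            s.vertices.groupby("region_id")["thickness_mm"].std().iloc[0]
            for s in scans
        ])
        ref = np.mean([
            s.vertices.groupby("region_id")["thickness_mm"].std().iloc[5]
            for s in scans
        ])
        assert sig > ref * 1.02


class TestAgeEffect:
    def _fit_slope(self, scans, sex):
        sub = [s for s in scans if s.sex == sex]
        age = np.array([s.age_years for s in sub])
        cth = np.array([s.vertices["thickness_mm"].mean() for s in sub])
        return stats.linregress(age, cth)

    def test_noiseless_slope_recovered_exactly(self):
        cfg = SimulationConfig(
            atlas_size=10, vertices_per_region=20,
            n_patients_per_class={"HC": 15}, n_ixi_subjects=30,
            healthy_slope_mm_per_year={"F": -0.01, "M": -0.01},
            sex_offset_mm=0.0, patient_intercept_sd_mm=0.0,
            within_patient_sd_mm=0.0, vertex_noise_sd_mm=0.0, seed=4,
        )
        scans = simulate_healthy_reference(cfg)
        for sex in ("F", "M"):
            fit = self._fit_slope(scans, sex)
            assert fit.slope == pytest.approx(-0.01, abs=1e-12)

    def test_noisy_slope_within_three_standard_errors(self):
        cfg = SimulationConfig(atlas_size=20, vertices_per_region=30, seed=8)
        scans = simulate_healthy_reference(cfg)  # 335 scans
        assert len(scans) >= 300
        for sex in ("F", "M"):
            fit = self._fit_slope(scans, sex)
            truth = cfg.healthy_slope_mm_per_year[sex]
            assert abs(fit.slope - truth) < 3 * fit.stderr


def test_default_class_effect_structure():
    eff = default_class_effect(68, effect_mm=0.05)
    assert set(eff) == {"RR", "PP", "SP", "HC"}
    sets = [set(eff[c]) for c in ("RR", "PP", "SP")]
    assert all(len(s) == 7 for s in sets)
    assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
    # severity gradient: RR mildest, SP strongest
    mags = [next(iter(eff[c].values())) for c in ("RR", "PP", "SP")]
    assert mags[0] < mags[1] < mags[2]
    with pytest.raises(ValueError):
        default_class_effect(12, fraction=0.5)
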