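"""Synthetic cohort generator: effective age, determinism, artifacts."""

import numpy as np
import pandas as pd
import pytest

from brainclock import hoi, synthetic
from brainclock.errors import ConfigurationError, GenerationError
from brainclock.synthetic import CohortConfig, SubjectRecord


@pytest.mark.parametrize(
    "record_kw, offsets, expect",
    [
        (dict(diagnosis="HC", region_group="nonLAC"), None, 60.0),
        (dict(diagnosis="HC", region_group="LAC"), {"LAC": 5.0}, 65.0),
        (
            dict(diagnosis="AD", region_group="LAC", sex="F"),
            {"LAC": 5.0, "AD": 8.0, "F_LAC_AD": 2.0},
            75.0,
        ),
        (dict(diagnosis="MCI", region_group="nonLAC"), None, 63.0),
    ],
)
def test_effective_age_offsets(record_kw, offsets, expect):
    cfg = (
        CohortConfig()
        if offsets is None
        else CohortConfig(effective_age_offsets=offsets)
    )
    rec = SubjectRecord("s", 60.0, **record_kw)
    assert synthetic.effective_age(rec, cfg) == expect


def test_effective_age_rejects_unknown_enum():
    with pytest.raises(ConfigurationError):
        synthetic.effective_age(SubjectRecord("s", 60.0, diagnosis="XX"), CohortConfig())


class TestTimeseriesGeneration:
    def test_same_seed_bitwise_identical(self):
        cfg = CohortConfig(n_regions=8, n_timepoints=100, seed=5)
        rec = SubjectRecord("a", 70.0)
        t1 = synthetic.generate_subject_timeseries(rec, cfg)
        t2 = synthetic.generate_subject_timeseries(rec, cfg)
        np.testing.assert_array_equal(t1.data, t2.data)

    def test_minimum_dimensions_enforced(self):
        with pytest.raises(GenerationError):
            synthetic.generate_subject_timeseries(
                SubjectRecord("a", 70.0), CohortConfig(n_regions=2, n_timepoints=100)
            )

    def test_marginals_finite(self):
        cfg = CohortConfig(n_regions=6, n_timepoints=200, seed=1)
        ts = synthetic.generate_subject_timeseries(SubjectRecord("a", 50.0), cfg)
        assert np.all(np.isfinite(ts.data))

    def test_site_offset_shifts_level(self):
        base = CohortConfig(n_regions=6, n_timepoints=100, seed=2)
        shifted = CohortConfig(
            n_regions=6, n_timepoints=100, seed=2, site_offsets={"scanner0": 10.0}
        )
        rec = SubjectRecord("a", 50.0, scanner_id="scanner0")
        d0 = synthetic.generate_subject_timeseries(rec, base).data
        d1 = synthetic.generate_subject_timeseries(rec, shifted).data
        np.testing.assert_allclose(d1 - d0, 10.0, atol=1e-12)

    def test_hub_omega_increases_with_effective_age(self):
        """Redundancy among hub regions must grow with age (monotone grid)."""
        cfg = CohortConfig(
            n_regions=10, n_timepoints=600, effective_age_offsets={}, seed=7
        )
        hubs = cfg.resolved_hubs()
        means = []
        for age in (40.0, 65.0, 90.0):
            vals = []
            for i in range(30):
                ts = synthetic.generate_subject_timeseries(
                    SubjectRecord(f"g{age}_{i}", age), cfg
                )
                m = hoi.omega_matrix(ts).values
                vals.append(np.mean([m[a, b] for a in hubs for b in hubs if a < b]))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_age_signal_switched_off(self):
        """With zero slopes, omega entries are uncorrelated with age."""
        cfg = CohortConfig(
            n_regions=6, n_timepoints=300, effective_age_offsets={},
            hub_loading_slope=0.0, synergy_weight_slope=0.0, seed=9,
        )
        ages = np.linspace(40, 90, 60)
        entries = []
        for i, age in enumerate(ages):
            ts = synthetic.generate_subject_timeseries(SubjectRecord(f"z{i}", age), cfg)
            entries.append(hoi.omega_matrix(ts).values[0, 1])
        r = np.corrcoef(ages, entries)[0, 1]
        assert abs(r) < 0.25


class TestArtifacts:
    cfg = CohortConfig(n_regions=6, n_timepoints=2000, seed=3)

    def test_zero_fractions_identity(self):
        ts = synthetic.generate_subject_timeseries(SubjectRecord("a", 60.0), self.cfg)
        out = synthetic.inject_artifacts(ts, 0.0, 0.0, seed=1)
        np.testing.assert_array_equal(out.data, ts.data)
        assert out.corrupted_segments == {}

    def test_exact_corruption_count(self):
        ts = synthetic.generate_subject_timeseries(SubjectRecord("a", 60.0), self.cfg)
        out = synthetic.inject_artifacts(ts, spike_fraction=0.2, seed=1)
        assert len(out.corrupted_segments) == round(0.2 * (2000 // 20))
        assert set(out.corrupted_segments.values()) == {"spike"}

    def test_returns_copy(self):
        ts = synthetic.generate_subject_timeseries(SubjectRecord("a", 60.0), self.cfg)
        before = ts.data.copy()
        synthetic.inject_artifacts(ts, spike_fraction=0.5, seed=2)
        np.testing.assert_array_equal(ts.data, before)

    def test_fraction_bounds(self):
        ts = synthetic.generate_subject_timeseries(SubjectRecord("a", 60.0), self.cfg)
        with pytest.raises(ConfigurationError):
            synthetic.inject_artifacts(ts, spike_fraction=1.2)


class TestCohort:
    def test_stratification_counts_exact(self):
        cfg = CohortConfig(n_subjects=20, n_regions=4, n_timepoints=50, seed=1)
        manifest, series = synthetic.generate_cohort(
            cfg,
            [
                {"count": 10, "region_group": "LAC", "diagnosis": "HC"},
                {"count": 10, "region_group": "nonLAC", "diagnosis": "HC"},
            ],
        )
        assert manifest.region_group.value_counts().to_dict() == {"LAC": 10, "nonLAC": 10}
        assert len(series) == 20

    def test_counts_exceeding_n_subjects_rejected(self):
        cfg = CohortConfig(n_subjects=5, n_regions=4, n_timepoints=50)
        with pytest.raises(ConfigurationError):
            synthetic.generate_cohort(cfg, [{"count": 6}], make_timeseries=False)

    def test_manifest_deterministic(self):
        cfg = CohortConfig(n_subjects=15, n_regions=4, n_timepoints=50, seed=4)
        m1, _ = synthetic.generate_cohort(cfg, make_timeseries=False)
        m2, _ = synthetic.generate_cohort(cfg, make_timeseries=False)
        pd.testing.assert_frame_equal(m1, m2)

    def test_manifest_only_sex_counts(self):
        """Requested per-stratum sex counts appear verbatim in the manifest."""
        counts = {"HC": (954, 532), "MCI": (111, 22), "AD": (85, 23), "bvFTD": (39, 18)}
        strata = []
        for dx, (f, m) in counts.items():
            strata.append({"count": f, "diagnosis": dx, "sex": "F", "region_group": "LAC"})
            strata.append({"count": m, "diagnosis": dx, "sex": "M", "region_group": "LAC"})
        total = sum(f + m for f, m in counts.values())
        cfg = CohortConfig(n_subjects=total, n_regions=4, n_timepoints=50, seed=0)
        manifest, _ = synthetic.generate_cohort(cfg, strata, make_timeseries=False)
        tab = pd.crosstab(manifest.diagnosis, manifest.sex)
        for dx, (f, m) in counts.items():
            assert (tab.loc[dx, "F"], tab.loc[dx, "M"]) == (f, m)
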