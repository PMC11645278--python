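"""Synthetic cohort generator.

Produces region x time signal matrices whose higher-order interaction
structure varies deterministically with an *effective age*: chronological
age plus configurable offsets for region-of-residence (LAC vs non-LAC),
diagnosis (HC/MCI/AD/bvFTD) and a sex x region x diagnosis interaction.
The generator uses a latent-factor construction:

* *hub* regions load on a shared latent factor with a loading that grows
  linearly with effective age, so redundancy among hubs increases with age;
* each *synergy triplet* (i, j, k) rewrites region k as a weighted sum of
  regions i and j plus residual noise, with the weight again linear in
  effective age, so synergy also carries age signal;
* per-scanner additive level shifts emulate site effects, and an fMRI-like
  baseline level gives realistic temporal signal-to-noise ratios.

Everything is a pure function of (config, seed): the per-subject stream is
seeded from the cohort seed and a stable hash of the subject id.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, GenerationError

SEXES = ("F", "M")
DIAGNOSES = ("HC", "MCI", "AD", "bvFTD")
REGION_GROUPS = ("LAC", "nonLAC")
EYES = ("open", "closed")
MODALITIES = ("fMRI", "EEG")

LAC_COUNTRIES = ("AR", "BR", "CL", "CO", "CU", "MX", "PE")
NONLAC_COUNTRIES = ("US", "CN", "JP", "IE", "IT", "TR", "UK")


@dataclass(frozen=True)
class SubjectRecord:
    """Demographic/acquisition metadata for one subject."""

    subject_id: str
    age: float
    sex: str = "F"
    diagnosis: str = "HC"
    region_group: str = "nonLAC"
    country: str = "US"
    scanner_id: str = "scanner0"
    eyes: str = "open"
    education: float = 12.0

    def validate(self, age_range: tuple[float, float] = (21.0, 92.0)) -> None:
        if self.sex not in SEXES:
            raise ConfigurationError(f"unknown sex {self.sex!r}")
        if self.diagnosis not in DIAGNOSES:
            raise ConfigurationError(f"unknown diagnosis {self.diagnosis!r}")
        if self.region_group not in REGION_GROUPS:
            raise ConfigurationError(f"unknown region_group {self.region_group!r}")
        if self.eyes not in EYES:
            raise ConfigurationError(f"unknown eyes condition {self.eyes!r}")
        if not self.scanner_id:
            raise ConfigurationError("scanner_id must be non-empty")
        lo, hi = age_range
        if not (lo <= self.age <= hi):
            raise ConfigurationError(
                f"age {self.age} outside configured range [{lo}, {hi}]"
            )


@dataclass
class RegionTimeSeries:
    """One subject's T x R parcellated signal matrix plus acquisition metadata."""

    subject_id: str
    data: np.ndarray
    sampling_interval: float
    modality: str = "fMRI"
    corrupted_segments: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise GenerationError("time-series data must be a 2-D T x R matrix")
        if self.modality not in MODALITIES:
            raise ConfigurationError(f"unknown modality {self.modality!r}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


DEFAULT_OFFSETS: dict[str, float] = {
    "LAC": 5.0,
    "MCI": 3.0,
    "AD": 8.0,
    "bvFTD": 6.0,
    "F_LAC_AD": 2.0,
}


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the cohort generator.

    ``hub_loading_base``/``hub_loading_slope`` parameterize the age-dependent
    shared-factor loading lambda(a) = base + slope * (a - reference_age), and
    ``synergy_weight_base``/``synergy_weight_slope`` the analogous weight of
    each synergy triplet. With both slopes set to zero, the interaction
    structure is independent of age.
    """

    n_subjects: int = 100
    n_regions: int = 82
    n_timepoints: int = 400
    age_range: tuple[float, float] = (40.0, 90.0)
    age_law: str = "uniform"
    effective_age_offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OFFSETS)
    )
    hub_regions: tuple[int, ...] | None = None
    synergy_triplets: tuple[tuple[int, int, int], ...] | None = None
    hub_loading_base: float = 1.0
    hub_loading_slope: float = 0.02
    synergy_weight_base: float = 0.5
    synergy_weight_slope: float = 0.01
    reference_age: float = 65.0
    common_loading: float = 0.2
    noise_sd: float = 1.0
    baseline_level: float = 200.0
    site_offsets: Mapping[str, float] = field(default_factory=dict)
    modality: str = "fMRI"
    sampling_interval: float | None = None
    seed: int = 0

    def resolved_hubs(self) -> tuple[int, ...]:
        if self.hub_regions is not None:
            hubs = tuple(int(i) for i in self.hub_regions)
        else:
            hubs = tuple(range(max(3, self.n_regions // 4)))
        for i in hubs:
            if not 0 <= i < self.n_regions:
                raise ConfigurationError(f"hub region {i} outside [0, {self.n_regions})")
        return hubs

    def resolved_triplets(self) -> tuple[tuple[int, int, int], ...]:
        if self.synergy_triplets is not None:
            trips = tuple(tuple(int(v) for v in t) for t in self.synergy_triplets)
        else:
            hubs = set(self.resolved_hubs())
            free = [i for i in range(self.n_regions) if i not in hubs]
            trips = tuple(
                (free[3 * q], free[3 * q + 1], free[3 * q + 2])
                for q in range(min(3, len(free) // 3))
            )
        for t in trips:
            if len(t) != 3 or len(set(t)) != 3:
                raise ConfigurationError(f"synergy triplet {t} must be 3 distinct regions")
            for i in t:
                if not 0 <= i < self.n_regions:
                    raise ConfigurationError(
                        f"triplet region {i} outside [0, {self.n_regions})"
                    )
        return trips

    def resolved_sampling_interval(self) -> float:
        if self.sampling_interval is not None:
            return float(self.sampling_interval)
        return 2.0 if self.modality == "fMRI" else 1.0 / 128.0


def effective_age(record: SubjectRecord, config: CohortConfig) -> float:
    """Chronological age plus the configured group offsets (deterministic)."""
    record.validate(config.age_range)
    offs = config.effective_age_offsets
    a = float(record.age)
    if record.region_group == "LAC":
        a += float(offs.get("LAC", 0.0))
    if record.diagnosis != "HC":
        a += float(offs.get(record.diagnosis, 0.0))
    if record.sex == "F" and record.region_group == "LAC" and record.diagnosis == "AD":
        a += float(offs.get("F_LAC_AD", 0.0))
    return a


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    # crc32 gives a stable, platform-independent per-subject stream
    return np.random.default_rng([int(seed), zlib.crc32(subject_id.encode())])


def generate_subject_timeseries(
    record: SubjectRecord, config: CohortConfig
) -> RegionTimeSeries:
    """Simulate one subject's T x R matrix from the latent-factor model."""
    T, R = config.n_timepoints, config.n_regions
    if T < 3 or R < 3:
        raise GenerationError(f"need T >= 3 and R >= 3, got T={T}, R={R}")
    a_eff = effective_age(record, config)
    rng = _subject_rng(config.seed, record.subject_id)

    g = rng.standard_normal(T)
    X = config.noise_sd * rng.standard_normal((T, R))
    X += config.common_loading * g[:, None]

    lam = config.hub_loading_base + config.hub_loading_slope * (
        a_eff - config.reference_age
    )
    lam = max(lam, 0.05)
    hubs = list(config.resolved_hubs())
    X[:, hubs] += lam * g[:, None]

    w = config.synergy_weight_base + config.synergy_weight_slope * (
        a_eff - config.reference_age
    )
    resid_sd = 0.5 * config.noise_sd
    for i, j, k in config.resolved_triplets():
        X[:, k] = w * (X[:, i] + X[:, j]) + resid_sd * rng.standard_normal(T)

    dt = config.resolved_sampling_interval()
    if config.modality == "EEG":
        # band-limit to an alpha-range low-pass; the same filter on every
        # channel preserves the zero-lag correlation structure in expectation
        fs = 1.0 / dt
        sos = sps.butter(4, min(12.0, 0.45 * fs), btype="low", fs=fs, output="sos")
        X = sps.sosfiltfilt(sos, X, axis=0)
        X = np.ascontiguousarray(X)
    else:
        X += config.baseline_level
    X += float(config.site_offsets.get(record.scanner_id, 0.0))

    return RegionTimeSeries(
        subject_id=record.subject_id,
        data=X,
        sampling_interval=dt,
        modality=config.modality,
    )


def inject_artifacts(
    ts: RegionTimeSeries,
    spike_fraction: float = 0.0,
    flat_fraction: float = 0.0,
    seed: int = 0,
) -> RegionTimeSeries:
    """Corrupt a stated fraction of signal segments, returning a copy.

    Spike segments receive large transient excursions (amplitude ten times
    the per-region series SD, so |z| > 5 by any reasonable scale estimate);
    flat segments are replaced by near-constant signal. The corrupted
    segment indices are recorded on the returned object.
    """
    if not (0.0 <= spike_fraction <= 1.0 and 0.0 <= flat_fraction <= 1.0):
        raise ConfigurationError("artifact fractions must lie in [0, 1]")
    seg_len = 20 if ts.modality == "fMRI" else max(1, round(1.0 / ts.sampling_interval))
    n_seg = ts.n_timepoints // seg_len
    n_spike = round(spike_fraction * n_seg)
    n_flat = round(flat_fraction * n_seg)
    if n_spike + n_flat > n_seg:
        raise ConfigurationError("spike_fraction + flat_fraction exceed available segments")

    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_seg, size=n_spike + n_flat, replace=False)
    data = ts.data.copy()
    corrupted = dict(ts.corrupted_segments)
    sd = data.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    for q, s in enumerate(chosen):
        lo, hi = s * seg_len, (s + 1) * seg_len
        if q < n_spike:
            n_hits = max(1, seg_len // 10)
            hit = lo + rng.choice(seg_len, size=n_hits, replace=False)
            signs = rng.choice([-1.0, 1.0], size=(n_hits, data.shape[1]))
            data[hit, :] = data[hit, :] + 10.0 * sd * signs
            corrupted[int(s)] = "spike"
        else:
            mean = data[lo:hi].mean(axis=0)
            data[lo:hi] = mean + 1e-6 * sd * rng.standard_normal((seg_len, data.shape[1]))
            corrupted[int(s)] = "flat"

    return RegionTimeSeries(
        subject_id=ts.subject_id,
        data=data,
        sampling_interval=ts.sampling_interval,
        modality=ts.modality,
        corrupted_segments=corrupted,
    )


MANIFEST_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "diagnosis",
    "region_group",
    "country",
    "scanner_id",
    "eyes",
    "education",
)


def _sample_field(rng, name, fixed, region_group):
    if name in fixed:
        return fixed[name]
    if name == "sex":
        return rng.choice(SEXES)
    if name == "diagnosis":
        return rng.choice(DIAGNOSES, p=[0.55, 0.15, 0.20, 0.10])
    if name == "region_group":
        return rng.choice(REGION_GROUPS)
    if name == "country":
        pool = LAC_COUNTRIES if region_group == "LAC" else NONLAC_COUNTRIES
        return rng.choice(pool)
    if name == "scanner_id":
        return f"{region_group}_scanner{rng.integers(2)}"
    if name == "eyes":
        return rng.choice(EYES, p=[0.7, 0.3])
    if name == "education":
        return float(np.clip(rng.normal(12.0, 4.0), 0.0, 25.0))
    raise KeyError(name)


def sample_demographics(
    config: CohortConfig,
    strata: Sequence[Mapping[str, object]] | None = None,
) -> list[SubjectRecord]:
    """Draw a demographics table.

    ``strata`` is a list of dicts, each carrying a ``count`` plus any fixed
    record fields; unfixed fields are sampled. Counts are honoured exactly.
    With ``strata=None`` a single default stratum of ``n_subjects`` is used.
    """
    rng = np.random.default_rng([int(config.seed), 0xD390])
    if strata is None:
        strata = [{"count": config.n_subjects}]
    total = sum(int(s["count"]) for s in strata)
    if total > config.n_subjects:
        raise ConfigurationError(
            f"requested {total} subjects but config.n_subjects = {config.n_subjects}"
        )
    lo, hi = config.age_range
    records: list[SubjectRecord] = []
    idx = 0
    for stratum in strata:
        fixed = {k: v for k, v in stratum.items() if k != "count"}
        for _ in range(int(stratum["count"])):
            if "age" in fixed:
                age = float(fixed["age"])
            elif config.age_law == "uniform":
                age = float(rng.uniform(lo, hi))
            else:
                raise ConfigurationError(f"unknown age law {config.age_law!r}")
            region_group = _sample_field(rng, "region_group", fixed, None)
            rec = SubjectRecord(
                subject_id=fixed.get("subject_id_prefix", "sub") + f"{idx:05d}",
                age=age,
                sex=_sample_field(rng, "sex", fixed, region_group),
                diagnosis=_sample_field(rng, "diagnosis", fixed, region_group),
                region_group=region_group,
                country=_sample_field(rng, "country", fixed, region_group),
                scanner_id=_sample_field(rng, "scanner_id", fixed, region_group),
                eyes=_sample_field(rng, "eyes", fixed, region_group),
                education=_sample_field(rng, "education", fixed, region_group),
            )
            rec.validate(config.age_range)
            records.append(rec)
            idx += 1
    return records


def records_to_manifest(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in MANIFEST_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))


def manifest_to_records(manifest: pd.DataFrame) -> list[SubjectRecord]:
    return [
        SubjectRecord(
            subject_id=str(row.subject_id),
            age=float(row.age),
            sex=str(row.sex),
            diagnosis=str(row.diagnosis),
            region_group=str(row.region_group),
            country=str(row.country),
            scanner_id=str(row.scanner_id),
            eyes=str(row.eyes),
            education=float(row.education),
        )
        for row in manifest.itertuples(index=False)
    ]


def generate_cohort(
    config: CohortConfig,
    demographics: Sequence[SubjectRecord] | Sequence[Mapping[str, object]] | None = None,
    make_timeseries: bool = True,
) -> tuple[pd.DataFrame, dict[str, RegionTimeSeries]]:
    """Generate a manifest and (optionally) one time series per subject.

    ``demographics`` may be explicit :class:`SubjectRecord` objects or a list
    of strata dicts for :func:`sample_demographics`.
    """
    if demographics and isinstance(demographics[0], SubjectRecord):
        records = list(demographics)  # type: ignore[arg-type]
        for r in records:
            r.validate(config.age_range)
    else:
        records = sample_demographics(config, demographics)  # type: ignore[arg-type]
    manifest = records_to_manifest(records)
    if manifest.subject_id.duplicated().any():
        raise ConfigurationError("duplicate subject_id in demographics")
    series: dict[str, RegionTimeSeries] = {}
    if make_timeseries:
        for rec in records:
            series[rec.subject_id] = generate_subject_timeseries(rec, config)
    return manifest, series


# Typical 2019-2022 country-level values (World Bank / UNDP orders of
# magnitude), used to seed realistic exposome tables for synthetic cohorts.
_INDICATOR_BASE = {
    # country: (gini, pm25, communicable, noncommunicable, gii)
    "AR": (42.3, 13.8, 45.0, 520.0, 0.29),
    "BR": (52.9, 11.5, 60.0, 540.0, 0.39),
    "CL": (44.9, 22.6, 30.0, 430.0, 0.19),
    "CO": (54.8, 15.8, 55.0, 450.0, 0.42),
    "CU": (40.0, 17.0, 35.0, 480.0, 0.30),
    "MX": (45.4, 19.9, 50.0, 530.0, 0.35),
    "PE": (40.2, 29.6, 65.0, 420.0, 0.36),
    "US": (39.8, 7.7, 20.0, 490.0, 0.18),
    "CN": (38.2, 39.1, 25.0, 560.0, 0.19),
    "JP": (32.9, 13.1, 15.0, 300.0, 0.08),
    "IE": (30.6, 8.2, 14.0, 350.0, 0.07),
    "IT": (35.2, 15.3, 13.0, 340.0, 0.06),
    "TR": (41.9, 26.0, 28.0, 470.0, 0.27),
    "UK": (32.6, 9.7, 16.0, 360.0, 0.09),
}


def synthetic_country_indicators(
    countries: Iterable[str] | None = None, seed: int = 0, jitter: float = 0.0
) -> pd.DataFrame:
    """Country-level exposome table (Gini, PM2.5, disease burdens, GII)."""
    rng = np.random.default_rng(seed)
    names = list(countries) if countries is not None else sorted(_INDICATOR_BASE)
    rows = []
    for c in names:
        base = _INDICATOR_BASE.get(c)
        if base is None:
            base = (
                rng.uniform(30, 55),
                rng.uniform(7, 40),
                rng.uniform(10, 70),
                rng.uniform(300, 560),
                rng.uniform(0.05, 0.45),
            )
        vals = np.asarray(base, dtype=float)
        if jitter > 0:
            vals = vals * (1.0 + jitter * rng.standard_normal(5))
        rows.append(
            {
                "country": c,
                "gini": vals[0],
                "pm25": vals[1],
                "communicable": vals[2],
                "noncommunicable": vals[3],
                "gii": float(np.clip(vals[4], 0.0, 1.0)),
            }
        )
    return pd.DataFrame(rows)
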