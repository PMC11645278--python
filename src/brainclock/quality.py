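"""Signal-quality metrics (ODQ) and scanner harmonization of brain-age gaps.

The overall data quality (ODQ) score of a recording is the percentage of
fixed-length signal segments passing all quality rules: 20-sample segments
scored by temporal signal-to-noise ratio for fMRI-like data, 1-second
segments scored by four artifact rules for EEG-like data. Scanner
harmonization rescales brain-age gaps within each scanner to [-1, 1] with
a sign-preserving two-sided min-max map (positive gaps divided by the
scanner's maximum positive gap, negative gaps by |minimum|), so zero gaps
stay zero and the sign and within-scanner ordering are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateInputError
from .synthetic import RegionTimeSeries


@dataclass
class QualityReport:
    subject_id: str
    odq: float
    segment_flags: list[str]
    parameters: dict = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return len(self.segment_flags)


def fmri_odq(
    ts: RegionTimeSeries,
    tsnr_threshold: float = 50.0,
    cv_threshold: float = 0.5,
    spike_z_threshold: float = 5.0,
) -> QualityReport:
    """fMRI quality from 20-sample segments.

    A segment is good iff (a) its tSNR (per-region mean/SD, median across
    regions) exceeds ``tsnr_threshold``, (b) the across-region coefficient
    of variation of tSNR stays below ``cv_threshold`` (spatial consistency),
    and (c) no sample deviates from the segment median by more than
    ``spike_z_threshold`` per-region robust SDs (spike check; the SD is a
    whole-series MAD estimate so spikes cannot mask themselves).
    """
    seg_len = 20
    X = ts.data
    if X.shape[0] < seg_len:
        raise ContractError(f"need at least {seg_len} samples, got {X.shape[0]}")
    n_seg = X.shape[0] // seg_len
    mad = np.median(np.abs(X - np.median(X, axis=0)), axis=0)
    robust_sd = np.where(mad > 0, 1.4826 * mad, 1.0)
    flags: list[str] = []
    for s in range(n_seg):
        seg = X[s * seg_len : (s + 1) * seg_len]
        sd = seg.std(axis=0, ddof=1)
        tsnr = np.where(sd > 0, seg.mean(axis=0) / sd, np.inf)
        tsnr_med = float(np.median(tsnr))
        finite = tsnr[np.isfinite(tsnr)]
        cv = float(finite.std() / abs(finite.mean())) if finite.size and finite.mean() != 0 else np.inf
        z = np.abs(seg - np.median(seg, axis=0)) / robust_sd
        if tsnr_med <= tsnr_threshold:
            flags.append("low_tsnr")
        elif cv >= cv_threshold:
            flags.append("artifact")
        elif np.any(z > spike_z_threshold):
            flags.append("artifact")
        else:
            flags.append("good")
    odq = 100.0 * flags.count("good") / n_seg
    return QualityReport(
        subject_id=ts.subject_id, odq=odq, segment_flags=flags,
        parameters={"tsnr_threshold": tsnr_threshold, "cv_threshold": cv_threshold,
                    "spike_z_threshold": spike_z_threshold, "segment_length": seg_len},
    )


def eeg_odq(
    ts: RegionTimeSeries,
    fs: float | None = None,
    flat_rel_threshold: float = 1e-3,
    amplitude_ratio_threshold: float = 10.0,
    hf_power_threshold: float = 0.5,
    correlation_threshold: float = 0.05,
) -> QualityReport:
    """EEG quality from 1-second segments and four artifact rules.

    Per segment: *flat* if any channel SD falls below ``flat_rel_threshold``
    times the recording's median channel SD; *artifact* if any channel's
    99th-percentile |amplitude| over median |amplitude| exceeds
    ``amplitude_ratio_threshold``; *noisy* if the fraction of spectral power
    above 30 Hz exceeds ``hf_power_threshold``; *decorrelated* if the mean
    absolute inter-channel correlation drops below ``correlation_threshold``.
    """
    if fs is None:
        if not ts.sampling_interval or ts.sampling_interval <= 0:
            raise ContractError("sampling rate unknown")
        fs = 1.0 / ts.sampling_interval
    seg_len = int(round(fs))
    X = ts.data
    if X.shape[0] < seg_len:
        raise ContractError("recording shorter than one segment")
    n_seg = X.shape[0] // seg_len
    ref_sd = float(np.median(X.std(axis=0, ddof=1)))
    flags: list[str] = []
    for s in range(n_seg):
        seg = X[s * seg_len : (s + 1) * seg_len]
        centered = seg - seg.mean(axis=0)
        sd = seg.std(axis=0, ddof=1)
        absamp = np.abs(centered)
        med_amp = np.median(absamp, axis=0)
        p99 = np.percentile(absamp, 99, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(med_amp > 0, p99 / np.where(med_amp > 0, med_amp, 1.0), np.inf)
        ratio = np.where((med_amp == 0) & (p99 == 0), 1.0, ratio)
        spec = np.abs(np.fft.rfft(centered, axis=0)) ** 2
        freqs = np.fft.rfftfreq(seg_len, d=1.0 / fs)
        total = spec[1:].sum()
        hf_frac = spec[1:][freqs[1:] > 30.0].sum() / total if total > 0 else 0.0
        if np.any(sd < flat_rel_threshold * ref_sd):
            flags.append("flat")
        elif np.any(ratio > amplitude_ratio_threshold):
            flags.append("artifact")
        elif hf_frac > hf_power_threshold:
            flags.append("noisy")
        else:
            corr = np.corrcoef(centered, rowvar=False)
            off = np.abs(corr[~np.eye(corr.shape[0], dtype=bool)])
            if np.nanmean(off) < correlation_threshold:
                flags.append("decorrelated")
            else:
                flags.append("good")
    odq = 100.0 * flags.count("good") / n_seg
    return QualityReport(
        subject_id=ts.subject_id, odq=odq, segment_flags=flags,
        parameters={"fs": fs, "flat_rel_threshold": flat_rel_threshold,
                    "amplitude_ratio_threshold": amplitude_ratio_threshold,
                    "hf_power_threshold": hf_power_threshold,
                    "correlation_threshold": correlation_threshold},
    )


def minmax_harmonize_by_scanner(
    gaps, scanner_ids
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sign-preserving per-scanner min-max scaling of brain-age gaps.

    Within each scanner, positive gaps are divided by the scanner's maximum
    positive gap and negative gaps by the absolute value of its minimum, so
    harmonized gaps lie in [-1, 1], zero maps to zero, and the within-scanner
    rank order is preserved exactly. Returns the harmonized gaps plus a
    per-scanner scale table for audit.
    """
    g = np.asarray(gaps, dtype=float)
    ids = np.asarray(scanner_ids)
    if g.size != ids.size:
        raise ContractError("gaps and scanner_ids must align")
    out = np.empty_like(g)
    rows = []
    for scanner in pd.unique(ids):
        sel = ids == scanner
        vals = g[sel]
        if vals.size < 2 or np.ptp(vals) == 0:
            raise DegenerateInputError(
                f"scanner {scanner!r} has degenerate gap spread; cannot harmonize"
            )
        pos_scale = vals.max() if vals.max() > 0 else 1.0
        neg_scale = abs(vals.min()) if vals.min() < 0 else 1.0
        scaled = np.where(vals > 0, vals / pos_scale, vals / neg_scale)
        out[sel] = scaled
        rows.append({"scanner_id": scanner, "pos_scale": pos_scale,
                     "neg_scale": neg_scale, "n": int(vals.size)})
    return out, pd.DataFrame(rows)
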