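"""End-to-end orchestration: cohort -> connectivity -> graphs -> model ->
evaluation -> importance -> exposome -> quality/harmonization.

The run is fully described by a :class:`RunConfig` (serializable to YAML)
and a seed; every stage writes its reports under the output directory and
a provenance log records the config, seed and package versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, exposome, gcn, graphs, hoi, io, quality, stats, synthetic
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "brainclock_out"
    seed: int = 0
    n_subjects: int = 120
    n_regions: int = 15
    n_timepoints: int = 300
    modality: str = "fMRI"
    n_augment: int = 100
    permutation_iterations: int = 5000
    n_bootstrap: int = 1000
    exposome_repeats: int = 2
    hidden_width: int = 64
    dropout_rate: float = 0.5
    learning_rate_grid: tuple[float, ...] = (1e-2, 1e-3)
    epoch_grid: tuple[int, ...] = (100, 200)
    stages: tuple[str, ...] = (
        "simulate", "omega", "train", "evaluate", "importance", "exposome", "quality",
    )
    manifest_path: str | None = None
    timeseries_path: str | None = None
    indicators_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("learning_rate_grid", "epoch_grid", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("learning_rate_grid", "epoch_grid", "stages"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage_durations(stage_starts: dict[str, float]) -> dict[str, float]:
    items = list(stage_starts.items())
    now = time.time()
    return {
        name: round((items[i + 1][1] if i + 1 < len(items) else now) - start, 3)
        for i, (name, start) in enumerate(items)
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the staged analysis; returns a dict of in-memory results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    results: dict = {}
    stage_times: dict[str, float] = {}
    active = set(config.stages)

    def _stage(name):
        logger.info("stage %s", name)
        stage_times[name] = time.time()

    try:
        cohort_cfg = synthetic.CohortConfig(
            n_subjects=config.n_subjects,
            n_regions=config.n_regions,
            n_timepoints=config.n_timepoints,
            modality=config.modality,
            seed=config.seed,
        )
        if "simulate" in active:
            _stage("simulate")
            strata = [
                {"count": config.n_subjects // 2, "region_group": "nonLAC"},
                {"count": config.n_subjects - config.n_subjects // 2,
                 "region_group": "LAC"},
            ]
            manifest, series = synthetic.generate_cohort(cohort_cfg, strata)
            io.write_manifest(manifest, out / "manifest.csv")
            io.write_timeseries_h5(series, out / "timeseries.h5")
        else:
            if not config.manifest_path or not config.timeseries_path:
                raise ConfigurationError(
                    "simulate disabled but manifest/timeseries paths missing"
                )
            manifest = io.read_manifest(config.manifest_path)
            series = io.read_timeseries_h5(config.timeseries_path)
        records = {r.subject_id: r for r in synthetic.manifest_to_records(manifest)}
        results["manifest"] = manifest

        if "omega" in active:
            _stage("omega")
            omegas = {
                sid: hoi.normalize_omega(hoi.omega_matrix(ts))
                for sid, ts in series.items()
            }
            samples = [graphs.build_graph(omegas[sid], records[sid]) for sid in omegas]
            samples, removed = graphs.filter_invalid(samples)
            results["omega"] = omegas
            results["removed"] = removed
        else:
            return results

        if "train" in active:
            _stage("train")
            # the age model is fitted on healthy controls only; diseased
            # subjects enter later as evaluation strata for gap biases
            hc_samples = [
                s for s in samples if s.record and s.record.diagnosis == "HC"
            ]
            split = graphs.stratified_split(hc_samples, seed=config.seed)
            train_samples = [s for s in hc_samples if s.sample_id in set(split.train_ids)]
            augmented = graphs.augment_training_set(
                train_samples, n_augment=config.n_augment, seed=config.seed
            )
            model_cfg = gcn.ModelConfig(
                hidden_width=config.hidden_width,
                dropout_rate=config.dropout_rate,
                learning_rate_grid=config.learning_rate_grid,
                epoch_grid=config.epoch_grid,
                seed=config.seed,
            )
            model, cv_report = gcn.train_with_grid_search(
                hc_samples, split, model_cfg, augmented=augmented
            )
            split.to_frame().to_csv(out / "split.csv", index=False)
            cv_report.to_csv(out / "cv_report.csv", index=False)
            io.write_model_h5(model, out / "model.h5")
            results.update(model=model, split=split, cv_report=cv_report)

        if "evaluate" in active and "train" in active:
            _stage("evaluate")
            # hold-out controls for goodness of fit; gap biases are assessed
            # on the hold-out controls plus every diseased subject
            test_samples = [s for s in samples if s.sample_id in set(split.test_ids)]
            eval_samples = test_samples + [
                s for s in samples if s.record and s.record.diagnosis != "HC"
            ]
            holdout_pred = gcn.predict(model, test_samples)
            pred = gcn.predict(model, eval_samples)
            merged = pred.frame.merge(
                manifest, left_on="sample_id", right_on="subject_id"
            )
            metrics = stats.fit_ols_metrics(
                holdout_pred.frame["age"], holdout_pred.frame["predicted"]
            )
            group_tbl = pd.concat(
                [stats.group_gap_table(merged, "region_group"),
                 stats.group_gap_table(merged, "diagnosis").rename(
                     columns={"diagnosis": "region_group"})],
                ignore_index=True,
            )
            hc = merged[merged.diagnosis == "HC"]
            lac = hc.loc[hc.region_group == "LAC", "gap"]
            non = hc.loc[hc.region_group == "nonLAC", "gap"]
            perm = None
            if len(lac) and len(non):
                perm = stats.permutation_subsample_test(
                    lac, non, iterations=config.permutation_iterations,
                    seed=config.seed,
                )
            pred.frame.to_csv(out / "predictions.csv", index=False)
            group_tbl.to_csv(out / "group_gaps.csv", index=False)
            io.write_json(
                {
                    "metrics": metrics.to_dict(),
                    "lac_vs_nonlac": None if perm is None else dataclasses.asdict(perm),
                },
                out / "metrics.json",
            )
            results.update(predictions=pred, metrics=metrics, permutation=perm,
                           test_samples=test_samples)

        if "importance" in active and "evaluate" in active and "train" in active:
            _stage("importance")
            from .importance import bootstrap_importance

            report = bootstrap_importance(
                model, results["test_samples"],
                n_bootstrap=config.n_bootstrap, seed=config.seed,
            )
            report.nodes.to_csv(out / "importance_nodes.csv", index=False)
            if report.edges is not None:
                report.edges.to_csv(out / "importance_edges.csv", index=False)
            results["importance"] = report

        if "exposome" in active and "evaluate" in active:
            _stage("exposome")
            if config.indicators_path:
                indicators = pd.read_csv(config.indicators_path)
            else:
                indicators = synthetic.synthetic_country_indicators(seed=config.seed)
                indicators.to_csv(out / "indicators.csv", index=False)
            all_pred = gcn.predict(model, samples)
            try:
                exp_report = exposome.fit_exposome_model(
                    manifest, indicators, all_pred.frame,
                    n_repeats=config.exposome_repeats, seed=config.seed,
                )
                gii_report = exposome.fit_gii_model(
                    manifest, indicators, all_pred.frame,
                    n_repeats=config.exposome_repeats, seed=config.seed,
                )
                for name, rep in (("exposome", exp_report), ("gii", gii_report)):
                    rep.metrics.to_csv(out / f"{name}_metrics.csv", index=False)
                    rep.importance.to_csv(out / f"{name}_importance.csv", index=False)
                    io.write_json(rep.significant, out / f"{name}_significant.json")
                results.update(exposome=exp_report, gii=gii_report)
            except Exception:
                logger.exception("exposome stage failed")
                raise

        if "quality" in active:
            _stage("quality")
            odq_fn = quality.fmri_odq if config.modality == "fMRI" else quality.eeg_odq
            reports = [odq_fn(ts) for ts in series.values()]
            qtable = pd.DataFrame(
                [{"subject_id": r.subject_id, "odq": r.odq} for r in reports]
            )
            qtable.to_csv(out / "quality.csv", index=False)
            results["quality"] = qtable
            if "evaluate" in active and "train" in active:
                merged = results["predictions"].frame.merge(
                    manifest, left_on="sample_id", right_on="subject_id"
                )
                harmonized, scales = quality.minmax_harmonize_by_scanner(
                    merged["gap"].to_numpy(), merged["scanner_id"].to_numpy()
                )
                merged["gap_harmonized"] = harmonized
                merged[["subject_id", "scanner_id", "gap", "gap_harmonized"]].to_csv(
                    out / "harmonized_gaps.csv", index=False
                )
                scales.to_csv(out / "scanner_scales.csv", index=False)
                results["harmonized"] = merged
    except Exception as exc:
        io.write_json(
            {"status": "failed", "stage": max(stage_times, key=stage_times.get),
             "error": str(exc)},
            out / "provenance.json",
        )
        raise

    provenance = {
        "status": "ok",
        "config_digest": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "n_train": len(results.get("split").train_ids) if "split" in results else None,
        "n_test": len(results.get("split").test_ids) if "split" in results else None,
        "n_augmented": config.n_augment if "train" in active else 0,
        "stage_seconds": _stage_durations(stage_times),
        "total_seconds": round(time.time() - t_start, 3),
    }
    io.write_json(provenance, out / "provenance.json")
    config.to_yaml(out / "config.yaml")
    results["provenance"] = provenance
    return results
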