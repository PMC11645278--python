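import pytest

from brainclock import gcn, graphs, hoi, synthetic
from brainclock.experiments import planted_node_samples


@pytest.fixture(scope="session")
def small_cohort():
    """120 healthy subjects, 12 regions, with LAC/nonLAC strata."""
    cfg = synthetic.CohortConfig(
        n_subjects=120, n_regions=12, n_timepoints=300, seed=11
    )
    strata = [
        {"count": 60, "region_group": "nonLAC", "diagnosis": "HC"},
        {"count": 60, "region_group": "LAC", "diagnosis": "HC"},
    ]
    manifest, series = synthetic.generate_cohort(cfg, strata)
    return cfg, manifest, series


@pytest.fixture(scope="session")
def graph_samples(small_cohort):
    cfg, manifest, series = small_cohort
    records = {r.subject_id: r for r in synthetic.manifest_to_records(manifest)}
    samples = [
        graphs.build_graph(hoi.normalize_omega(hoi.omega_matrix(ts)), records[sid])
        for sid, ts in series.items()
    ]
    kept, _ = graphs.filter_invalid(samples)
    return kept


@pytest.fixture(scope="session")
def trained_model(graph_samples):
    split = graphs.stratified_split(graph_samples, seed=3)
    cfg = gcn.ModelConfig(
        hidden_width=32, learning_rate_grid=(1e-2,), epoch_grid=(150,), seed=3
    )
    model, report = gcn.train_with_grid_search(graph_samples, split, cfg)
    return model, split, report


make_planted_node_samples = planted_node_samples
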