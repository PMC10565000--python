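"""CD8 gating, clustering-antibody selection, Louvain partition, naming."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from citegate import (
    CD8_GATE,
    DEFAULT_NAMING_RULES,
    ConfigurationError,
    GateRule,
    apply_gate,
    cluster_cells,
    name_clusters,
    select_clustering_antibodies,
)
from citegate.panel import CD8_POPULATION_NAMES


@pytest.fixture(scope="module")
def cd8_gate_mask(normalized, experiment, threshold_table):
    return apply_gate(normalized.adt_clr, experiment.antibody_names,
                      threshold_table, CD8_GATE)


@pytest.fixture(scope="module")
def cd8_clustering(normalized, experiment, threshold_table, cd8_gate_mask):
    clr = normalized.adt_clr[cd8_gate_mask]
    selected = select_clustering_antibodies(
        experiment.antibody_names, clr, threshold_table, gate_rule=CD8_GATE)
    cols = [experiment.antibody_names.index(a) for a in selected]
    result = cluster_cells(clr[:, cols])
    named = name_clusters(result, clr, experiment.antibody_names,
                          threshold_table, DEFAULT_NAMING_RULES)
    return selected, named


def test_gate_retains_cd8_and_rejects_other_lineages(cd8_gate_mask, truth,
                                                     singlet_mask):
    pop = truth.population[singlet_mask]
    gated = cd8_gate_mask[singlet_mask]
    is_cd8 = np.isin(pop, CD8_POPULATION_NAMES)
    assert gated[is_cd8].mean() >= 0.95          # CD3+CD8+ subsets retained
    assert gated[~is_cd8].mean() <= 0.02         # CD4 T, B, myeloid rejected


def test_gate_is_idempotent(normalized, experiment, threshold_table, cd8_gate_mask):
    again = apply_gate(normalized.adt_clr[cd8_gate_mask],
                       experiment.antibody_names, threshold_table, CD8_GATE)
    assert again.all()


def test_empty_gate_retains_all_cells(normalized, experiment, threshold_table):
    mask = apply_gate(normalized.adt_clr, experiment.antibody_names,
                      threshold_table, GateRule("all", set(), set()))
    assert mask.all()


def test_gate_with_missing_threshold_raises(normalized, experiment):
    from citegate import ThresholdTable

    with pytest.raises(ConfigurationError, match="CD3"):
        apply_gate(normalized.adt_clr, experiment.antibody_names,
                   ThresholdTable(), GateRule("x", {"CD3"}, set()))


def test_gate_negatives_excluded_from_clustering_panel(cd8_clustering):
    selected, _ = cd8_clustering
    assert "CD19" not in selected and "CD4" not in selected
    assert "CD14" not in selected and "CD16" not in selected
    assert len(selected) >= 3


def test_clustering_recovers_planted_phenotypes(cd8_clustering, cd8_gate_mask, truth):
    _, named = cd8_clustering
    ari = adjusted_rand_score(truth.population[cd8_gate_mask], named.labels)
    assert ari >= 0.9


def test_clustering_deterministic_under_seed(normalized, experiment,
                                             threshold_table, cd8_gate_mask):
    clr = normalized.adt_clr[cd8_gate_mask][:, :10]
    r1 = cluster_cells(clr, seed=42)
    r2 = cluster_cells(clr, seed=42)
    np.testing.assert_array_equal(r1.labels, r2.labels)


def test_identical_cells_form_single_cluster():
    x = np.zeros((200, 5))
    res = cluster_cells(x)
    assert res.n_clusters == 1


def test_nonpositive_resolution_rejected():
    with pytest.raises(ValueError):
        cluster_cells(np.random.default_rng(0).normal(size=(100, 5)), resolution=0.0)


def test_cluster_ids_contiguous_and_sizes_sum(cd8_clustering, cd8_gate_mask):
    _, named = cd8_clustering
    assert named.labels.min() == 0
    assert set(np.unique(named.labels)) == set(range(named.n_clusters))
    assert named.sizes().sum() == int(cd8_gate_mask.sum())


def test_planted_populations_named_correctly(cd8_clustering, cd8_gate_mask, truth):
    """Each planted CD8 phenotype's majority cluster carries its name."""
    _, named = cd8_clustering
    pops = truth.population[cd8_gate_mask]
    for pop in ["Naive", "Em", "Emra", "MAIT", "CD38+ Emra"]:
        in_pop = pops == pop
        if in_pop.sum() < 20:
            continue
        majority = np.bincount(named.labels[in_pop]).argmax()
        assert named.name_of(int(majority)) == pop


def test_unmatched_cluster_is_unassigned(normalized, experiment, threshold_table):
    """A partition over cells that satisfy no naming rule yields 'unassigned'."""
    rng = np.random.default_rng(0)
    clr = rng.normal(-1.0, 0.1, size=(100, len(experiment.antibody_names)))
    from citegate.clustering import ClusterResult

    res = ClusterResult(labels=np.zeros(100, dtype=int), names={},
                        positive_fraction=None, mean_clr=None, embedding=None)
    named = name_clusters(res, clr, experiment.antibody_names, threshold_table,
                          DEFAULT_NAMING_RULES)
    assert named.name_of(0) == "unassigned"


def test_lineage_conflicted_cluster_flagged_likely_doublet(
        experiment, threshold_table):
    """Cells positive for both CD3 and CD14 mark their cluster as a likely
    doublet cluster."""
    n = 80
    clr = np.full((n, len(experiment.antibody_names)), -2.0)
    for ab in ("CD3", "CD14", "CD8", "CD33"):
        j = experiment.antibody_names.index(ab)
        clr[:, j] = threshold_table.get(ab) + 1.0
    from citegate.clustering import ClusterResult

    res = ClusterResult(labels=np.zeros(n, dtype=int), names={},
                        positive_fraction=None, mean_clr=None, embedding=None)
    named = name_clusters(res, clr, experiment.antibody_names, threshold_table,
                          DEFAULT_NAMING_RULES)
    assert named.likely_doublet[0]
    assert named.name_of(0) == "likely doublet"
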