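"""Differential expression: exact rank-sum oracle, filters, planted effects."""

import itertools

import numpy as np
import pandas as pd
import pytest

from citegate import SimConfig, apply_de_filters, find_markers, normalize_rna, simulate_experiment
from citegate.de import expressing_proportions, per_cluster_de
from citegate.panel import CD8_POPULATION_NAMES
from citegate.stats import bonferroni, rank_sum_test
from scipy import stats as sps


def brute_force_rank_sum_p(x, y):
    """Independent oracle: enumerate every group-1 assignment of the pooled
    values and count rank sums at least as far from the mean as observed."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    n = len(pooled)
    mu = n1 * (n + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for comb in itertools.combinations(range(n), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


@pytest.mark.parametrize("seed,n1,n2,ties", [
    (0, 5, 5, False), (1, 8, 6, False), (2, 12, 12, False),
    (3, 6, 6, True), (4, 10, 7, True), (5, 12, 9, True),
])
def test_exact_wilcoxon_matches_enumeration_oracle(seed, n1, n2, ties):
    rng = np.random.default_rng(seed)
    if ties:
        x = rng.integers(0, 4, n1).astype(float)
        y = rng.integers(0, 4, n2).astype(float)
    else:
        x = rng.normal(0, 1, n1)
        y = rng.normal(0.8, 1, n2)
    _, p = rank_sum_test(x, y)
    assert p == pytest.approx(brute_force_rank_sum_p(x, y), abs=1e-9)


def test_identical_groups_give_p_one_and_zero_lfc():
    x = np.tile([[1.0, 0.0]], (20, 1))
    table = find_markers(x, np.arange(10), np.arange(10, 20), ["G1", "G2"],
                         tested_genes=["G1", "G2"])
    assert (table["p_raw"] == 1.0).all()
    assert (table["avg_log2FC"] == 0.0).all()


def test_avg_log2fc_antisymmetric_under_group_swap():
    rng = np.random.default_rng(6)
    x = rng.gamma(2, 1, size=(60, 4))
    g1, g2 = np.arange(30), np.arange(30, 60)
    genes = [f"G{i}" for i in range(4)]
    t12 = find_markers(x, g1, g2, genes, tested_genes=genes)
    t21 = find_markers(x, g2, g1, genes, tested_genes=genes)
    np.testing.assert_allclose(t12["avg_log2FC"], -t21["avg_log2FC"], atol=1e-12)
    np.testing.assert_allclose(t12["p_raw"], t21["p_raw"], atol=1e-12)


def test_bonferroni_cap_and_monotonicity():
    assert bonferroni(0.01, 485) == 1.0            # 0.01 * 485 caps at 1
    p = np.array([1e-6, 1e-4, 0.2])
    adj = bonferroni(p, 485)
    assert (np.diff(adj) >= 0).all()
    assert (adj >= p).all()


@pytest.mark.parametrize("row,kept", [
    (dict(p_adj_bonferroni=0.04, avg_log2FC=0.3, pct1=0.5, pct2=0.1), True),   # ratio 5
    (dict(p_adj_bonferroni=0.06, avg_log2FC=0.3, pct1=0.5, pct2=0.1), False),  # p too high
    (dict(p_adj_bonferroni=0.04, avg_log2FC=0.3, pct1=0.2, pct2=0.1), False),  # ratio 2
    (dict(p_adj_bonferroni=0.04, avg_log2FC=-0.1, pct1=0.5, pct2=0.1), False), # down
    (dict(p_adj_bonferroni=0.04, avg_log2FC=0.3, pct1=0.2, pct2=0.0), True),   # pct2=0 passes
])
def test_de_filter_rules(row, kept):
    table = pd.DataFrame([dict(gene="G", **row)])
    out = apply_de_filters(table, p_cutoff=0.05, lfc_cutoff=0.0, pct_ratio_cutoff=2.5)
    assert (len(out) == 1) == kept


@pytest.fixture(scope="module")
def de_experiment():
    config = SimConfig(rng_seed=5, doublet_rate=0.0, discriminative_genes=[],
                       n_cells_per_subject=25)
    experiment, truth = simulate_experiment(config)
    rna_norm = normalize_rna(experiment.rna)
    groups = experiment.subject_meta["group"]
    condition = np.array([groups[s] for s in truth.subject], dtype=object)
    cd8 = np.isin(truth.population, CD8_POPULATION_NAMES)
    return experiment, truth, rna_norm, condition, cd8


def test_planted_de_genes_recovered(de_experiment):
    experiment, truth, rna_norm, condition, cd8 = de_experiment
    table = find_markers(rna_norm, cd8 & (condition == "CAD_high"),
                         cd8 & (condition == "CAD_low"), experiment.gene_names)
    sig = apply_de_filters(table)
    planted = {g for g, _ in truth.de_genes}
    hits = set(sig["gene"]) & planted
    false = set(sig["gene"]) - planted
    assert len(hits) / len(planted) >= 0.9
    assert len(false) / (table.attrs["n_tested"] - len(planted)) <= 0.05


def test_label_shuffle_controls_familywise_error(de_experiment):
    experiment, _, rna_norm, condition, cd8 = de_experiment
    rng = np.random.default_rng(0)
    idx = np.flatnonzero(cd8)[:400]
    fractions = []
    for _ in range(30):
        perm = rng.permutation(idx)
        m1, m2 = perm[:200], perm[200:]
        table = find_markers(rna_norm, m1, m2, experiment.gene_names)
        fractions.append((table["p_adj_bonferroni"] < 0.05).mean())
    assert np.mean(fractions) <= 0.05


def test_per_cluster_de_skips_thin_clusters(de_experiment):
    experiment, _, rna_norm, condition, cd8 = de_experiment
    labels = np.zeros(experiment.n_cells, dtype=int)
    labels[:5] = 1                               # cluster 1 far below the minimum
    tables = per_cluster_de(rna_norm, labels, condition, experiment.gene_names,
                            min_cells_per_condition=10)
    assert 0 in tables and 1 not in tables


def test_de_planted_in_one_population_localizes_there():
    config = SimConfig(rng_seed=13, doublet_rate=0.0, discriminative_genes=[],
                       de_populations=["CD38+ Emra"], n_cells_per_subject=40)
    experiment, truth = simulate_experiment(config)
    rna_norm = normalize_rna(experiment.rna)
    groups = experiment.subject_meta["group"]
    condition = np.array([groups[s] for s in truth.subject], dtype=object)
    labels, uniq = pd.factorize(truth.population)
    tables = per_cluster_de(rna_norm, labels, condition, experiment.gene_names)
    planted = {g for g, _ in truth.de_genes}
    target = tables[list(uniq).index("CD38+ Emra")]
    target_sig = set(apply_de_filters(target)["gene"])
    assert len(target_sig & planted) >= 5        # effect found where planted
    for name in ("Naive", "Em"):
        other = tables[list(uniq).index(name)]
        other_sig = apply_de_filters(other)
        assert len(other_sig) / other.attrs["n_tested"] <= 0.05


def test_expressing_proportions_and_rank_test(de_experiment):
    experiment, truth, _, condition, cd8 = de_experiment
    labels = np.zeros(experiment.n_cells, dtype=int)
    groups = experiment.subject_meta["group"]
    fracs, tests = expressing_proportions(
        experiment.rna, labels, truth.subject, groups,
        ["GZMB"], experiment.gene_names)
    assert ((fracs["fraction"] >= 0) & (fracs["fraction"] <= 1)).all()
    assert len(fracs) == experiment.subject_meta.shape[0]
    # planted GZMB up-regulation in cases shows up at the subject level
    assert tests["p"].iloc[0] < 0.001


def test_identical_fractions_give_p_one():
    subjects = np.array([f"S{i}" for i in range(12)] * 10, dtype=object)
    groups = pd.Series(["CAD_high"] * 6 + ["CAD_low"] * 6,
                       index=[f"S{i}" for i in range(12)])
    counts = np.ones((120, 1), dtype=int)        # everyone expresses the gene
    labels = np.zeros(120, dtype=int)
    fracs, tests = expressing_proportions(counts, labels, subjects, groups,
                                          ["G"], ["G"])
    assert (fracs["fraction"] == 1.0).all()
    assert tests["p"].iloc[0] == 1.0
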