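"""Generator invariants: planted truth must be consistent with the data."""

import numpy as np
import pytest

from citegate import ConfigurationError, SimConfig, clr_normalize_adt, simulate_experiment
from citegate.panel import PopulationSpec, default_populations


def small_config(**kw):
    defaults = dict(n_subjects=8, n_cases=4, subjects_per_plate=4,
                    n_genes=60, n_cells_per_subject=30, rng_seed=3)
    defaults.update(kw)
    return SimConfig(**defaults)


def test_zero_doublet_rate_plants_no_doublets():
    _, truth = simulate_experiment(small_config(doublet_rate=0.0))
    assert truth.is_doublet.sum() == 0


def test_fixed_seed_reproduces_bit_identical_matrices():
    e1, t1 = simulate_experiment(small_config(rng_seed=42))
    e2, t2 = simulate_experiment(small_config(rng_seed=42))
    assert (e1.rna != e2.rna).nnz == 0
    np.testing.assert_array_equal(e1.adt, e2.adt)
    np.testing.assert_array_equal(e1.tags, e2.tags)
    np.testing.assert_array_equal(t1.population, t2.population)
    assert t1.true_thresholds == t2.true_thresholds


def test_invalid_population_frequencies_rejected():
    pops = default_populations()
    pops[0].frequency = 0.5   # frequencies no longer sum to 1
    with pytest.raises(ConfigurationError):
        simulate_experiment(small_config(populations=pops))


def test_unknown_effect_gene_rejected():
    with pytest.raises(ConfigurationError):
        simulate_experiment(small_config(de_genes=[("NOT_A_GENE", 1.0)]))


def test_marker_positive_cells_exceed_true_threshold(experiment, truth,
                                                     singlet_mask, true_threshold_vector):
    """At the default (~6 SD) separation, virtually every marker-positive
    singlet lies above the planted threshold."""
    clr = clr_normalize_adt(experiment.adt)[singlet_mask]
    pos = truth.marker_positive_matrix(experiment.antibody_names)[singlet_mask]
    for j in range(len(experiment.antibody_names)):
        if pos[:, j].any():
            frac = (clr[pos[:, j], j] > true_threshold_vector[j]).mean()
            assert frac >= 0.99


def test_adt_components_separated_by_configured_shift(experiment, truth,
                                                      singlet_mask, sim_default):
    """Mean CLR difference between marker-positive and -negative singlets
    matches the configured log2 shift within Monte-Carlo tolerance."""
    config = sim_default[0]
    clr = clr_normalize_adt(experiment.adt)[singlet_mask]
    pos = truth.marker_positive_matrix(experiment.antibody_names)[singlet_mask]
    gaps = []
    for j in range(len(experiment.antibody_names)):
        if pos[:, j].sum() >= 50 and (~pos[:, j]).sum() >= 50:
            gaps.append(clr[pos[:, j], j].mean() - clr[~pos[:, j], j].mean())
    assert np.allclose(np.mean(gaps), config.positive_adt_shift, atol=0.3)


def test_doublets_have_larger_library_sizes(experiment, truth):
    lib = np.asarray(experiment.rna.sum(axis=1)).ravel()
    assert np.median(lib[truth.is_doublet]) > np.median(lib[~truth.is_doublet])


def test_every_doublet_records_mechanism(truth):
    kinds = truth.doublet_kind[truth.is_doublet]
    assert set(kinds) <= {"tag", "transcriptomic", "biological"}
    assert (kinds != "").all()


def test_true_thresholds_lie_between_component_means(experiment, truth, singlet_mask):
    clr = clr_normalize_adt(experiment.adt)[singlet_mask]
    pos = truth.marker_positive_matrix(experiment.antibody_names)[singlet_mask]
    for j, ab in enumerate(experiment.antibody_names):
        t = truth.true_thresholds[ab]
        if np.isnan(t):
            continue
        lo = clr[~pos[:, j], j].mean()
        hi = clr[pos[:, j], j].mean()
        assert lo < t < hi


def test_planted_de_effect_recovered_in_raw_means():
    """Case/control mean ratio of planted DE genes matches the configured
    log2 effect within +-0.2 at 200 cells per subject."""
    config = SimConfig(n_subjects=20, n_cases=10, n_cells_per_subject=200,
                       doublet_rate=0.0, discriminative_genes=[], rng_seed=9)
    experiment, truth = simulate_experiment(config)
    case = np.isin(truth.subject, truth.case_subjects)
    rna = np.asarray(experiment.rna.todense(), dtype=float)
    gi = {g: j for j, g in enumerate(experiment.gene_names)}
    for gene, effect in truth.de_genes:
        ratio = np.log2(rna[case, gi[gene]].mean() / rna[~case, gi[gene]].mean())
        assert abs(ratio - effect) <= 0.2, gene
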