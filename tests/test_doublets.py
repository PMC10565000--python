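"""Demultiplexing, artificial-nearest-neighbor scoring, biological doublets."""

import numpy as np
import pytest

from citegate import (
    ConfigurationError,
    GateRule,
    apply_gate,
    assign_subjects,
    demultiplex_by_tags,
    remove_biological_doublets,
    score_doublets_ann,
)


def _tag_matrix(rows, n_pad=200, seed=0):
    """Pad hand-written rows with clearly separated background singlets so the
    per-tag mixture fits have enough data."""
    rng = np.random.default_rng(seed)
    n_tags = len(rows[0])
    pad = rng.poisson(1.5, size=(n_pad, n_tags))
    own = rng.integers(0, n_tags, size=n_pad)
    pad[np.arange(n_pad), own] += rng.poisson(400, size=n_pad)
    return np.vstack([np.array(rows), pad])


def test_single_dominant_tag_is_singlet():
    tags = _tag_matrix([[500, 2, 1, 3]])
    res = demultiplex_by_tags(tags, ["ST1", "ST2", "ST3", "ST4"])
    assert res.call[0] == "singlet" and res.tag[0] == "ST1"


def test_two_dominant_tags_is_multiplet():
    tags = _tag_matrix([[500, 480, 1, 2]])
    res = demultiplex_by_tags(tags, ["ST1", "ST2", "ST3", "ST4"])
    assert res.call[0] == "multiplet"


def test_no_positive_tag_is_undetermined():
    tags = _tag_matrix([[0, 1, 0, 2]])
    res = demultiplex_by_tags(tags, ["ST1", "ST2", "ST3", "ST4"])
    assert res.call[0] == "undetermined"


def test_demux_recovers_planted_multiplets(experiment, truth):
    res = demultiplex_by_tags(experiment.tags, experiment.tag_names)
    is_tag_multiplet = truth.doublet_kind == "tag"
    singlets = ~truth.is_doublet
    recall = (res.call[is_tag_multiplet] == "multiplet").mean()
    false_rate = (res.call[singlets] == "multiplet").mean()
    assert recall >= 0.95
    assert false_rate <= 0.02


def test_demux_subject_assignment_matches_truth(experiment, truth):
    res = demultiplex_by_tags(experiment.tags, experiment.tag_names)
    subj = assign_subjects(res, experiment.cell_meta["plate"].to_numpy(),
                           experiment.subject_meta)
    singlets = (~truth.is_doublet) & res.is_singlet
    assert (subj[singlets].to_numpy() == truth.subject[singlets]).all()


def test_ann_scores_deterministic_and_bounded(experiment):
    s1 = score_doublets_ann(experiment.rna, seed=7)
    s2 = score_doublets_ann(experiment.rna, seed=7)
    np.testing.assert_array_equal(s1.score, s2.score)
    np.testing.assert_array_equal(s1.flagged, s2.flagged)
    assert (s1.score >= 0).all() and (s1.score <= 1).all()


def test_ann_zero_expected_rate_flags_nothing(experiment):
    s = score_doublets_ann(experiment.rna, expected_rate=0.0, seed=0)
    assert s.flagged.sum() == 0


def test_ann_flagged_fraction_tracks_expected_rate(experiment):
    s = score_doublets_ann(experiment.rna, expected_rate=0.05, seed=0)
    assert abs(s.flagged.mean() - 0.05) <= 0.025


def test_ann_scores_permutation_equivariant(experiment):
    x = np.asarray(experiment.rna.todense())[:600]
    rng = np.random.default_rng(0)
    perm = rng.permutation(x.shape[0])
    s = score_doublets_ann(x, seed=3)
    sp = score_doublets_ann(x[perm], seed=3)
    np.testing.assert_allclose(sp.score, s.score[perm])


def test_ann_k_must_be_below_cell_count(experiment):
    with pytest.raises(ValueError):
        score_doublets_ann(experiment.rna[:150], k=150, seed=0)


def test_ann_enriches_planted_heterotypic_doublets(experiment, truth):
    s = score_doublets_ann(experiment.rna, expected_rate=0.05, seed=0)
    heterotypic = np.isin(truth.doublet_kind, ["transcriptomic", "biological"])
    recall = s.flagged[heterotypic].mean()
    enrichment = recall / max(s.flagged.mean(), 1e-12)
    assert recall >= 0.6
    assert enrichment >= 5.0


def test_biological_doublets_removed_behind_cd8_gate(
        experiment, truth, normalized, threshold_table):
    """Planted CD8 x myeloid doublets pass a CD3+CD8+ gate but trip >= 2
    myeloid conflict markers and are removed."""
    reduced_gate = GateRule("CD8 loose", {"CD3", "CD8"}, set())
    gated = apply_gate(normalized.adt_clr, experiment.antibody_names,
                       threshold_table, reduced_gate)
    bio = truth.doublet_kind == "biological"
    gated_bio = gated & bio
    assert gated_bio.sum() >= 10    # the gate alone does not remove them
    keep, log = remove_biological_doublets(
        normalized.adt_clr[gated], experiment.antibody_names, threshold_table,
        conflict_markers=["CD14", "CD33", "CD11C"])
    removed_frac = (~keep)[bio[gated]].mean()
    assert removed_frac >= 0.9
    assert all(len(entry["conflicting_markers"]) >= 2 for entry in log)
    # ordinary CD8 singlets below all myeloid thresholds are retained
    clean = (~truth.is_doublet[gated]) & (truth.population[gated] == "Naive")
    assert keep[clean].mean() >= 0.98


def test_conflict_marker_without_threshold_is_configuration_error(
        experiment, normalized, threshold_table):
    with pytest.raises(ConfigurationError):
        remove_biological_doublets(
            normalized.adt_clr, experiment.antibody_names, threshold_table,
            conflict_markers=["NOT_AN_ANTIBODY"])


def test_stage_cascade_only_removes_cells(experiment):
    """Each removal stage yields a subset of the previous cell set."""
    res = demultiplex_by_tags(experiment.tags, experiment.tag_names)
    n0 = experiment.n_cells
    n1 = int(res.is_singlet.sum())
    sub = experiment.subset_cells(res.is_singlet)
    s = score_doublets_ann(sub.rna, expected_rate=0.05, seed=0)
    n2 = int((~s.flagged).sum())
    assert n0 >= n1 >= n2
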