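"""Mixture EM, threshold placement and the threshold table."""

import numpy as np
import pytest

from citegate import (
    FitError,
    MixtureFit,
    build_threshold_table,
    fit_two_component_mixture,
    threshold_from_mixture,
    threshold_from_negative_reference,
)
from citegate.experiment import NormalizedMatrices


def test_em_recovers_well_separated_components():
    """Estimates for 0.5 N(0,1) + 0.5 N(6,1) land within ~3 SE of truth."""
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(0, 1, 2500), rng.normal(6, 1, 2500)])
    fit = fit_two_component_mixture(x)
    assert fit.converged
    assert -0.15 <= fit.mu1 <= 0.15
    assert 5.85 <= fit.mu2 <= 6.15
    assert 0.45 <= fit.pi1 <= 0.55


def test_em_exact_on_two_point_masses():
    x = np.array([0.0] * 100 + [6.0] * 100)
    fit = fit_two_component_mixture(x, sigma_min=0.1)
    assert fit.mu1 == pytest.approx(0.0, abs=1e-6)
    assert fit.mu2 == pytest.approx(6.0, abs=1e-6)
    assert fit.pi1 == pytest.approx(0.5, abs=1e-6)


def test_single_component_is_flagged_ill_separated():
    rng = np.random.default_rng(1)
    fit = fit_two_component_mixture(rng.normal(0, 1, 2000))
    assert fit.ill_separated
    assert fit.mu2 - fit.mu1 < max(fit.sigma1, fit.sigma2)


def test_degenerate_input_raises():
    with pytest.raises(FitError):
        fit_two_component_mixture(np.full(100, 3.0))
    with pytest.raises(FitError):
        fit_two_component_mixture(np.arange(10))   # too few values


def test_symmetric_mixture_threshold_is_midpoint():
    fit = MixtureFit(pi1=0.5, pi2=0.5, mu1=0.0, mu2=6.0, sigma1=1.0, sigma2=1.0,
                     log_likelihood=0.0, n_iter=1, converged=True)
    assert threshold_from_mixture(fit) == pytest.approx(3.0, abs=1e-6)


def test_weighted_mixture_threshold_matches_closed_form():
    # pi1 phi(t;0,1) = pi2 phi(t;6,1)  =>  t = 3 + ln(pi1/pi2)/6
    fit = MixtureFit(pi1=0.9, pi2=0.1, mu1=0.0, mu2=6.0, sigma1=1.0, sigma2=1.0,
                     log_likelihood=0.0, n_iter=1, converged=True)
    expected = 3.0 + np.log(9.0) / 6.0
    assert threshold_from_mixture(fit) == pytest.approx(expected, abs=1e-6)


def test_vanishing_separation_threshold_tends_to_midpoint():
    fit = MixtureFit(pi1=0.5, pi2=0.5, mu1=2.0, mu2=2.0 + 1e-13, sigma1=1.0,
                     sigma2=1.0, log_likelihood=0.0, n_iter=1, converged=True)
    assert threshold_from_mixture(fit) == pytest.approx(2.0, abs=1e-6)


def test_threshold_shift_invariance():
    """Adding a constant to the data shifts the threshold by that constant."""
    rng = np.random.default_rng(2)
    x = np.concatenate([rng.normal(0, 1, 1500), rng.normal(5, 1, 800)])
    t0 = threshold_from_mixture(fit_two_component_mixture(x))
    t7 = threshold_from_mixture(fit_two_component_mixture(x + 7.0))
    assert t7 - t0 == pytest.approx(7.0, abs=1e-6)


def test_negative_reference_quantile():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 200_000)
    assert threshold_from_negative_reference(x, 0.99) == pytest.approx(2.326, abs=0.03)
    assert threshold_from_negative_reference(np.full(100, 4.2), 0.99) == 4.2
    sym = np.concatenate([x, -x])
    assert threshold_from_negative_reference(sym, 0.5) == pytest.approx(0.0, abs=1e-6)


def test_negative_reference_needs_enough_cells():
    with pytest.raises(FitError):
        threshold_from_negative_reference(np.zeros(10), 0.99)


def test_threshold_table_recovers_planted_thresholds(
        threshold_table, experiment, true_threshold_vector):
    """All 49 antibodies determined, each within 0.25 CLR units of truth."""
    assert threshold_table.undetermined() == []
    est = threshold_table.as_vector(experiment.antibody_names)
    assert np.max(np.abs(est - true_threshold_vector)) < 0.25


def test_unimodal_antibody_flagged_undetermined():
    rng = np.random.default_rng(4)
    n = 2000
    clr = np.column_stack([
        np.concatenate([rng.normal(0, 0.4, n // 2), rng.normal(3, 0.4, n - n // 2)]),
        rng.normal(0, 0.4, n),               # ambient only: no structure
    ])
    norm = NormalizedMatrices(adt_clr=clr, rna_norm=np.zeros((n, 1)))
    table = build_threshold_table(norm, ["AB_BIMODAL", "AB_FLAT"])
    assert table.is_determined("AB_BIMODAL")
    assert not table.is_determined("AB_FLAT")
    assert table.undetermined() == ["AB_FLAT"]


def test_per_context_thresholds_follow_planted_shift():
    """Two cell types with positives shifted differently get different
    thresholds, in the planted direction."""
    rng = np.random.default_rng(5)
    n = 3000
    ctx = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
    neg = rng.normal(0, 0.4, n)
    pos_shift = np.where(ctx == "A", 3.0, 5.0)
    is_pos = rng.random(n) < 0.4
    values = np.where(is_pos, neg + pos_shift, neg)
    norm = NormalizedMatrices(adt_clr=values[:, None], rna_norm=np.zeros((n, 1)))
    table = build_threshold_table(norm, ["AB"], cell_type_map=ctx)
    ta, tb = table.get("AB", "A"), table.get("AB", "B")
    assert ta < tb
    assert ta == pytest.approx(1.5, abs=0.5)
    assert tb == pytest.approx(2.5, abs=0.7)


def test_negative_reference_fallback_used_when_mixture_fails():
    rng = np.random.default_rng(6)
    n = 2000
    ctx = np.array(["T"] * (n // 2) + ["B"] * (n // 2))
    # antibody flat in both contexts -> mixture fails; B cells serve as the
    # known-negative reference for the T-context threshold
    values = rng.normal(0, 0.5, n)
    norm = NormalizedMatrices(adt_clr=values[:, None], rna_norm=np.zeros((n, 1)))
    table = build_threshold_table(norm, ["CD3"], cell_type_map=ctx,
                                  negative_reference={"CD3": "B"})
    assert table.is_determined("CD3", "T")
    row = table.table[(table.table.antibody == "CD3") & (table.table.context == "T")]
    assert row["method"].iloc[0] == "negative_reference"
    expected = np.quantile(values[ctx == "B"], 0.99)
    assert table.get("CD3", "T") == pytest.approx(expected, abs=1e-9)
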