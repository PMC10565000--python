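"""Synthetic multiplexed CITE-seq experiments with planted ground truth.

The generator emulates a hash-tagged case/control study design: subjects
assigned round-robin to multi-sample plates, a targeted RNA panel with
negative-binomial counts, a 49-antibody surface panel whose CLR-transformed
values form two well-separated near-normal components per antibody, one
dominant sample tag per singlet, and planted doublets of three kinds
(tag-multiplet, transcriptomic, biological CD8 x myeloid) formed by summing
the raw counts of two constituent cells from the same plate.

Every planted quantity — per-cell population, doublet flags and mechanisms,
per-antibody positivity thresholds, case/control effect genes — is recorded
in a :class:`GroundTruth` so downstream stages can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from . import panel as panel_defaults
from .errors import ConfigurationError
from .experiment import CellExperiment
from .normalize import clr_normalize_adt
from .panel import PopulationSpec

DOUBLET_KINDS = ("tag", "transcriptomic", "biological")


@dataclass
class SimConfig:
    """Study-design parameters for one simulated experiment.

    Defaults mirror the emulated cohort: 60 subjects (30 cases by Gensini
    score), 4 subjects multiplexed per plate, a 496-gene / 49-antibody
    panel, and antibody signal separated from ambient background by
    ``positive_adt_shift`` log2 units (~7 component SDs at the default
    ``adt_log2_sd``, comfortably above the 3-SD design floor).
    """

    n_subjects: int = 60
    n_cases: int = 30
    subjects_per_plate: int = 4
    n_genes: int = panel_defaults.N_GENES_DEFAULT
    n_antibodies: int = panel_defaults.N_ANTIBODIES_DEFAULT
    n_cells_per_subject: int = 60
    populations: list[PopulationSpec] = field(default_factory=panel_defaults.default_populations)
    de_genes: list[tuple[str, float]] = field(
        default_factory=lambda: list(panel_defaults.DEFAULT_DE_GENES))
    discriminative_genes: list[tuple[str, float]] = field(
        default_factory=lambda: list(panel_defaults.DEFAULT_DISCRIMINATIVE_GENES))
    de_populations: list[str] | None = None   # None -> effects in all populations
    doublet_rate: float = 0.05
    doublet_kind_fractions: dict[str, float] = field(
        default_factory=lambda: {"tag": 0.4, "transcriptomic": 0.4, "biological": 0.2})
    ambient_adt_mean: float = 30.0            # ambient/background ADT counts
    positive_adt_shift: float = 3.0           # log2 shift of the positive component
    adt_log2_sd: float = 0.35                 # biological SD of log2 ADT intensity
    rna_dispersion: float = 0.5               # NB dispersion (var = m + a*m^2)
    tag_signal_mean: float = 400.0            # dominant sample-tag counts
    tag_background_mean: float = 1.5          # off-target tag counts
    batch_log2_sd: float = 0.05               # per-plate multiplicative ADT offset
    # each population additionally up-regulates a disjoint random block of
    # panel genes, emulating subset-specific transcriptional programs
    n_program_genes: int = 30
    program_fold_range: tuple[float, float] = (2.0, 6.0)
    rng_seed: int = 0

    @property
    def n_plates(self) -> int:
        return math.ceil(self.n_subjects / self.subjects_per_plate)

    def validate(self) -> None:
        if self.n_cases > self.n_subjects:
            raise ConfigurationError("n_cases exceeds n_subjects")
        if not (0.0 <= self.doublet_rate < 0.5):
            raise ConfigurationError("doublet_rate must lie in [0, 0.5)")
        freq = sum(p.frequency for p in self.populations)
        if abs(freq - 1.0) > 1e-6:
            raise ConfigurationError(
                f"population frequencies sum to {freq:.6f}, expected 1")
        genes = set(self.gene_names())
        for g, _ in list(self.de_genes) + list(self.discriminative_genes):
            if g not in genes:
                raise ConfigurationError(f"effect gene {g!r} not in simulated panel")
        abs_ = set(self.antibody_names())
        for p in self.populations:
            unknown = (p.positive_markers | p.negative_markers) - abs_
            if unknown:
                raise ConfigurationError(
                    f"population {p.name!r} references unknown antibodies {sorted(unknown)}")
        if self.de_populations is not None:
            names = {p.name for p in self.populations}
            unknown = set(self.de_populations) - names
            if unknown:
                raise ConfigurationError(f"de_populations not simulated: {sorted(unknown)}")
        kf = self.doublet_kind_fractions
        if set(kf) - set(DOUBLET_KINDS) or abs(sum(kf.values()) - 1.0) > 1e-6:
            raise ConfigurationError("doublet_kind_fractions must cover tag/"
                                     "transcriptomic/biological and sum to 1")

    def gene_names(self) -> list[str]:
        return panel_defaults.gene_names(self.n_genes)

    def antibody_names(self) -> list[str]:
        return panel_defaults.antibody_names(self.n_antibodies)

    def tag_names(self) -> list[str]:
        return [f"ST{i + 1}" for i in range(self.subjects_per_plate)]


@dataclass
class GroundTruth:
    """Planted truth for one simulated experiment (singlets + doublets)."""

    population: np.ndarray            # per-cell population name ("doublet" for doublets)
    subject: np.ndarray               # per-cell generating subject id
    is_doublet: np.ndarray            # per-cell bool
    doublet_kind: np.ndarray          # per-cell "", "tag", "transcriptomic", "biological"
    doublet_partner_populations: np.ndarray  # per-cell "popA+popB" or ""
    true_thresholds: dict[str, float]        # antibody -> CLR-log2 threshold
    positive_markers: dict[str, list[str]]   # population -> effective positive antibody set
    de_genes: list[tuple[str, float]]
    discriminative_genes: list[tuple[str, float]]
    case_subjects: list[str]

    def __post_init__(self) -> None:
        if (self.is_doublet & (self.doublet_kind == "")).any():
            raise ValueError("every flagged doublet must record its mechanism")

    def marker_positive_matrix(self, antibodies: list[str]) -> np.ndarray:
        """Boolean cells x antibodies matrix of planted marker positivity.

        Doublets are positive for the union of their constituents' markers.
        """
        pos = np.zeros((len(self.population), len(antibodies)), dtype=bool)
        ab_index = {a: j for j, a in enumerate(antibodies)}
        for i, (pop, kind, partners) in enumerate(
                zip(self.population, self.doublet_kind, self.doublet_partner_populations)):
            pops = partners.split("+") if kind else [pop]
            for p in pops:
                for a in self.positive_markers.get(p, []):
                    if a in ab_index:
                        pos[i, ab_index[a]] = True
        return pos

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "population": self.population,
            "subject": self.subject,
            "is_doublet": self.is_doublet,
            "doublet_kind": self.doublet_kind,
            "doublet_partner_populations": self.doublet_partner_populations,
        })


def _equalized_positive_sets(
        populations: list[PopulationSpec], antibodies: list[str]) -> dict[str, set[str]]:
    """Effective positive marker sets with equal cardinality per population.

    Every antibody is made positive in at least one population (so each has a
    genuine two-component signal), and all populations end up positive for the
    same number of antibodies, which keeps the per-cell CLR centering offset
    identical across populations and the per-antibody components clean.
    Deterministic: no randomness, resolved by sorted order.
    """
    pos = {p.name: set(p.positive_markers) for p in populations}
    neg = {p.name: set(p.negative_markers) for p in populations}
    covered = set().union(*pos.values()) if pos else set()
    uncovered = [a for a in antibodies if a not in covered]
    order = sorted(pos)  # deterministic tie-break by population name

    def eligible(ab: str) -> list[str]:
        return [n for n in order if ab not in neg[n]]

    for ab in uncovered:
        cands = eligible(ab)
        if not cands:            # negative everywhere by design: leave ambient-only
            continue
        target = min(cands, key=lambda n: (len(pos[n]), n))
        pos[target].add(ab)

    k = max(len(s) for s in pos.values())
    explicit = set().union(*(p.positive_markers for p in populations))
    for name in order:
        # pad only with antibodies no population claims explicitly, so
        # phenotyping markers used by naming rules stay where they belong
        free = [a for a in antibodies
                if a not in pos[name] and a not in neg[name] and a not in explicit]
        # prefer antibodies with the fewest positive populations so coverage spreads
        free.sort(key=lambda a: (sum(a in s for s in pos.values()), a))
        while len(pos[name]) < k and free:
            pos[name].add(free.pop(0))
    return pos


def _gensini_scores(rng: np.random.Generator, is_case: np.ndarray) -> np.ndarray:
    """Angiographic severity scores consistent with the labeling rule."""
    scores = np.where(is_case,
                      rng.uniform(31.0, 100.0, size=is_case.size),
                      rng.uniform(0.0, 5.9, size=is_case.size))
    return np.round(scores, 1)


def simulate_experiment(config: SimConfig) -> tuple[CellExperiment, GroundTruth]:
    """Generate one experiment plus its ground truth, reproducibly by seed."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    genes = config.gene_names()
    antibodies = config.antibody_names()
    tag_names = config.tag_names()
    pops = config.populations
    pop_names = [p.name for p in pops]
    freqs = np.array([p.frequency for p in pops])
    freqs = freqs / freqs.sum()
    n_pop = len(pops)

    # ---- subjects ----------------------------------------------------------
    n_plates = config.n_plates
    subject_ids = [f"S{i + 1:03d}" for i in range(config.n_subjects)]
    plate_of_subject = np.arange(config.n_subjects) % n_plates      # round-robin
    tag_of_subject = np.arange(config.n_subjects) // n_plates        # slot on plate
    # alternate case/control so each plate mixes both groups
    is_case = np.zeros(config.n_subjects, dtype=bool)
    case_slots = np.arange(config.n_subjects)[::2][:config.n_cases]
    if case_slots.size < config.n_cases:   # more cases than odd slots
        extra = np.setdiff1d(np.arange(config.n_subjects), case_slots)
        case_slots = np.concatenate([case_slots, extra[:config.n_cases - case_slots.size]])
    is_case[case_slots] = True
    gensini = _gensini_scores(rng, is_case)
    sex = rng.choice(["M", "F"], size=config.n_subjects, p=[0.73, 0.27])
    subject_meta = pd.DataFrame({
        "group": np.where(is_case, "CAD_high", "CAD_low"),
        "gensini": gensini,
        "sex": sex,
        "plate": [f"P{p + 1:02d}" for p in plate_of_subject],
        "tag": [tag_names[t] for t in tag_of_subject],
    }, index=pd.Index(subject_ids, name="subject"))

    # ---- virtual cells (singlets + doublet constituents) -------------------
    n_singlets = config.n_subjects * config.n_cells_per_subject
    r = config.doublet_rate
    n_doublets = int(round(r / (1.0 - r) * n_singlets)) if r > 0 else 0

    v_subject = np.repeat(np.arange(config.n_subjects), config.n_cells_per_subject)
    v_pop = rng.choice(n_pop, size=n_singlets, p=freqs)

    kinds: list[str] = []
    if n_doublets:
        kf = config.doublet_kind_fractions
        counts = {k: int(round(kf.get(k, 0.0) * n_doublets)) for k in DOUBLET_KINDS}
        while sum(counts.values()) > n_doublets:
            counts[max(counts, key=counts.get)] -= 1
        while sum(counts.values()) < n_doublets:
            counts[max(DOUBLET_KINDS, key=lambda k: kf.get(k, 0.0))] += 1
        for k in DOUBLET_KINDS:
            kinds += [k] * counts[k]

    cd8_idx = [i for i, p in enumerate(pops) if p.name in panel_defaults.CD8_POPULATION_NAMES]
    myeloid_idx = [i for i, p in enumerate(pops) if p.name == "Myeloid"]
    subjects_on_plate = [np.flatnonzero(plate_of_subject == pl) for pl in range(n_plates)]

    d_sub = np.empty((n_doublets, 2), dtype=int)
    d_pop = np.empty((n_doublets, 2), dtype=int)
    for j, kind in enumerate(kinds):
        pl = int(rng.integers(n_plates))
        on_plate = subjects_on_plate[pl]
        if kind == "tag" and on_plate.size >= 2:
            d_sub[j] = rng.choice(on_plate, size=2, replace=False)
        else:
            d_sub[j] = [int(rng.choice(on_plate))] * 2
        if kind == "biological" and cd8_idx and myeloid_idx:
            w = freqs[cd8_idx] / freqs[cd8_idx].sum()
            d_pop[j] = [int(rng.choice(cd8_idx, p=w)), int(rng.choice(myeloid_idx))]
        else:
            a = int(rng.choice(n_pop, p=freqs))
            others = [i for i in range(n_pop) if i != a]
            if others:
                wo = freqs[others] / freqs[others].sum()
                b = int(rng.choice(others, p=wo))
            else:
                b = a
            d_pop[j] = [a, b]

    v_subject = np.concatenate([v_subject, d_sub.ravel()]) if n_doublets else v_subject
    v_pop = np.concatenate([v_pop, d_pop.ravel()]) if n_doublets else v_pop
    n_virtual = v_subject.size

    # ---- RNA counts (negative binomial via gamma-Poisson) ------------------
    base_mean = rng.lognormal(mean=np.log(0.4), sigma=1.0, size=config.n_genes)
    base_mean = np.clip(base_mean, 0.05, 20.0)
    gene_index = {g: j for j, g in enumerate(genes)}
    # planted effect genes are drawn from the expressed part of the panel: an
    # effect on a gene with essentially no counts would be unmeasurable by design
    for g, _ in list(config.de_genes) + list(config.discriminative_genes):
        base_mean[gene_index[g]] = max(base_mean[gene_index[g]], 1.0)
    pop_mult = np.ones((n_pop, config.n_genes))
    for i, p in enumerate(pops):
        for g, fold in p.expression_profile.items():
            if g in gene_index:
                pop_mult[i, gene_index[g]] = fold
    # subset-specific program genes: disjoint random blocks of panel genes not
    # already carrying explicit profile, case or control effects
    effect_genes = ({g for g, _ in config.de_genes}
                    | {g for g, _ in config.discriminative_genes}
                    | {g for p in pops for g in p.expression_profile})
    free_genes = [j for j, g in enumerate(genes) if g not in effect_genes]
    if config.n_program_genes > 0 and free_genes:
        free_order = rng.permutation(free_genes)
        lo, hi = config.program_fold_range
        for i in range(n_pop):
            block = free_order[i * config.n_program_genes:(i + 1) * config.n_program_genes]
            pop_mult[i, block] = rng.uniform(lo, hi, size=block.size)

    case_mult = np.ones(config.n_genes)
    for g, eff in list(config.de_genes) + list(config.discriminative_genes):
        case_mult[gene_index[g]] *= 2.0 ** eff

    de_pop_mask = np.ones(n_pop, dtype=bool)
    if config.de_populations is not None:
        de_pop_mask = np.array([p.name in config.de_populations for p in pops])
    cell_is_case = is_case[v_subject] & de_pop_mask[v_pop]

    mean_matrix = base_mean[None, :] * pop_mult[v_pop]
    mean_matrix = np.where(cell_is_case[:, None], mean_matrix * case_mult[None, :],
                           mean_matrix)
    shape = 1.0 / config.rna_dispersion
    lam = rng.gamma(shape, mean_matrix * config.rna_dispersion)
    rna = rng.poisson(lam).astype(np.int64)

    # ---- ADT counts (log-normal intensity around component means, Poisson) -
    eff_pos = _equalized_positive_sets(pops, antibodies)
    pos_mask = np.zeros((n_pop, config.n_antibodies), dtype=bool)
    ab_index = {a: j for j, a in enumerate(antibodies)}
    for i, p in enumerate(pops):
        for a in eff_pos[p.name]:
            pos_mask[i, ab_index[a]] = True
    mu_log2 = np.log2(config.ambient_adt_mean) + config.positive_adt_shift * pos_mask
    plate_offset = rng.normal(0.0, config.batch_log2_sd, size=n_plates)
    y = rng.normal(mu_log2[v_pop], config.adt_log2_sd)
    y = y + plate_offset[plate_of_subject[v_subject]][:, None]
    adt = rng.poisson(np.exp2(y)).astype(np.int64)

    # ---- sample tags --------------------------------------------------------
    tags = rng.poisson(config.tag_background_mean,
                       size=(n_virtual, config.subjects_per_plate)).astype(np.int64)
    own = tag_of_subject[v_subject]
    tags[np.arange(n_virtual), own] += rng.poisson(config.tag_signal_mean, size=n_virtual)

    # ---- fold constituents into doublets ------------------------------------
    s = slice(0, n_singlets)
    rna_s, adt_s, tags_s = rna[s], adt[s], tags[s]
    if n_doublets:
        a_rows = rna[n_singlets::2], adt[n_singlets::2], tags[n_singlets::2]
        b_rows = rna[n_singlets + 1::2], adt[n_singlets + 1::2], tags[n_singlets + 1::2]
        rna_all = np.vstack([rna_s, a_rows[0] + b_rows[0]])
        adt_all = np.vstack([adt_s, a_rows[1] + b_rows[1]])
        tags_all = np.vstack([tags_s, a_rows[2] + b_rows[2]])
    else:
        rna_all, adt_all, tags_all = rna_s, adt_s, tags_s
    n_cells = rna_all.shape[0]

    population = np.array([pop_names[i] for i in v_pop[:n_singlets]]
                          + ["doublet"] * n_doublets, dtype=object)
    subject_truth = np.array([subject_ids[i] for i in v_subject[:n_singlets]]
                             + [subject_ids[i] for i in d_sub[:, 0]], dtype=object)
    is_doublet = np.zeros(n_cells, dtype=bool)
    is_doublet[n_singlets:] = True
    doublet_kind = np.array([""] * n_singlets + kinds, dtype=object)
    partners = np.array(
        [""] * n_singlets
        + [f"{pop_names[a]}+{pop_names[b]}" for a, b in d_pop], dtype=object)
    plate_per_cell = np.concatenate([
        plate_of_subject[v_subject[:n_singlets]],
        plate_of_subject[d_sub[:, 0]] if n_doublets else np.empty(0, dtype=int),
    ]).astype(int)

    # shuffle cell order so doublets are interleaved with singlets
    perm = rng.permutation(n_cells)
    rna_all, adt_all, tags_all = rna_all[perm], adt_all[perm], tags_all[perm]
    population, subject_truth = population[perm], subject_truth[perm]
    is_doublet, doublet_kind, partners = is_doublet[perm], doublet_kind[perm], partners[perm]
    plate_per_cell = plate_per_cell[perm]

    barcodes = pd.Index([f"C{i + 1:06d}" for i in range(n_cells)], name="barcode")
    cell_meta = pd.DataFrame({
        "plate": [f"P{p + 1:02d}" for p in plate_per_cell],
        "subject": pd.array([None] * n_cells, dtype="string"),   # filled by demux
    }, index=barcodes)

    # ---- planted thresholds: midpoints of the singlet CLR components --------
    clr = clr_normalize_adt(adt_all[~is_doublet])
    singlet_pops = np.array([pop_names.index(p) for p in population[~is_doublet]])
    singlet_pos = pos_mask[singlet_pops]
    true_thresholds: dict[str, float] = {}
    for j, ab in enumerate(antibodies):
        v = clr[:, j]
        m = singlet_pos[:, j]
        if m.any() and (~m).any():
            true_thresholds[ab] = float((v[m].mean() + v[~m].mean()) / 2.0)
        else:  # ambient-only antibody: no positive population, no threshold
            true_thresholds[ab] = float("nan")

    experiment = CellExperiment(
        rna=sparse.csr_matrix(rna_all),
        adt=adt_all,
        tags=tags_all,
        gene_names=genes,
        antibody_names=antibodies,
        tag_names=tag_names,
        cell_meta=cell_meta,
        subject_meta=subject_meta,
    )
    truth = GroundTruth(
        population=population,
        subject=subject_truth,
        is_doublet=is_doublet,
        doublet_kind=doublet_kind,
        doublet_partner_populations=partners,
        true_thresholds=true_thresholds,
        positive_markers={k: sorted(v) for k, v in eff_pos.items()},
        de_genes=list(config.de_genes),
        discriminative_genes=list(config.discriminative_genes),
        case_subjects=[subject_ids[i] for i in np.flatnonzero(is_case)],
    )
    return experiment, truth
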