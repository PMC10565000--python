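"""Rank genes by RF permutation importance and enrich the DE gene list.

The classifier separates CAD-high from CAD-low CD8 cells on normalized
expression with subject-grouped 3-fold cross-validation; the up-regulated
DE genes are then tested for over-representation in the bundled
TCR/cytotoxicity/exhaustion gene-set library.
"""

import argparse
from pathlib import Path

import numpy as np

from citegate import (
    CD8_GATE,
    apply_de_filters,
    apply_gate,
    build_threshold_table,
    enrich,
    find_markers,
    normalize_experiment,
    packaged_gmt_path,
    rank_genes_by_importance,
    rank_pathways,
    read_experiment,
    read_gmt,
    read_truth,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixture", type=Path, default=ROOT / "results" / "fixture")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--max-cells", type=int, default=1000)
    args = ap.parse_args()

    experiment = read_experiment(args.fixture)
    truth = read_truth(args.fixture / "truth.json")
    normalized = normalize_experiment(experiment.rna, experiment.adt)
    thresholds = build_threshold_table(normalized, experiment.antibody_names)
    mask = apply_gate(normalized.adt_clr, experiment.antibody_names,
                      thresholds, CD8_GATE)
    groups = experiment.subject_meta["group"]
    condition = np.array([groups.get(s) for s in truth.subject], dtype=object)

    idx = np.flatnonzero(mask)
    if idx.size > args.max_cells:
        rng = np.random.default_rng(args.seed)
        idx = np.sort(rng.choice(idx, size=args.max_cells, replace=False))
    imp = rank_genes_by_importance(
        normalized.rna_norm[idx], condition[idx], truth.subject[idx],
        experiment.gene_names,
        grid={"n_estimators": [100, 300], "max_depth": [10]},
        n_repeats=3, seed=args.seed)
    imp.table.to_csv(args.out / "importance.csv", index=False)
    disc = {g for g, _ in truth.discriminative_genes}
    top15 = set(imp.table.nsmallest(15, "rank")["gene"])
    print(f"RF on {idx.size} CD8 cells; selected {imp.metadata['selected']}")
    print(f"top 10 genes: {imp.table['gene'].head(10).tolist()}")
    print(f"planted discriminative genes in top 15: {len(top15 & disc)}/{len(disc)}")

    m1 = mask & (condition == "CAD_high")
    m2 = mask & (condition == "CAD_low")
    de = find_markers(normalized.rna_norm, m1, m2, experiment.gene_names)
    query = apply_de_filters(de).query("direction == 'up'")["gene"].tolist()
    library = read_gmt(packaged_gmt_path())
    table = enrich(query, library, de["gene"].tolist())
    table.to_csv(args.out / "enrichment.csv", index=False)
    ranked = rank_pathways(table)
    ranked.to_csv(args.out / "enrichment_significant.csv", index=False)
    print(f"enrichment of {len(query)} up-regulated genes against "
          f"{len(library)} sets: {len(ranked)} significant")
    for _, row in ranked.iterrows():
        print(f"  {row['set']}: overlap {row['overlap']}/{row['set_size']}, "
              f"-log10 adj p = {row['neg_log10_p_adj']:.1f}")


if __name__ == "__main__":
    main()
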