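"""Generate the default synthetic CITE-seq experiment and write it to disk.

Emulates the multiplexed case/control design: 60 subjects (30 CAD-high by
Gensini score, 30 CAD-low), 4 subjects hash-tagged per plate, 49 surface
antibodies, a 496-gene targeted panel, 5% planted doublets of three kinds,
and planted case/control effect genes.  The fixture (MTX/CSV + truth JSON)
feeds the numbered scripts that follow.
"""

import argparse
from pathlib import Path

from citegate import SimConfig, simulate_experiment, write_fixture

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "fixture")
    args = ap.parse_args()

    config = SimConfig(rng_seed=args.seed)
    experiment, truth = simulate_experiment(config)
    write_fixture(experiment, truth, args.out)

    n_doublets = int(truth.is_doublet.sum())
    print(f"wrote {experiment.n_cells} cells "
          f"({experiment.rna.shape[1]} genes, {experiment.adt.shape[1]} antibodies) "
          f"to {args.out}")
    print(f"planted doublets: {n_doublets} "
          f"({n_doublets / experiment.n_cells:.1%} of cells)")
    print(f"planted DE genes: {[g for g, _ in truth.de_genes]}")
    print(f"planted discriminative genes: {[g for g, _ in truth.discriminative_genes]}")


if __name__ == "__main__":
    main()
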