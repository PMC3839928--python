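"""Simulate the synthetic study's data sets and write them to disk.

Generates the human-scale (4,109 x 50) and yeast-scale (3,620 x 30)
coherent-state transcript tables, the annotated length tables with planted
metabolic-ontology subsets, and the planted-overexpression expression matrix
(10 normal + 529 tumor samples).  Full tables go under scratch/data/ (they
are multi-megabyte); a small inventory goes to results/.

Run:  python analysis/01_simulate_datasets.py [--seed 0]
"""

import argparse
from pathlib import Path

import pandas as pd

from translen.io import write_expression_matrix, write_transcript_table
from translen.simulate import simulate_profile_matrix
from translen.study import (EXPR_CUTOFFS, expression_study, length_study,
                            profile_study)
from translen.simulate import human_like_config, yeast_like_config

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    data_dir = ROOT / "scratch" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    inventory = []
    ls = length_study(seed=args.seed)
    for organism, make in [("human", human_like_config),
                           ("yeast", yeast_like_config)]:
        cfg = make(seed=args.seed)
        matrix, _ = simulate_profile_matrix(cfg)
        table = ls[f"{organism}_table"]
        dest = data_dir / f"{organism}_transcript_lengths.tsv"
        write_transcript_table(dest, matrix, table)
        inventory.append({
            "dataset": dest.name,
            "entities": matrix.n_transcripts,
            "gel_slices": matrix.n_slices,
            "mean_length_nt": round(float(table.lengths.mean()), 1),
            "annotation_terms": len(table.annotation_sets),
        })
        print(f"wrote {dest} ({matrix.n_transcripts} x {matrix.n_slices})")

    es = expression_study(seed=args.seed)
    E = es["by_cutoff"][EXPR_CUTOFFS[0]]["matrix"]
    dest = data_dir / "expression_normal_tumor.tsv"
    write_expression_matrix(dest, E)
    inventory.append({
        "dataset": dest.name,
        "entities": len(E.entity_ids),
        "gel_slices": "",
        "mean_length_nt": "",
        "annotation_terms": "",
    })
    print(f"wrote {dest} ({len(E.entity_ids)} x {len(E.sample_ids)})")

    pd.DataFrame(inventory).to_csv(results / "simulated_datasets.tsv",
                                   sep="\t", index=False)
    print(f"inventory -> {results / 'simulated_datasets.tsv'}")


if __name__ == "__main__":
    main()
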