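"""Cantelli subset-length statistics over the planted annotation subsets.

Runs the three finite-population designs on the synthetic length tables:
metabolic-ontology subsets against the global set (shorter-than-typical),
glucose-metabolism subsets against the respiratory electron transport chain
(longer-than-typical), and the mutually exclusive splits (normal-only vs
both-overexpressed; DNA-damage overexpressed vs underexpressed).  Emits
tables shaped like the subset-length report tables.

Run:  python analysis/03_subset_length_statistics.py [--seed 0]
"""

import argparse
from pathlib import Path

import pandas as pd

from translen.study import length_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    study = length_study(seed=args.seed)
    rows = []
    for name, res in study["tests"].items():
        rows.append({
            "comparison": name,
            "design": res.design,
            "sizes": "/".join(f"{k}={v}" for k, v in res.sizes.items()),
            "delta_nt": round(res.delta_observed, 1),
            "null_sd_nt": round(res.null_variance**0.5, 1),
            "direction": res.direction,
            "cantelli_p": res.cantelli_p,
        })
        flag = "significant" if res.cantelli_p < 0.05 else "not significant"
        print(f"{name}: delta = {res.delta_observed:+.0f} nt "
              f"({res.direction}), P <= {res.cantelli_p:.3g} [{flag}]")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    df = pd.DataFrame(rows)
    df[df.design == "one_subset"].to_csv(
        results / "subset_vs_global_lengths.tsv", sep="\t", index=False)
    df[df.design == "two_subset"].to_csv(
        results / "subset_vs_etc_lengths.tsv", sep="\t", index=False)
    df[df.design == "split"].to_csv(
        results / "split_lengths.tsv", sep="\t", index=False)
    print(f"-> {results}/subset_vs_global_lengths.tsv, "
          "subset_vs_etc_lengths.tsv, split_lengths.tsv")


if __name__ == "__main__":
    main()
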