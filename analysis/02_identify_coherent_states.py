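"""Identify the transcript-length distribution functions by SVD.

Decomposes the human- and yeast-scale synthetic profile matrices, fits the
five leading eigenvectors with the asymmetric Hermite series, the
eigenvalues with a geometric series, and the overall profile with an
asymmetric Gaussian, then reports each set's equilibrium migration distance,
its transcript length on the organism calibration, the asymmetry and the
fit correlations.

Run:  python analysis/02_identify_coherent_states.py [--seed 0]
"""

import argparse
from pathlib import Path

import pandas as pd

from translen.study import profile_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    study = profile_study(seed=args.seed)
    rows = []
    for organism, r in study.items():
        fit, truth = r["fit"], r["truth"]
        rows.append({
            "set": f"{organism}_global",
            "P": r["config"].n_transcripts,
            "X": r["config"].grid.n_slices,
            "x0_mm": fit.params.x0,
            "x0_true_mm": truth["x0"],
            "equilibrium_length_nt": round(fit.equilibrium_length_nt, 0),
            "length_uncertainty_nt": round(
                fit.equilibrium_length_uncertainty_nt, 0),
            "k_mm2": round(fit.params.k, 5),
            "s": round(fit.params.s, 3),
            "s_true": truth["s"],
            "eta": round(r["eta"], 3),
            "mean_hermite_corr": round(fit.mean_correlation, 3),
            "eigenvalue_geom_corr": round(r["eta_correlation"], 4),
            "overall_gaussian_corr": round(r["overall_correlation"], 4),
            "top5_info_fraction": round(r["top5_fraction"], 3),
            "entropy": round(r["eigensystem"].entropy, 3),
        })
        print(f"{organism}: equilibrium {fit.params.x0:.0f} mm "
              f"(~{fit.equilibrium_length_nt:.0f}+-"
              f"{fit.equilibrium_length_uncertainty_nt:.0f} nt), "
              f"s = {fit.params.s:.2f}, eta = {r['eta']:.2f}; "
              f"mean eigenvector|Hermite correlation "
              f"{fit.mean_correlation:.2f}, eigenvalue|geometric correlation "
              f"{r['eta_correlation']:.3f}, overall-profile|Gaussian "
              f"correlation {r['overall_correlation']:.3f}")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(results / "coherent_state_fits.tsv",
                              sep="\t", index=False)
    print(f"-> {results / 'coherent_state_fits.tsv'}")


if __name__ == "__main__":
    main()
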