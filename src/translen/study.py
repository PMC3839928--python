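"""The synthetic study: organism-scale fixtures and the full analysis over them.

This module pins the study conditions — sample sizes, planted subset sizes
and mean lengths, expression-study design — and drives every stage of the
pipeline over data the package simulates itself:

* profile study: human-scale (4,109 x 50, equilibrium 84 mm) and yeast-scale
  (3,620 x 30, equilibrium 78 mm) coherent-state matrices, decomposed and
  fitted (Hermite series, geometric eigenvalues, overall-profile Gaussian);
* length study: annotated length tables whose planted subset sizes and mean
  lengths echo the reported metabolic-ontology subsets (translation,
  ribosome, respiratory electron transport chain, glucose metabolism, ...),
  tested with the three Cantelli designs;
* expression study: a 4,109-transcript expression matrix with 10 normal and
  529 tumor samples and planted top-X overexpression subsets, annotated,
  partitioned and scanned for planted annotation-term enrichment.

Planted subsets are drawn disjoint for the length tables (the statistics
only see means and counts); the enrichment fixture instead plants controlled
overlaps between annotation terms and the overexpression subsets.
"""

from __future__ import annotations

from typing import Dict, Set

import numpy as np

from .enrichment import (annotate_overexpressed, enrichment_scan,
                         partition_subsets)
from .lengthstats import one_subset_test, split_test, two_subset_test
from .model import human_calibration, yeast_calibration
from .simulate import (human_like_config, simulate_annotated_lengths,
                       simulate_expression, simulate_profile_matrix,
                       yeast_like_config)
from .svd import (decompose, fit_geometric_series, fit_hermite_series,
                  fit_profile_gaussian, overall_profile)

# Human subset study conditions: (term, M, target subset mean length in nt);
# sizes and means follow the reported human tables (global mean 2,480 nt).
HUMAN_BASE_MEAN = 2480.0
HUMAN_BASE_VAR = 1.0e6
HUMAN_TERMS = [
    ("translation", 178, 2096.0),
    ("ribosome", 78, 1582.0),
    ("respiratory_etc", 55, 1460.0),
    ("mrcc_i", 25, 1153.0),
    ("cox_activity", 14, 1108.0),
    ("glucose_metabolic_process", 100, 2399.0),
    ("glycolysis", 29, 2428.0),
    ("neuron_projection", 259, 2666.0),
    ("synaptic_transmission", 238, 2667.0),
    ("over_both", 200, 1723.0),
    ("over_tumor_only", 135, 2001.0),
    ("over_normal_only", 102, 2599.0),
]

# Yeast study conditions (global mean 1,621 nt).
YEAST_BASE_MEAN = 1621.0
YEAST_BASE_VAR = 2.5e5
YEAST_TERMS = [
    ("translation", 319, 1271.0),
    ("ribosome", 274, 1135.0),
    ("respiratory_etc", 22, 995.0),
    ("glucose_metabolic_process", 66, 1686.0),
    ("glycolysis", 23, 1695.0),
    # DNA-damage (MMS) response flags: overexpressed transcripts longer than
    # underexpressed ones, in the ~4:3 ratio of the reported equilibria
    ("mms_overexpressed", 300, 1771.0),
    ("mms_underexpressed", 300, 1321.0),
]

# Expression study: transcript universe shared with the human length table;
# planted overexpression subsets sized like the reported X = 250 partition.
EXPR_SAMPLES = {"normal": 10, "tumor": 529}
EXPR_CUTOFFS = (250, 300)

# Planted (term overlap y with subset) for the enrichment fixture, following
# the reported contingency shapes: (term, Y, subset, y).
ENRICH_PLANTS = [
    ("translation", 178, "both", 36),
    ("ribosome", 78, "both", 28),
    ("respiratory_etc", 55, "both", 21),
    ("mrcc_i", 25, "both", 9),
    ("cox_activity", 14, "both", 9),
    ("glucose_metabolic_process", 100, "normal_overall", 17),
    ("glycolysis", 29, "normal_overall", 9),
    ("neuron_projection", 259, "normal_only", 22),
    ("synaptic_transmission", 238, "normal_only", 19),
]


def _background_mean(global_mean: float, terms, N: int) -> float:
    """Background mean making the realized global mean hit the stated one
    despite the planted subsets' pull."""
    planted_total = sum(M * mean for _, M, mean in terms)
    planted_n = sum(M for _, M, _ in terms)
    return (global_mean * N - planted_total) / (N - planted_n)


def _term_specs(terms, base_mean):
    return [(name, M, mean - base_mean) for name, M, mean in terms]


def profile_study(seed: int = 0, n_human: int = 4109,
                  n_yeast: int = 3620) -> Dict[str, dict]:
    """Simulate and fully identify the human- and yeast-scale coherent states."""
    out = {}
    for organism, make, n, cal in [
            ("human", human_like_config, n_human, human_calibration()),
            ("yeast", yeast_like_config, n_yeast, yeast_calibration())]:
        cfg = make(n_transcripts=n, seed=seed)
        matrix, truth = simulate_profile_matrix(cfg)
        eig = decompose(matrix)
        fit = fit_hermite_series(eig, Q=5, calibration=cal)
        eta, eta_corr = fit_geometric_series(eig, Q=5)
        gparams, gcorr = fit_profile_gaussian(overall_profile(matrix),
                                              matrix.grid)
        out[organism] = {
            "config": cfg,
            "truth": truth,
            "eigensystem": eig,
            "fit": fit,
            "eta": eta,
            "eta_correlation": eta_corr,
            "overall_params": gparams,
            "overall_correlation": gcorr,
            "top5_fraction": float(eig.eigenvalue_fractions[:5].sum()),
        }
    return out


def length_study(seed: int = 0, n_human: int = 4109,
                 n_yeast: int = 3620) -> Dict[str, dict]:
    """Build the annotated length tables and run every subset test."""
    bg_h = _background_mean(HUMAN_BASE_MEAN, HUMAN_TERMS, n_human)
    human, truth_h = simulate_annotated_lengths(
        n_human, _term_specs(HUMAN_TERMS, bg_h),
        base_mean=bg_h, base_var=HUMAN_BASE_VAR, seed=seed)
    bg_y = _background_mean(YEAST_BASE_MEAN, YEAST_TERMS, n_yeast)
    yeast, truth_y = simulate_annotated_lengths(
        n_yeast, _term_specs(YEAST_TERMS, bg_y),
        base_mean=bg_y, base_var=YEAST_BASE_VAR, seed=seed + 1)

    tests: Dict[str, object] = {}
    # shorter-than-typical subsets vs the global set (one-subset design)
    for org, table in [("human", human), ("yeast", yeast)]:
        for term in ("translation", "ribosome", "respiratory_etc"):
            tests[f"{org}_{term}_vs_global"] = one_subset_test(table, term)
    for term in ("mrcc_i", "cox_activity", "over_both"):
        tests[f"human_{term}_vs_global"] = one_subset_test(human, term)

    # glucose metabolism vs the respiratory chain (two independent subsets)
    for org, table in [("human", human), ("yeast", yeast)]:
        for term in ("glucose_metabolic_process", "glycolysis"):
            tests[f"{org}_{term}_vs_etc"] = two_subset_test(
                table, term, "respiratory_etc")
    for term in ("over_tumor_only", "over_normal_only"):
        tests[f"human_{term}_vs_etc"] = two_subset_test(
            human, term, "respiratory_etc")

    # mutually exclusive splits (Eq-13-style)
    normal_overall = (human.annotation_sets["over_normal_only"]
                      | human.annotation_sets["over_both"])
    tests["human_normal_only_vs_both_split"] = split_test(
        human, "over_normal_only", normal_overall)
    mms_universe = (yeast.annotation_sets["mms_overexpressed"]
                    | yeast.annotation_sets["mms_underexpressed"])
    tests["yeast_mms_over_vs_under_split"] = split_test(
        yeast, "mms_overexpressed", mms_universe)

    return {"human_table": human, "yeast_table": yeast,
            "human_truth": truth_h, "yeast_truth": truth_y, "tests": tests}


def expression_study(seed: int = 0, n_entities: int = 4109) -> Dict[str, object]:
    """Planted overexpression: simulate, annotate, partition, check recovery."""
    ids = [f"G{i:05d}" for i in range(n_entities)]
    both = set(ids[:200])
    tumor_only = set(ids[200:335])
    normal_only = set(ids[335:437])
    planted = {"normal": both | normal_only, "tumor": both | tumor_only}
    results = {}
    for X in EXPR_CUTOFFS:
        E = simulate_expression(n_entities, EXPR_SAMPLES, planted, X=X,
                                seed=seed + X)
        call_n = annotate_overexpressed(E, "normal", X)
        call_t = annotate_overexpressed(E, "tumor", X)
        part = partition_subsets(call_n, call_t)
        recovered = (part.both == both and part.a_only == normal_only
                     and part.b_only == tumor_only)
        results[X] = {"matrix": E, "partition": part, "recovered": recovered}
    return {"planted": {"both": both, "tumor_only": tumor_only,
                        "normal_only": normal_only},
            "by_cutoff": results}


def enrichment_study(partition_named: Dict[str, Set[str]],
                     universe, seed: int = 0):
    """Build annotation terms with planted subset overlaps and scan them.

    For each (term, Y, subset, y) plant exactly y members inside the subset
    and Y - y outside all three mutually exclusive subsets, then run the
    hypergeometric scan over the whole partition.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    flagged = (partition_named["normal_only"] | partition_named["tumor_only"]
               | partition_named["both"])
    outside = sorted(set(universe) - flagged)
    annotations: Dict[str, Set[str]] = {}
    for term, Y, subset, y in ENRICH_PLANTS:
        inside = sorted(partition_named[subset])
        members = set(rng.choice(inside, y, replace=False))
        members |= set(rng.choice(outside, Y - y, replace=False))
        annotations[term] = members
    scan = enrichment_scan(
        {k: partition_named[k] for k in
         ("normal_only", "tumor_only", "both", "normal_overall",
          "tumor_overall")},
        annotations, universe)
    return scan, annotations
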