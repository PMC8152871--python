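"""Compare the simulated groups: similarity, flags, membership tests, behavior.

Reads the group matrices written by 03_connectivity_matrices.py (run it
first, for both the combined and the easier/harder states), computes
the intergroup Spearman similarity per pair subset, the
enhancement/suppression flags against the planted ground truth, the
network-IV specificity/sensitivity rank-sum tests, and the behavioral
easier-vs-harder contrasts.
"""

import argparse
from pathlib import Path

import pandas as pd

from syntaxconn import (
    behavioral_contrast,
    classify_pairs,
    default_catalog,
    default_generative_spec,
    flag_enhanced,
    flag_suppressed,
    network_assignment_test,
    simulate_behavior,
    spearman_similarity,
)
from syntaxconn.connectivity import PartialCorrMatrix

OUT = Path(__file__).resolve().parent.parent / "results"
GROUPS = ("normal", "lpmc_f3", "extra")


def load_matrix(group: str, state: str) -> PartialCorrMatrix:
    return PartialCorrMatrix.from_tsv(
        OUT / f"matrix_{group}_{state}.tsv", provenance=group, condition_set=state
    )


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    catalog = default_catalog()
    pairs = classify_pairs(catalog)
    combined = {g: load_matrix(g, "combined") for g in GROUPS}

    rows = []
    for i, a in enumerate(GROUPS):
        for b in GROUPS[i + 1:]:
            for subset in ("within", "between", "all"):
                res = spearman_similarity(combined[a], combined[b], pairs, subset)
                rows.append(
                    {"group_a": a, "group_b": b, "subset": subset,
                     "R_S": res.r_s, "n": res.n, "p": res.p}
                )
                print(f"{a} vs {b} [{subset:7s}]: R_S = {res.r_s:+.2f} "
                      f"(n = {res.n}, p = {res.p:.2g})")
    pd.DataFrame(rows).to_csv(OUT / "similarity.tsv", sep="\t", index=False)

    # flags: easier-state normal group as reference, harder-state groups as targets
    try:
        reference = load_matrix("normal", "easier")
        harder = [load_matrix(g, "harder") for g in GROUPS]
    except FileNotFoundError:
        print("(state-specific matrices missing: run 03 with --state easier/harder)")
    else:
        enhanced = flag_enhanced(harder, pairs)
        suppressed = flag_suppressed(reference, harder, pairs)
        truth = default_generative_spec(seed=args.seed).ground_truth()
        print(f"enhanced between-network edges (all groups r > {enhanced.threshold}): "
              f"{enhanced.enhanced_pairs()}  (planted: {list(truth.enhanced_pairs)})")
        print(f"suppressed within-network edges: {suppressed.suppressed_pairs()}  "
              f"(planted: {list(truth.suppressed_pairs)})")
        flags = enhanced.to_frame()[["region_a", "region_b", "label", "enhanced"]]
        flags = flags.merge(
            suppressed.to_frame()[["region_a", "region_b", "suppressed"]],
            on=["region_a", "region_b"], how="outer",
        )
        for col in ("enhanced", "suppressed"):
            flags[col] = flags[col].fillna(False).astype(bool)
        flags.to_csv(OUT / "flags.tsv", sep="\t", index=False)

    spec_res, sens_res = network_assignment_test(combined["normal"], pairs, "IV")
    print(f"network IV specificity: W = {spec_res.w:.0f} "
          f"(n = {spec_res.n_within}+{spec_res.n_other}), p = {spec_res.p:.2g}")
    print(f"network IV sensitivity: W = {sens_res.w:.0f} "
          f"(n = {sens_res.n_within}+{sens_res.n_other}), p = {sens_res.p:.2g}")

    behavior = simulate_behavior(seed=args.seed)
    for measure in ("error", "rt"):
        for group in GROUPS:
            sub = behavior[behavior["group"] == group]
            res = behavioral_contrast(sub, measure, "paired")
            print(f"{group} paired harder-easier [{measure}]: "
                  f"t({res.df:.0f}) = {res.t:.1f}, p = {res.p:.2g}, "
                  f"mean diff = {res.mean_diff:+.1f}")
    for cond in ("Pot", "Pot+"):
        res = behavioral_contrast(
            behavior, "error", "unpaired", groups=("lpmc_f3", "normal"), condition=cond
        )
        print(f"lpmc_f3 vs normal errors [{cond}]: t({res.df:.0f}) = {res.t:.1f}, "
              f"p = {res.p:.2g}")


if __name__ == "__main__":
    main()
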