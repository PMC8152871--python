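"""Group-level statistics on connectivity matrices and behavior.

Covers four analyses: (1) intergroup similarity — Spearman rank
correlation R_S between the edge r-values of two group matrices,
separately for within-network, between-network or all pairs; (2)
edge-level flags — enhancement (r above a threshold in every compared
group) and suppression (an edge strong in a reference group falling to
or below the threshold in every target group); (3) network-membership
rank-sum tests — specificity (within-network r vs r of edges linking
that network to the others) and sensitivity (within-network r vs
within-r of the remaining networks); (4) easier-vs-harder behavioral
contrasts on error rates and response times.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .catalog import PairClassification, PairLabel
from .connectivity import PartialCorrMatrix

__all__ = [
    "SimilarityResult",
    "EdgeFlags",
    "AssignmentTestResult",
    "ContrastResult",
    "CompareError",
    "spearman_similarity",
    "flag_enhanced",
    "flag_suppressed",
    "network_assignment_test",
    "behavioral_contrast",
    "EASIER_CONDITIONS",
    "HARDER_CONDITIONS",
    "FLAG_THRESHOLD",
]

#: edge-strength threshold (r units) for enhancement/suppression flags
FLAG_THRESHOLD = 0.20

EASIER_CONDITIONS = ("Act", "Act+", "Pas")
HARDER_CONDITIONS = ("Pas+", "Pot", "Pot+")


class CompareError(ValueError):
    """Raised for undefined statistics (too few pairs, empty samples...)."""


@dataclass(frozen=True)
class SimilarityResult:
    """Spearman R_S between two groups' edge r-values on one pair subset."""

    r_s: float
    n: int
    p: float
    subset: str
    groups: tuple[str, str]

    def __post_init__(self) -> None:
        if not (abs(self.r_s) <= 1 + 1e-12 and 0 <= self.p <= 1):
            raise CompareError(f"invalid similarity result: R_S={self.r_s}, p={self.p}")


@dataclass(frozen=True)
class EdgeFlags:
    """Per-pair enhanced/suppressed flags for one comparison."""

    pairs: tuple[PairLabel, ...]
    enhanced: np.ndarray
    suppressed: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        if np.any(self.enhanced & self.suppressed):
            raise CompareError("a pair cannot be both enhanced and suppressed")

    def enhanced_pairs(self) -> list[tuple[str, str]]:
        return [
            (p.region_a, p.region_b)
            for p, f in zip(self.pairs, self.enhanced)
            if f
        ]

    def suppressed_pairs(self) -> list[tuple[str, str]]:
        return [
            (p.region_a, p.region_b)
            for p, f in zip(self.pairs, self.suppressed)
            if f
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_a": [p.region_a for p in self.pairs],
                "region_b": [p.region_b for p in self.pairs],
                "label": [p.label for p in self.pairs],
                "enhanced": self.enhanced,
                "suppressed": self.suppressed,
            }
        )


@dataclass(frozen=True)
class AssignmentTestResult:
    """Wilcoxon rank-sum result for one network-membership contrast.

    ``w`` is the rank-sum of the first (within-network) sample.
    """

    w: float
    p: float
    contrast: str  # "specificity" | "sensitivity"
    network: str
    n_within: int
    n_other: int

    def __post_init__(self) -> None:
        n1, n2 = self.n_within, self.n_other
        w_min = n1 * (n1 + 1) / 2
        w_max = n1 * (2 * n2 + n1 + 1) / 2
        if not (w_min <= self.w <= w_max):
            raise CompareError(
                f"rank-sum W={self.w} outside attainable range [{w_min}, {w_max}]"
            )


@dataclass(frozen=True)
class ContrastResult:
    """Two-sided t-test record for a behavioral contrast."""

    t: float
    df: float
    p: float
    design: str
    measure: str
    mean_diff: float


def _pair_values(
    A: PartialCorrMatrix,
    B: PartialCorrMatrix,
    pairs: PairClassification,
    subset: str,
) -> tuple[np.ndarray, np.ndarray, tuple[PairLabel, ...]]:
    if A.region_names != B.region_names:
        raise CompareError("group matrices have mismatched region order")
    selected = pairs.subset(subset)
    if not selected:
        raise CompareError(f"pair subset {subset!r} is empty")
    return A.pair_vector(selected), B.pair_vector(selected), selected


def _exact_spearman_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 10)."""
    n = len(a)
    ra = scipy.stats.rankdata(a)
    rb = scipy.stats.rankdata(b)

    def rho(perm_rb: np.ndarray) -> float:
        return float(np.corrcoef(ra, perm_rb)[0, 1])

    observed = abs(rho(rb))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if abs(rho(rb[list(perm)])) >= observed - 1e-12:
            count += 1
    return count / total


def spearman_similarity(
    A: PartialCorrMatrix,
    B: PartialCorrMatrix,
    pairs: PairClassification,
    subset: Literal["within", "between", "all"] = "all",
    method: Literal["asymptotic", "exact"] = "asymptotic",
) -> SimilarityResult:
    """Spearman rank correlation of two groups' r-values on a pair subset.

    Ties get average ranks; the two-sided p-value uses the large-sample
    t approximation, or exact permutation enumeration when
    ``method="exact"`` (n <= 10 only).
    """
    a, b, selected = _pair_values(A, B, pairs, subset)
    n = len(selected)
    if n < 3:
        raise CompareError(f"R_S needs at least 3 pairs, got {n}")
    res = scipy.stats.spearmanr(a, b)
    r_s, p = float(res.statistic), float(res.pvalue)
    if method == "exact":
        if n > 10:
            raise CompareError("exact permutation p limited to n <= 10")
        p = _exact_spearman_p(a, b)
    return SimilarityResult(
        r_s=r_s,
        n=n,
        p=p,
        subset=subset,
        groups=(A.provenance, B.provenance),
    )


def flag_enhanced(
    groups: Sequence[PartialCorrMatrix],
    pairs: PairClassification,
    threshold: float = FLAG_THRESHOLD,
    restrict: Literal["within", "between", "all"] = "between",
) -> EdgeFlags:
    """Flag pairs with r strictly above threshold in *every* group matrix.

    Restricted by default to between-network pairs (the cross-talk
    enhancement criterion); set ``restrict="within"`` for the
    within-network consistency flags of the full 25-region analysis.
    """
    if not groups:
        raise CompareError("empty group list")
    selected = pairs.subset(restrict)
    values = np.stack([g.pair_vector(selected) for g in groups])
    enhanced = np.all(values > threshold, axis=0)
    return EdgeFlags(
        pairs=selected,
        enhanced=enhanced,
        suppressed=np.zeros_like(enhanced),
        threshold=threshold,
    )


def flag_suppressed(
    reference: PartialCorrMatrix,
    groups: Sequence[PartialCorrMatrix],
    pairs: PairClassification,
    threshold: float = FLAG_THRESHOLD,
    restrict: Literal["within", "between", "all"] = "within",
) -> EdgeFlags:
    """Flag pairs strong in the reference (r > threshold) but weak
    (r <= threshold) in every target group matrix.

    Declared convention for the "weaker connectivity" marks: symmetric
    with the enhancement rule around the same threshold.
    """
    if not groups:
        raise CompareError("empty group list")
    selected = pairs.subset(restrict)
    ref = reference.pair_vector(selected)
    values = np.stack([g.pair_vector(selected) for g in groups])
    suppressed = (ref > threshold) & np.all(values <= threshold, axis=0)
    return EdgeFlags(
        pairs=selected,
        enhanced=np.zeros_like(suppressed),
        suppressed=suppressed,
        threshold=threshold,
    )


def _rank_sum_test(
    within_vals: np.ndarray, other_vals: np.ndarray, contrast: str, network: str
) -> AssignmentTestResult:
    if len(within_vals) == 0 or len(other_vals) == 0:
        raise CompareError(f"{contrast} test for network {network}: empty sample")
    res = scipy.stats.mannwhitneyu(
        within_vals, other_vals, alternative="two-sided", method="auto"
    )
    n1 = len(within_vals)
    w = float(res.statistic) + n1 * (n1 + 1) / 2  # U1 -> rank-sum of sample 1
    return AssignmentTestResult(
        w=w,
        p=float(res.pvalue),
        contrast=contrast,
        network=network,
        n_within=n1,
        n_other=len(other_vals),
    )


def network_assignment_test(
    G: PartialCorrMatrix, pairs: PairClassification, network: str
) -> tuple[AssignmentTestResult, AssignmentTestResult]:
    """Specificity and sensitivity rank-sum tests for one network.

    Specificity: within-network r vs r of between-network pairs linking
    this network to any other (distinctness of the block).  Sensitivity:
    within-network r vs within-r of all other networks (comparable
    block strength).
    """
    within = G.pair_vector(pairs.subset("within", network))
    linking = G.pair_vector(pairs.subset("between", network))
    other_within_pairs = tuple(
        p for p in pairs.subset("within") if network not in p.networks
    )
    if len(within) == 0:
        raise CompareError(f"network {network!r} has no within pairs")
    other_within = G.pair_vector(other_within_pairs)
    specificity = _rank_sum_test(within, linking, "specificity", network)
    sensitivity = _rank_sum_test(within, other_within, "sensitivity", network)
    return specificity, sensitivity


def _condition_means(
    table: pd.DataFrame, measure: str, conditions: Sequence[str]
) -> pd.Series:
    col = {"error": "error_rate", "rt": "mean_rt"}[measure]
    sub = table[table["condition"].isin(conditions)]
    # unweighted mean over the member conditions, per participant
    per_cond = sub.pivot_table(
        index="participant", columns="condition", values=col, aggfunc="mean"
    )
    return per_cond.mean(axis=1)


def behavioral_contrast(
    table: pd.DataFrame,
    measure: Literal["error", "rt"],
    design: Literal["paired", "unpaired"] = "paired",
    groups: tuple[str, str] | None = None,
    condition: str | None = None,
) -> ContrastResult:
    """Behavioral t-test: harder-vs-easier within participants, or
    group-vs-group on one condition.

    Paired design: each participant's harder mean (over Pas+, Pot, Pot+)
    against their easier mean (over Act, Act+, Pas); control and
    one-argument conditions are excluded.  Unpaired design: two
    participant groups compared on a single condition.
    """
    if design == "paired":
        easier = _condition_means(table, measure, EASIER_CONDITIONS)
        harder = _condition_means(table, measure, HARDER_CONDITIONS)
        common = easier.index.intersection(harder.index)
        if len(common) < 2:
            raise CompareError("paired contrast needs at least 2 participants")
        diffs = harder.loc[common] - easier.loc[common]
        if np.allclose(diffs.std(ddof=1), 0) and np.allclose(diffs.mean(), 0):
            t, p = 0.0, 1.0
        else:
            res = scipy.stats.ttest_rel(harder.loc[common], easier.loc[common])
            t, p = float(res.statistic), float(res.pvalue)
        return ContrastResult(
            t=t,
            df=len(common) - 1,
            p=p,
            design="paired harder-easier",
            measure=measure,
            mean_diff=float(diffs.mean()),
        )
    if design == "unpaired":
        if groups is None or condition is None:
            raise CompareError("unpaired design needs groups=(a, b) and condition=")
        col = {"error": "error_rate", "rt": "mean_rt"}[measure]
        samples = []
        for g in groups:
            sub = table[(table["group"] == g) & (table["condition"] == condition)]
            vals = sub.groupby("participant")[col].mean()
            if len(vals) < 2:
                raise CompareError(
                    f"unpaired contrast: fewer than 2 participants in group {g!r}"
                )
            samples.append(vals.to_numpy())
        res = scipy.stats.ttest_ind(samples[0], samples[1])
        return ContrastResult(
            t=float(res.statistic),
            df=len(samples[0]) + len(samples[1]) - 2,
            p=float(res.pvalue),
            design=f"unpaired {groups[0]} vs {groups[1]} ({condition})",
            measure=measure,
            mean_diff=float(samples[0].mean() - samples[1].mean()),
        )
    raise CompareError(f"unknown design {design!r}")
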