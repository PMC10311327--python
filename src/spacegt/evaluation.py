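"""Callset comparison metrics and paired statistics.

Comparison is strict: a site counts as a true positive only when the
predicted unphased genotype equals the truth genotype exactly; a genotype
mismatch at a truth-variant site contributes one false negative *and* one
false positive.  Sites with undefined truth are removed from both sets.

Besides precision/recall/F, the weighted genotype concordance (wGC)
averages per-genotype-class concordances over classes 0|0, 0|1 and 1|1,
correcting for the class imbalance of panel-derived callsets in which
absent genotypes dominate.

Significance of paired per-sample metric differences is assessed with the
exact two-sided Wilcoxon signed-rank test (full enumeration of the 2^n
sign assignments, average ranks on ties), whose smallest attainable
p-value at n paired samples is 2^(1-n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "Genotype",
    "ComparisonResult",
    "PrecisionRecallF",
    "genotype_class",
    "variant_class",
    "compare",
    "precision_recall_f",
    "weighted_genotype_concordance",
    "wilcoxon_exact",
    "bonferroni_bound",
    "improvement_correlation",
]

#: Unordered diploid genotype as a sorted allele-index pair; None = undefined.
Genotype = tuple[int, int] | None

CLASSES = ("0|0", "0|1", "1|1")

ABSENT = (0, 0)


def genotype_class(gt: Genotype) -> str:
    """Map a genotype to the three-class scheme 0|0 / 0|1 / 1|1.

    Any heterozygote with one reference allele is 0|1; genotypes without a
    reference allele (including multi-allelic ones) fall in class 1|1.
    """
    if gt is None:
        return "*|*"
    if gt == ABSENT:
        return "0|0"
    if 0 in gt:
        return "0|1"
    return "1|1"


def variant_class(ref: str, alts: Iterable[str]) -> str:
    """SNV / indel (<50 bp) / SV (>=50 bp) by REF/ALT length difference."""
    alts = tuple(alts)
    diff = max(abs(len(ref) - len(a)) for a in alts)
    if diff >= 50:
        return "SV"
    if diff == 0 and len(ref) == 1:
        return "SNV"
    return "indel"


@dataclass
class ComparisonResult:
    """Strict TP/FP/FN tallies plus per-genotype-class counts."""

    TP: int = 0
    FP: int = 0
    FN: int = 0
    class_correct: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CLASSES})
    class_wrong: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CLASSES})
    n_removed_undefined_truth: int = 0
    n_predicted_undefined: int = 0

    def __add__(self, other: "ComparisonResult") -> "ComparisonResult":
        out = ComparisonResult(
            self.TP + other.TP, self.FP + other.FP, self.FN + other.FN,
            {c: self.class_correct[c] + other.class_correct[c] for c in CLASSES},
            {c: self.class_wrong[c] + other.class_wrong[c] for c in CLASSES},
            self.n_removed_undefined_truth + other.n_removed_undefined_truth,
            self.n_predicted_undefined + other.n_predicted_undefined,
        )
        return out


def compare(truth: Mapping, predicted: Mapping,
            universe: Iterable) -> ComparisonResult:
    """Score ``predicted`` against ``truth`` over the known-variant universe.

    All three arguments are keyed by site identity; genotype values are
    unordered allele pairs or None (undefined).  A universe site missing
    from ``truth`` is treated as absent truth; missing from ``predicted``
    as an undefined prediction (no claim is made, so it is never a false
    positive, but it is incorrect at truth-variant sites).
    """
    universe = set(universe)
    stray = set(predicted) - universe
    if stray:
        raise ValueError(
            f"{len(stray)} predicted sites are outside the known-variant "
            f"universe (e.g. {sorted(stray)[0]!r})"
        )
    result = ComparisonResult()
    for site in universe:
        t = truth.get(site, ABSENT)
        if t is None:
            result.n_removed_undefined_truth += 1
            continue
        p = predicted.get(site)
        if p is None:
            result.n_predicted_undefined += 1
        correct = p == t
        cls = genotype_class(t)
        if correct:
            result.class_correct[cls] += 1
        else:
            result.class_wrong[cls] += 1
        t_variant = t != ABSENT
        p_variant = p is not None and p != ABSENT
        if t_variant and correct:
            result.TP += 1
        else:
            if t_variant:
                result.FN += 1
            if p_variant:
                result.FP += 1
    return result


class PrecisionRecallF(NamedTuple):
    precision: float
    recall: float
    f_score: float


def precision_recall_f(result: ComparisonResult) -> PrecisionRecallF:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), F their harmonic mean.

    Any 0/0 ratio is defined as 0.
    """
    tp, fp, fn = result.TP, result.FP, result.FN
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = (2 * precision * recall / (precision + recall)
         if precision + recall else 0.0)
    return PrecisionRecallF(precision, recall, f)


def weighted_genotype_concordance(result: ComparisonResult) -> float:
    """Mean of per-class concordances T/(T+F) over 0|0, 0|1, 1|1.

    Classes with no sites are excluded from the mean; raises if all three
    are empty.
    """
    concs = []
    for cls in CLASSES:
        total = result.class_correct[cls] + result.class_wrong[cls]
        if total:
            concs.append(result.class_correct[cls] / total)
    if not concs:
        raise ValueError("all genotype classes are empty")
    return float(np.mean(concs))


def wilcoxon_exact(a: Sequence[float], b: Sequence[float] | None = None,
                   alternative: str = "two-sided") -> float:
    """Exact two-sided Wilcoxon signed-rank p-value by full enumeration.

    ``a`` holds paired differences, or the first sample when ``b`` is
    given.  Zero differences are dropped; absolute differences receive
    average ranks on ties; all ``2^n`` sign assignments of the ranks are
    enumerated exactly (integer arithmetic on doubled ranks), and
    ``p = min(1, 2 * min(P(W <= w), P(W >= w)))``.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    d = np.asarray(a, dtype=float)
    if b is not None:
        d = d - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = d.shape[0]
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n > 25:
        raise ValueError("exact enumeration supported for n <= 25")
    ranks = rankdata(np.abs(d))
    r2 = np.rint(2 * ranks).astype(int)  # doubled ranks are integers
    w2_obs = int(r2[d > 0].sum())
    total = int(r2.sum())
    ways = np.zeros(total + 1, dtype=np.int64)
    ways[0] = 1
    for r in r2:
        ways[r:] += ways[:-r].copy() if r else ways.copy()
    denom = float(2 ** n)
    p_le = ways[: w2_obs + 1].sum() / denom
    p_ge = ways[w2_obs:].sum() / denom
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def bonferroni_bound(p: float, m: int) -> float:
    """Bonferroni upper bound min(1, m*p) on a corrected p-value."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return min(1.0, m * p)


def improvement_correlation(results_a: Sequence[float],
                            results_b: Sequence[float],
                            results_baseline: Sequence[float]) -> float:
    """Pearson correlation of metric improvements over a shared baseline.

    Correlates ``results_a - results_baseline`` with
    ``results_b - results_baseline`` across aligned
    (sample, variant class, metric) entries.
    """
    a = np.asarray(results_a, dtype=float)
    b = np.asarray(results_b, dtype=float)
    base = np.asarray(results_baseline, dtype=float)
    if not (a.shape == b.shape == base.shape) or a.ndim != 1 or a.size < 2:
        raise ValueError("need three aligned vectors of equal length >= 2")
    da = a - base
    db = b - base
    if np.std(da) == 0 or np.std(db) == 0:
        raise ValueError("zero variance in a difference vector")
    return float(np.corrcoef(da, db)[0, 1])
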