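"""Diploid genotyping over the bubble graph with a haplotype-pair HMM.

The hidden state at each bubble is an (ordered, internally) pair of panel
haplotypes; consecutive bubbles are linked by a Li–Stephens transition in
which each haplotype independently switches with probability
``theta = 1 - exp(-rho * d)`` (``d`` = reference distance) and lands
uniformly on one of the ``H`` panel haplotypes.  Emissions compare the
observed counts of allele-unique spaced k-mers with Poisson expectations:
mean ``c`` for two copies of the owning allele, ``c/2`` for one, and the
error rate ``epsilon * c`` for zero copies.  Posterior genotypes are
forward–backward marginals summed over states inducing the same unordered
allele pair, so linkage disequilibrium in the panel informs bubbles whose
alleles own no unique k-mers.  A bubble with no k-mer evidence and no LD
context (a lone bubble on its chromosome) is reported undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .counting import KmerCountTable
from .pangenome import (
    Bubble,
    PangenomeGraph,
    UniqueKmerIndex,
    index_unique_kmers,
)
from .seeds import Seed

__all__ = [
    "GenotypingParams",
    "GenotypeCall",
    "genotype",
    "genotype_posteriors",
    "calls_to_site_genotypes",
    "write_calls",
]


@dataclass
class GenotypingParams:
    """Parameters of the genotyping model.

    c: diploid k-mer coverage (expected count of a k-mer present on both
    haplotypes); epsilon: relative rate of erroneous counts for alleles
    with zero copies; rho: per-base haplotype switch rate.
    """

    seed: Seed
    c: float
    epsilon: float = 0.01
    rho: float = 1e-5

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")
        if self.rho < 0.0:
            raise ValueError("rho must be >= 0")


@dataclass
class GenotypeCall:
    """Diploid call for one bubble.

    ``genotype`` is an unordered allele-index pair, or None when the call
    is undefined; ``posterior`` is the probability mass of the reported
    genotype under the HMM.
    """

    bubble: int
    genotype: tuple[int, int] | None
    posterior: float

    @property
    def undefined(self) -> bool:
        return self.genotype is None

    @property
    def genotype_class(self) -> str:
        g = self.genotype
        if g is None:
            return "*|*"
        if g == (0, 0):
            return "0|0"
        if 0 in g:
            return "0|1"
        if g[0] == g[1]:
            return "1|1" if g[0] == 1 else "multi-hom"
        return "multi-het"


def _log_poisson(count: int, mean: float) -> float:
    if mean <= 0.0:
        return 0.0 if count == 0 else -math.inf
    return count * math.log(mean) - mean - float(gammaln(count + 1))


def _emission_matrix(bubble: Bubble, b_idx: int, index: UniqueKmerIndex,
                     counts: KmerCountTable, params: GenotypingParams,
                     informative: bool) -> np.ndarray:
    """Log emission over ordered haplotype pairs (H x H)."""
    al = bubble.panel_alleles
    H = al.shape[0]
    logE = np.zeros((H, H))
    if not informative:
        return logE
    c = params.c
    means = (params.epsilon * c, c / 2.0, c)
    for a in range(len(bubble.alleles)):
        kmers = index.by_allele.get((b_idx, a))
        if not kmers:
            continue
        obs = [counts.get(k) for k in kmers]
        ll = np.array([
            sum(_log_poisson(o, means[m]) for o in obs) for m in range(3)
        ])
        copies = (al[:, None] == a).astype(int) + (al[None, :] == a).astype(int)
        logE += ll[copies]
    return logE


def _transition_apply(F: np.ndarray, theta: float, H: int) -> np.ndarray:
    """One Li–Stephens pair-transition step applied to an H x H table."""
    v = 1.0 - theta
    u = theta / H
    col = F.sum(axis=0, keepdims=True)  # sums over first haplotype
    row = F.sum(axis=1, keepdims=True)
    tot = F.sum()
    return v * v * F + u * v * (col + row) + u * u * tot


def _chain_posteriors(bubbles: list[Bubble], emissions: list[np.ndarray],
                      distances: list[int], rho: float) -> list[np.ndarray]:
    """Scaled forward–backward over one chromosome chain."""
    H = bubbles[0].panel_alleles.shape[0]
    thetas = [1.0 - math.exp(-rho * d) for d in distances]
    E = []
    for logE in emissions:
        m = logE.max()
        E.append(np.exp(logE - m))
    n = len(bubbles)
    fwd = []
    f = np.full((H, H), 1.0 / (H * H)) * E[0]
    f /= f.sum()
    fwd.append(f)
    for t in range(1, n):
        f = _transition_apply(fwd[-1], thetas[t - 1], H) * E[t]
        f /= f.sum()
        fwd.append(f)
    post = [None] * n
    b = np.ones((H, H))
    post[n - 1] = fwd[n - 1]
    for t in range(n - 2, -1, -1):
        b = _transition_apply(b * E[t + 1], thetas[t], H)
        b /= b.sum()
        g = fwd[t] * b
        post[t] = g / g.sum()
    return post


def genotype_posteriors(graph: PangenomeGraph, counts: KmerCountTable,
                        params: GenotypingParams,
                        index: UniqueKmerIndex | None = None
                        ) -> list[dict[tuple[int, int], float] | None]:
    """Per-bubble posterior over unordered allele pairs (None = undefined)."""
    if counts.seed.pattern != params.seed.pattern:
        raise ValueError("count table and params use different seeds")
    if index is None:
        index = index_unique_kmers(graph, params.seed)
    have_data = counts.total() > 0
    if have_data and params.c <= 0.0:
        raise ValueError("coverage must be > 0 when counts are non-empty")

    results: list[dict[tuple[int, int], float] | None] = [None] * len(graph.bubbles)
    for chain in graph.chains():
        bubbles = [graph.bubbles[i] for i in chain]
        informative = [
            have_data and index.bubble_has_kmers(i, len(graph.bubbles[i].alleles))
            for i in chain
        ]
        if len(chain) == 1 and not informative[0]:
            continue  # no evidence and no LD context: undefined
        emissions = [
            _emission_matrix(b, i, index, counts, params, inf)
            for b, i, inf in zip(bubbles, chain, informative)
        ]
        distances = [
            max(1, bubbles[t].start - bubbles[t - 1].end)
            for t in range(1, len(bubbles))
        ]
        posts = _chain_posteriors(bubbles, emissions, distances, params.rho)
        for b, i, P in zip(bubbles, chain, posts):
            al = b.panel_alleles
            lo = np.minimum(al[:, None], al[None, :])
            hi = np.maximum(al[:, None], al[None, :])
            agg: dict[tuple[int, int], float] = {}
            for g_lo, g_hi, p in zip(lo.ravel(), hi.ravel(), P.ravel()):
                key = (int(g_lo), int(g_hi))
                agg[key] = agg.get(key, 0.0) + float(p)
            results[i] = agg
    return results


def _argmax_genotype(post: dict[tuple[int, int], float]) -> tuple[tuple[int, int], float]:
    best_p = max(post.values())
    # ties broken toward more reference alleles, then lowest allele indices
    tied = [g for g, p in post.items() if p == best_p]
    tied.sort(key=lambda g: (-sum(1 for a in g if a == 0), g))
    return tied[0], best_p


def genotype(graph: PangenomeGraph, counts: KmerCountTable,
             params: GenotypingParams,
             index: UniqueKmerIndex | None = None) -> list[GenotypeCall]:
    """Genotype every bubble; see module docstring for the model."""
    posteriors = genotype_posteriors(graph, counts, params, index)
    calls = []
    for i, post in enumerate(posteriors):
        if post is None:
            calls.append(GenotypeCall(i, None, 0.0))
        else:
            g, p = _argmax_genotype(post)
            calls.append(GenotypeCall(i, g, min(p, 1.0)))
    return calls


def calls_to_site_genotypes(calls: list[GenotypeCall], graph: PangenomeGraph
                            ) -> dict[tuple, tuple[int, int] | None]:
    """Decompose bubble calls to per-VCF-record genotypes.

    Keys are site identities ``(chrom, start, ref, alts)``; values are
    unordered allele pairs or None for undefined (including merged alleles
    whose record-level decomposition is ambiguous).
    """
    out: dict[tuple, tuple[int, int] | None] = {}
    for call in calls:
        bubble = graph.bubbles[call.bubble]
        if call.genotype is None:
            for site in bubble.sites:
                out[site.key] = None
            continue
        a1, a2 = call.genotype
        comp1 = bubble.allele_components[a1]
        comp2 = bubble.allele_components[a2]
        for s_idx, site in enumerate(bubble.sites):
            if comp1 is None or comp2 is None:
                out[site.key] = None
            else:
                pair = (comp1[s_idx], comp2[s_idx])
                out[site.key] = (min(pair), max(pair))
    return out


def _gq(posterior: float) -> int:
    err = max(1.0 - posterior, 1e-10)
    return min(99, int(round(-10.0 * math.log10(err))))


def write_calls(calls: list[GenotypeCall], graph: PangenomeGraph,
                path: str | Path, sample: str = "SAMPLE") -> None:
    """Write calls as VCF 4.2 with GT and GQ.

    Merged bubbles are decomposed back to the original records where the
    called alleles map unambiguously to per-record alleles; otherwise the
    merged record itself is emitted.  Undefined calls are written './.'.
    """
    lines = ["##fileformat=VCFv4.2"]
    for chrom, seq in graph.reference.items():
        lines.append(f"##contig=<ID={chrom},length={len(seq)}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                 'Description="Genotype quality (phred posterior)">')
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")

    records: list[tuple[str, int, str, str, str, str]] = []
    for call in calls:
        bubble = graph.bubbles[call.bubble]
        if call.genotype is None:
            for site in bubble.sites:
                records.append((site.chrom, site.start, site.ref,
                                ",".join(site.alts), "./.", "."))
            continue
        a1, a2 = call.genotype
        comp1 = bubble.allele_components[a1]
        comp2 = bubble.allele_components[a2]
        gq = str(_gq(call.posterior))
        if comp1 is not None and comp2 is not None:
            for s_idx, site in enumerate(bubble.sites):
                pair = sorted((comp1[s_idx], comp2[s_idx]))
                records.append((site.chrom, site.start, site.ref,
                                ",".join(site.alts),
                                f"{pair[0]}/{pair[1]}", gq))
        else:
            alts = ",".join(bubble.alleles[1:]) or "."
            records.append((bubble.chrom, bubble.start, bubble.alleles[0],
                            alts, f"{min(a1, a2)}/{max(a1, a2)}", gq))
    records.sort(key=lambda r: (r[0], r[1]))
    for chrom, start, ref, alts, gt, gq in records:
        lines.append(
            f"{chrom}\t{start + 1}\t.\t{ref}\t{alts}\t.\tPASS\t.\tGT:GQ\t{gt}:{gq}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
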