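"""Pangenome bubble graph, allele-unique spaced k-mers and coverage.

The graph is built from a linear reference plus a phased panel VCF: each
variant (or cluster of nearby variants) becomes a *bubble* whose alleles
are the distinct panel-haplotype subsequences over the bubble span, and
every panel haplotype threads exactly one allele per bubble.  Variants
whose reference spans are closer than the seed length are merged into one
bubble, because windows of length ``l`` would otherwise straddle both.

Genotyping evidence comes from k-mers *unique* to one (bubble, allele):
canonical spaced k-mers that occur exactly once across the reference and
all allele paths.  Their read counts are compared with the expectation
under each candidate genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .counting import (
    KmerCountTable,
    decode_kmers,
    encode_sequence,
    spaced_kmer_codes,
)
from .seeds import Seed

__all__ = [
    "VariantSite",
    "Bubble",
    "PangenomeGraph",
    "UniqueKmerIndex",
    "GraphError",
    "read_fasta",
    "read_panel_vcf",
    "build_graph",
    "index_unique_kmers",
    "estimate_coverage",
]


class GraphError(ValueError):
    """Raised when reference and panel cannot be reconciled."""


@dataclass(frozen=True)
class VariantSite:
    """One panel VCF record (0-based half-open reference span)."""

    chrom: str
    start: int
    ref: str
    alts: tuple[str, ...]
    hap_alleles: tuple[int, ...]

    @property
    def end(self) -> int:
        return self.start + len(self.ref)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def key(self) -> tuple:
        """Site identity used to match callsets: (chrom, start, ref, alts)."""
        return (self.chrom, self.start, self.ref, self.alts)


@dataclass
class Bubble:
    """A variant locus: alternative allele paths between anchor points.

    ``alleles[0]`` is always the reference subsequence over ``[start, end)``;
    ``panel_alleles[h]`` is the allele index threaded by panel haplotype
    ``h``.  ``allele_components`` maps each merged allele back to per-site
    allele indices (None when two haplotype patterns collapsed to the same
    sequence, making the decomposition ambiguous).
    """

    chrom: str
    start: int
    end: int
    alleles: tuple[str, ...]
    panel_alleles: np.ndarray
    sites: list[VariantSite]
    allele_components: list[tuple[int, ...] | None]


@dataclass
class PangenomeGraph:
    reference: dict[str, str]
    bubbles: list[Bubble]
    n_haplotypes: int
    samples: list[str]

    def chains(self) -> list[list[int]]:
        """Bubble indices grouped per chromosome, in reference order."""
        by_chrom: dict[str, list[int]] = {}
        for i, b in enumerate(self.bubbles):
            by_chrom.setdefault(b.chrom, []).append(i)
        return list(by_chrom.values())


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into name -> uppercase sequence."""
    seqs: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            seqs[rec.name] = rec.sequence.upper()
    if not seqs:
        raise GraphError(f"no sequences in {path}")
    return seqs


def read_panel_vcf(path: str | Path) -> tuple[list[VariantSite], list[str]]:
    """Read a phased panel VCF into variant sites plus sample names.

    Genotypes must be phased ('|'); records with any missing haplotype
    allele are dropped, so every retained site assigns an allele to every
    panel haplotype.
    """
    sites: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            haps: list[int] = []
            ok = True
            for sample in samples:
                call = rec.samples[sample]
                alleles = call["GT"]
                if alleles is None or any(a is None for a in alleles):
                    ok = False
                    break
                if len(alleles) == 2 and not call.phased:
                    raise GraphError(
                        f"unphased genotype at {rec.chrom}:{rec.pos} ({sample})"
                    )
                haps.extend(int(a) for a in alleles)
            if not ok:
                continue
            alts = tuple(a for a in (rec.alts or ()))
            if not alts:
                continue
            sites.append(
                VariantSite(rec.chrom, rec.start, rec.ref.upper(),
                            tuple(a.upper() for a in alts), tuple(haps))
            )
    sites.sort(key=lambda s: (s.chrom, s.start))
    return sites, samples


def read_callset_vcf(path: str | Path, sample: str | int = 0
                     ) -> dict[tuple, tuple[int, int] | None]:
    """Read one sample's genotypes from a VCF into site -> genotype.

    Accepts phased or unphased genotypes; missing alleles ('./.') map to
    None (undefined).  Keys are ``(chrom, start, ref, alts)``.
    """
    out: dict[tuple, tuple[int, int] | None] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alleles = rec.samples[sample]["GT"]
            key = (rec.chrom, rec.start, rec.ref.upper(),
                   tuple(a.upper() for a in (rec.alts or ())))
            if alleles is None or any(a is None for a in alleles):
                out[key] = None
            else:
                pair = sorted(int(a) for a in alleles)
                out[key] = (pair[0], pair[-1])
    return out


def _bubble_from_cluster(cluster: list[VariantSite], ref: str) -> Bubble:
    span_start = cluster[0].start
    span_end = max(s.end for s in cluster)
    prev_end = -1
    for s in cluster:
        if s.start < prev_end:
            raise GraphError(
                f"overlapping panel records near {s.chrom}:{s.start + 1} "
                "cannot be reconciled by merging"
            )
        prev_end = s.end

    n_hap = len(cluster[0].hap_alleles)

    def build_seq(components: tuple[int, ...]) -> str:
        parts = []
        cursor = span_start
        for site, a in zip(cluster, components):
            parts.append(ref[cursor:site.start])
            parts.append(site.alleles[a])
            cursor = site.end
        parts.append(ref[cursor:span_end])
        return "".join(parts)

    ref_components = tuple(0 for _ in cluster)
    alleles: list[str] = [build_seq(ref_components)]
    components: list[tuple[int, ...] | None] = [ref_components]
    seq_to_idx = {alleles[0]: 0}
    panel = np.zeros(n_hap, dtype=np.int16)
    for h in range(n_hap):
        comp = tuple(site.hap_alleles[h] for site in cluster)
        seq = build_seq(comp)
        idx = seq_to_idx.get(seq)
        if idx is None:
            idx = len(alleles)
            seq_to_idx[seq] = idx
            alleles.append(seq)
            components.append(comp)
        elif components[idx] is not None and components[idx] != comp:
            components[idx] = None  # ambiguous decomposition
        panel[h] = idx
    return Bubble(cluster[0].chrom, span_start, span_end, tuple(alleles),
                  panel, list(cluster), components)


def build_graph(reference: dict[str, str] | str | Path,
                panel: list[VariantSite] | str | Path,
                seed: Seed,
                samples: list[str] | None = None) -> PangenomeGraph:
    """Build the bubble graph, merging variants closer than ``seed.l``.

    ``reference`` may be a FASTA path or a name -> sequence mapping;
    ``panel`` a VCF path or a pre-parsed site list.
    """
    if not isinstance(reference, dict):
        reference = read_fasta(reference)
    if isinstance(panel, (str, Path)):
        panel, samples = read_panel_vcf(panel)
    sites = sorted(panel, key=lambda s: (s.chrom, s.start))
    n_hap = len(sites[0].hap_alleles) if sites else 0
    for s in sites:
        if s.chrom not in reference:
            raise GraphError(f"panel chromosome {s.chrom!r} not in reference")
        actual = reference[s.chrom][s.start:s.end]
        if actual != s.ref:
            raise GraphError(
                f"REF mismatch at {s.chrom}:{s.start + 1}: "
                f"VCF says {s.ref!r}, reference has {actual!r}"
            )
        if len(s.hap_alleles) != n_hap:
            raise GraphError("inconsistent haplotype count across records")

    bubbles: list[Bubble] = []
    cluster: list[VariantSite] = []
    cluster_end = None
    for s in sites:
        if cluster and (s.chrom != cluster[0].chrom
                        or s.start - cluster_end >= seed.l):
            bubbles.append(_bubble_from_cluster(cluster, reference[cluster[0].chrom]))
            cluster = []
        cluster.append(s)
        cluster_end = max(cluster_end, s.end) if len(cluster) > 1 else s.end
    if cluster:
        bubbles.append(_bubble_from_cluster(cluster, reference[cluster[0].chrom]))

    if samples is None:
        samples = [f"sample{i}" for i in range(n_hap // 2)]
    return PangenomeGraph(reference, bubbles, n_hap, samples)


@dataclass
class UniqueKmerIndex:
    """Canonical spaced k-mers owned by exactly one (bubble, allele).

    A k-mer qualifies iff its total multiplicity across the full reference
    and every allele path is exactly one, and it occurs in exactly one
    allele path.  ``carriers`` counts panel haplotypes threading the
    owning allele (used for coverage estimation).
    """

    seed: Seed
    kmer_home: dict[str, tuple[int, int]]
    by_allele: dict[tuple[int, int], list[str]] = field(default_factory=dict)
    carriers: dict[tuple[int, int], int] = field(default_factory=dict)

    def n_kmers(self) -> int:
        return len(self.kmer_home)

    def bubble_has_kmers(self, bubble_idx: int, n_alleles: int) -> bool:
        return any(self.by_allele.get((bubble_idx, a)) for a in range(n_alleles))


def _allele_path(graph: PangenomeGraph, bubble: Bubble, allele_idx: int,
                 flank: int) -> str:
    ref = graph.reference[bubble.chrom]
    left = ref[max(0, bubble.start - flank):bubble.start]
    right = ref[bubble.end:bubble.end + flank]
    return left + bubble.alleles[allele_idx] + right


def index_unique_kmers(graph: PangenomeGraph, seed: Seed) -> UniqueKmerIndex:
    """Index spaced k-mers unique to one allele of one bubble.

    Multiplicities are accumulated over every chromosome of the reference
    plus every non-reference allele path (allele paths carry ``l - 1``
    reference bases of flank on each side); reference-allele path k-mers
    are counted through the reference itself.
    """
    flank = seed.l - 1
    multiplicity: dict[int, int] = {}

    def add_counts(seq: str) -> None:
        packed, _, _ = spaced_kmer_codes(encode_sequence(seq), seed)
        if packed.size:
            uniq, cnt = np.unique(packed, return_counts=True)
            for k, c in zip(uniq.tolist(), cnt.tolist()):
                multiplicity[k] = multiplicity.get(k, 0) + c

    for chrom_seq in graph.reference.values():
        add_counts(chrom_seq)
    for bubble in graph.bubbles:
        for a in range(1, len(bubble.alleles)):
            add_counts(_allele_path(graph, bubble, a, flank))

    homes: dict[int, list[tuple[int, int]]] = {}
    for b_idx, bubble in enumerate(graph.bubbles):
        for a in range(len(bubble.alleles)):
            packed, _, _ = spaced_kmer_codes(
                encode_sequence(_allele_path(graph, bubble, a, flank)), seed
            )
            for k in np.unique(packed).tolist():
                homes.setdefault(k, []).append((b_idx, a))

    kmer_home: dict[str, tuple[int, int]] = {}
    by_allele: dict[tuple[int, int], list[str]] = {}
    kept = [(k, hs[0]) for k, hs in homes.items()
            if len(hs) == 1 and multiplicity.get(k, 0) == 1]
    if kept:
        packed = np.array([k for k, _ in kept], dtype=np.uint64)
        strings = decode_kmers(packed, seed.w)
        for (_, home), s in zip(kept, strings):
            kmer_home[s] = home
            by_allele.setdefault(home, []).append(s)
    for kmers in by_allele.values():
        kmers.sort()

    carriers = {}
    for b_idx, bubble in enumerate(graph.bubbles):
        for a in range(len(bubble.alleles)):
            carriers[(b_idx, a)] = int((bubble.panel_alleles == a).sum())
    return UniqueKmerIndex(seed, kmer_home, by_allele, carriers)


def estimate_coverage(index: UniqueKmerIndex, counts: KmerCountTable) -> float:
    """Diploid k-mer coverage from the count histogram of common alleles.

    Restricted to unique k-mers of alleles carried by at least half the
    panel (both copies of such alleles are usually present, so their
    counts cluster at the diploid coverage); the mode of the nonzero count
    histogram is returned, falling back to the mean when no single count
    value dominates.  Returns 0.0 when no restricted k-mer was observed.
    """
    if not index.kmer_home:
        raise ValueError("unique k-mer index is empty")
    if counts.seed.pattern != index.seed.pattern:
        raise ValueError("count table was produced with a different seed")
    n_hap = max(
        (sum(c for (b, a2), c in index.carriers.items() if b == b0)
         for b0 in {b for b, _ in index.carriers}),
        default=0,
    )
    observed = [
        counts.get(k)
        for (b, a), kmers in index.by_allele.items()
        if index.carriers.get((b, a), 0) * 2 >= n_hap
        for k in kmers
    ]
    observed = [c for c in observed if c > 0]
    if not observed:
        return 0.0
    hist = np.bincount(observed).astype(float)
    top = hist.max()
    if (hist == top).sum() > 1 or top == 1:
        return float(np.mean(observed))
    # the histogram is a het/hom mixture with peaks near c/2 and c: smooth,
    # take the modal peak, and prefer the doubled position when it also
    # carries substantial mass (then the mode was the one-copy peak)
    smooth = np.convolve(hist, np.ones(3) / 3.0, mode="full")[1:1 + len(hist)]
    peak = smooth.max()
    candidates = np.flatnonzero(smooth == peak)
    m = int(candidates[np.argmax(hist[candidates])])  # tie-break on raw mass

    def mass(x: int) -> float:
        lo, hi = max(0, x - 2), min(len(smooth), x + 3)
        return float(smooth[lo:hi].sum()) if lo < len(smooth) else 0.0

    doubled = 2 * m
    if doubled < len(smooth) + 2 and mass(doubled) >= 0.25 * mass(m):
        lo, hi = max(1, doubled - 2), min(len(hist), doubled + 3)
        if hi > lo and hist[lo:hi].sum() > 0:
            vals = np.arange(lo, hi)
            return float((vals * hist[lo:hi]).sum() / hist[lo:hi].sum())
    return float(m)
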