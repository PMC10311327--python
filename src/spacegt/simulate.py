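"""Synthetic references, phased panels, truth samples and reads.

The generator emulates the study design the genotyper is evaluated under:
a uniform-random reference; a set of founder haplotypes carrying
Poisson-placed SNVs, short indels (<50 bp) and structural variants
(>=50 bp); a panel of haplotypes formed as recombination mosaics of the
founders, which induces linkage disequilibrium between nearby variants;
and uniform-coverage single-end reads with i.i.d. substitution errors.
Panel haplotypes pair up into diploid samples, enabling the leave-one-out
protocol: each sample is genotyped against the panel built from the
remaining samples, with its own two haplotypes as ground truth.

Everything is reproducible bit for bit from (config, rng_seed).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import count_sequences, reverse_complement
from .evaluation import (
    compare,
    precision_recall_f,
    variant_class,
    weighted_genotype_concordance,
    wilcoxon_exact,
)
from .genotyping import (
    GenotypingParams,
    calls_to_site_genotypes,
    genotype,
)
from .pangenome import (
    VariantSite,
    build_graph,
    estimate_coverage,
    index_unique_kmers,
)
from .seeds import Seed

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_panel",
    "simulate_reads",
    "downsample_reads",
    "leave_one_out_run",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the evaluated regime at desk scale: a panel of eleven
    diploid samples (22 haplotypes), 150 bp reads at 30x diploid coverage
    with the HiSeq-class substitution error rate of 0.087%, and variant
    densities in roughly the SNV : indel : SV proportions of a human
    pangenome callset.  Low-coverage experiments downsample or set
    ``coverage=5``.
    """

    ref_length: int = 100_000
    n_founders: int = 6
    n_haplotypes: int = 22
    snv_rate: float = 1.5e-3
    indel_rate: float = 2.5e-4
    sv_rate: float = 2e-5
    indel_len: float = 5.0       # geometric mean length, 1..49
    sv_len_min: int = 50
    sv_len_mean: float = 80.0
    read_length: int = 150
    coverage: float = 30.0
    error_rate: float = 0.00087
    crossover_rate: float = 1e-5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.snv_rate, self.indel_rate, self.sv_rate) < 0:
            raise ValueError("variant rates must be >= 0")
        if self.ref_length < 10 * self.read_length:
            raise ValueError("ref_length must be >= 10 * read_length")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even (diploid samples)")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class SimulatedTruth:
    """A synthetic cohort: reference, phased panel and truth haplotypes."""

    config: SimulationConfig
    chrom: str
    reference: str
    variants: list[VariantSite]      # hap_alleles = panel haplotype alleles
    panel: np.ndarray                # (n_haplotypes, n_variants) allele idx

    @property
    def n_samples(self) -> int:
        return self.config.n_haplotypes // 2

    @property
    def sample_names(self) -> list[str]:
        return [f"s{i}" for i in range(self.n_samples)]

    def haplotype_sequence(self, hap: int) -> str:
        parts = []
        cursor = 0
        for v_idx, site in enumerate(self.variants):
            allele = site.alleles[self.panel[hap, v_idx]]
            parts.append(self.reference[cursor:site.start])
            parts.append(allele)
            cursor = site.end
        parts.append(self.reference[cursor:])
        return "".join(parts)

    def sample_haplotypes(self, sample: int) -> tuple[str, str]:
        return (self.haplotype_sequence(2 * sample),
                self.haplotype_sequence(2 * sample + 1))

    def truth_genotypes(self, sample: int) -> dict[tuple, tuple[int, int]]:
        out = {}
        for v_idx, site in enumerate(self.variants):
            pair = sorted((int(self.panel[2 * sample, v_idx]),
                           int(self.panel[2 * sample + 1, v_idx])))
            out[site.key] = (pair[0], pair[1])
        return out

    # ---- serialization -------------------------------------------------

    def write_reference(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(self.reference), 80):
                fh.write(self.reference[i:i + 80] + "\n")

    def _vcf_header(self, names: list[str]) -> list[str]:
        return [
            "##fileformat=VCFv4.2",
            f"##contig=<ID={self.chrom},length={len(self.reference)}>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names),
        ]

    def write_panel_vcf(self, path: str | Path,
                        exclude_sample: int | None = None) -> None:
        """Phased panel VCF, optionally without one sample's columns."""
        keep = [s for s in range(self.n_samples) if s != exclude_sample]
        lines = self._vcf_header([self.sample_names[s] for s in keep])
        for v_idx, site in enumerate(self.variants):
            gts = [
                f"{self.panel[2 * s, v_idx]}|{self.panel[2 * s + 1, v_idx]}"
                for s in keep
            ]
            lines.append(
                f"{self.chrom}\t{site.start + 1}\t.\t{site.ref}\t"
                f"{','.join(site.alts)}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def write_truth_vcf(self, sample: int, path: str | Path) -> None:
        lines = self._vcf_header([self.sample_names[sample]])
        for v_idx, site in enumerate(self.variants):
            gt = (f"{self.panel[2 * sample, v_idx]}|"
                  f"{self.panel[2 * sample + 1, v_idx]}")
            lines.append(
                f"{self.chrom}\t{site.start + 1}\t.\t{site.ref}\t"
                f"{','.join(site.alts)}\t.\tPASS\t.\tGT\t{gt}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _draw_variants(ref: str, config: SimulationConfig,
                   rng: np.random.Generator) -> list[tuple[int, str, str]]:
    """Non-overlapping (start, ref, alt) triples via rejection sampling."""
    L = len(ref)
    margin = max(config.read_length, 200)
    specs: list[tuple[str, int]] = []
    for vclass, rate in (("snv", config.snv_rate),
                         ("indel", config.indel_rate),
                         ("sv", config.sv_rate)):
        specs.extend((vclass,) for _ in range(rng.poisson(rate * L)))
    out: list[tuple[int, str, str]] = []
    taken: list[tuple[int, int]] = []

    def overlaps(s: int, e: int) -> bool:
        return any(s < te + 1 and ts < e + 1 for ts, te in taken)

    for (vclass,) in specs:
        placed = False
        for _ in range(200):
            if vclass == "snv":
                pos = int(rng.integers(margin, L - margin))
                refa = ref[pos]
                choices = [b for b in "ACGT" if b != refa]
                alt = choices[int(rng.integers(0, 3))]
                s, e, r, a = pos, pos + 1, refa, alt
            else:
                if vclass == "indel":
                    size = int(min(49, rng.geometric(1.0 / config.indel_len)))
                else:
                    size = int(config.sv_len_min - 1 + rng.geometric(
                        1.0 / max(1.0, config.sv_len_mean - config.sv_len_min)))
                deletion = bool(rng.integers(0, 2))
                pos = int(rng.integers(margin, L - margin - size))
                if deletion:
                    s, e = pos, pos + size + 1
                    r, a = ref[s:e], ref[s]
                else:
                    s, e = pos, pos + 1
                    r = ref[s]
                    a = r + _random_sequence(size, rng)
            if not overlaps(s, e):
                taken.append((s, e))
                out.append((s, r, a))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place all variants without overlap; lower the rates"
            )
    out.sort(key=lambda t: t[0])
    return out


def simulate_panel(config: SimulationConfig) -> SimulatedTruth:
    """Generate reference, variant sites and a mosaic haplotype panel.

    Each variant is biallelic; founder haplotypes carry the alternative
    allele as independent coin flips (monomorphic assignments are
    redrawn), and panel haplotypes copy founders with Poisson crossovers,
    inducing LD that decays with distance.
    """
    rng = np.random.default_rng(config.rng_seed)
    ref = _random_sequence(config.ref_length, rng)
    triples = _draw_variants(ref, config, rng)
    n_var = len(triples)

    # neutral site-frequency spectrum: P(i derived copies) ~ 1/i
    founder = np.zeros((config.n_founders, n_var), dtype=np.int16)
    copy_counts = np.arange(1, config.n_founders)
    sfs = 1.0 / copy_counts
    sfs /= sfs.sum()
    for j in range(n_var):
        i = int(rng.choice(copy_counts, p=sfs))
        carriers = rng.choice(config.n_founders, size=i, replace=False)
        founder[carriers, j] = 1

    positions = np.array([t[0] for t in triples])
    panel = np.zeros((config.n_haplotypes, n_var), dtype=np.int16)
    L = config.ref_length
    for h in range(config.n_haplotypes):
        n_cross = rng.poisson(config.crossover_rate * L)
        cuts = np.sort(rng.integers(0, L, size=n_cross))
        sources = rng.integers(0, config.n_founders, size=n_cross + 1)
        seg = np.searchsorted(cuts, positions, side="right")
        if n_var:
            panel[h] = founder[sources[seg], np.arange(n_var)]

    variants = [
        VariantSite("ref1", s, r, (a,), tuple(int(x) for x in panel[:, j]))
        for j, (s, r, a) in enumerate(triples)
    ]
    return SimulatedTruth(config, "ref1", ref, variants, panel)


def simulate_reads(haplotypes: tuple[str, str], config: SimulationConfig,
                   rng_seed: int | None = None) -> list[str]:
    """Uniform single-end reads from a diploid pair with substitution errors.

    The read count is ``round(coverage * total_diploid_length /
    (2 * read_length))``; each read is drawn uniformly from both
    haplotypes and strands, and each base is substituted independently
    with probability ``error_rate``.
    """
    rl = config.read_length
    for hap in haplotypes:
        if rl > len(hap):
            raise ValueError("read length exceeds haplotype length")
    rng = np.random.default_rng(
        config.rng_seed if rng_seed is None else rng_seed)
    total = sum(len(h) for h in haplotypes)
    n_reads = round(config.coverage * total / (2 * rl))
    reads = []
    for _ in range(n_reads):
        hap = haplotypes[int(rng.integers(0, 2))]
        start = int(rng.integers(0, len(hap) - rl + 1))
        seq = hap[start:start + rl]
        if bool(rng.integers(0, 2)):
            seq = reverse_complement(seq)
        n_err = rng.binomial(rl, config.error_rate)
        if n_err:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            pos = rng.choice(rl, size=n_err, replace=False)
            for p in pos:
                base = chr(arr[p])
                choices = [b for b in "ACGT" if b != base]
                arr[p] = ord(choices[int(rng.integers(0, 3))])
            seq = arr.tobytes().decode("ascii")
        reads.append(seq)
    return reads


def write_fastq(reads: list[str], path: str | Path,
                prefix: str = "read") -> None:
    """Write reads with a constant quality string; .gz paths are gzipped."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def downsample_reads(reads: list[str], fraction: float,
                     rng_seed: int = 0) -> list[str]:
    """Keep each read independently with probability ``fraction``."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(reads)
    rng = np.random.default_rng(rng_seed)
    keep = rng.random(len(reads)) < fraction
    return [r for r, k in zip(reads, keep) if k]


def _loo_panel_sites(truth: SimulatedTruth, sample: int
                     ) -> tuple[list[VariantSite], list[int]]:
    """Panel sites without the held-out haplotypes.

    Variants carried (as alt) by neither the held-out truth haplotypes nor
    the remaining panel are dropped from the universe, mirroring the
    leave-one-out protocol.
    """
    held = {2 * sample, 2 * sample + 1}
    keep_haps = [h for h in range(truth.config.n_haplotypes) if h not in held]
    sites = []
    kept_idx = []
    for j, site in enumerate(truth.variants):
        alt_in_truth = any(truth.panel[h, j] > 0 for h in held)
        alt_in_panel = any(truth.panel[h, j] > 0 for h in keep_haps)
        if not (alt_in_truth or alt_in_panel):
            continue
        kept_idx.append(j)
        sites.append(VariantSite(
            site.chrom, site.start, site.ref, site.alts,
            tuple(int(truth.panel[h, j]) for h in keep_haps),
        ))
    return sites, kept_idx


def leave_one_out_run(truth: SimulatedTruth, seeds_to_test: list[Seed],
                      epsilon: float = 0.01, rho: float = 1e-5,
                      samples: list[int] | None = None,
                      coverage: str | float = "auto") -> tuple[pd.DataFrame,
                                                               pd.DataFrame]:
    """Genotype each sample against the panel of the others, per seed.

    Returns (report, stats): the report has one row per (sample, seed,
    variant class) with wGC/precision/recall/F and tallies; the stats
    frame holds exact paired Wilcoxon p-values across samples for every
    seed pair, metric and variant class.
    """
    if truth.n_samples < 2:
        raise ValueError("leave-one-out needs at least 2 diploid samples")
    if samples is None:
        samples = list(range(truth.n_samples))
    rows = []
    for s in samples:
        reads = simulate_reads(
            truth.sample_haplotypes(s), truth.config,
            rng_seed=truth.config.rng_seed + 10_000 + s,
        )
        sites, _ = _loo_panel_sites(truth, s)
        truth_gt = truth.truth_genotypes(s)
        for seed in seeds_to_test:
            graph = build_graph({truth.chrom: truth.reference}, sites, seed)
            counts = count_sequences(reads, seed)
            index = index_unique_kmers(graph, seed)
            c = (estimate_coverage(index, counts)
                 if coverage == "auto" else float(coverage))
            params = GenotypingParams(seed, c if c > 0 else 1.0,
                                      epsilon=epsilon, rho=rho)
            calls = genotype(graph, counts, params, index=index)
            pred = calls_to_site_genotypes(calls, graph)
            by_class: dict[str, tuple[dict, dict, set]] = {}
            for site in sites:
                vc = variant_class(site.ref, site.alts)
                t, p, u = by_class.setdefault(vc, ({}, {}, set()))
                key = site.key
                u.add(key)
                if key in truth_gt:
                    t[key] = truth_gt[key]
                if key in pred:
                    p[key] = pred[key]
            for vc, (t, p, u) in sorted(by_class.items()):
                res = compare(t, p, u)
                prf = precision_recall_f(res)
                try:
                    wgc = weighted_genotype_concordance(res)
                except ValueError:
                    wgc = float("nan")
                rows.append({
                    "sample": truth.sample_names[s], "seed": seed.pattern,
                    "variant_class": vc, "wGC": wgc,
                    "precision": prf.precision, "recall": prf.recall,
                    "F": prf.f_score, "TP": res.TP, "FP": res.FP,
                    "FN": res.FN,
                    "undefined": res.n_predicted_undefined,
                })
    report = pd.DataFrame(rows)
    stats = _paired_seed_stats(report)
    return report, stats


def _paired_seed_stats(report: pd.DataFrame) -> pd.DataFrame:
    rows = []
    seeds = list(dict.fromkeys(report["seed"]))
    metrics = ["wGC", "precision", "recall", "F"]
    for i, sa in enumerate(seeds):
        for sb in seeds[i + 1:]:
            for vc in sorted(report["variant_class"].unique()):
                sub = report[report["variant_class"] == vc]
                a = sub[sub["seed"] == sa].set_index("sample")
                b = sub[sub["seed"] == sb].set_index("sample")
                common = a.index.intersection(b.index)
                for metric in metrics:
                    da = a.loc[common, metric].to_numpy()
                    db = b.loc[common, metric].to_numpy()
                    mask = ~(np.isnan(da) | np.isnan(db))
                    try:
                        p = wilcoxon_exact(da[mask], db[mask])
                    except ValueError:
                        p = float("nan")
                    rows.append({
                        "seed_a": sa, "seed_b": sb, "variant_class": vc,
                        "metric": metric,
                        "mean_a": float(np.nanmean(da)) if mask.any() else float("nan"),
                        "mean_b": float(np.nanmean(db)) if mask.any() else float("nan"),
                        "p_value": p, "n": int(mask.sum()),
                    })
    return pd.DataFrame(rows)
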