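"""Graph construction, unique k-mer indexing and HMM genotyping."""

import itertools
import math
from collections import Counter

import numpy as np
import pysam
import pytest

from spacegt.counting import (
    KmerCountTable,
    canonicalize,
    count_sequences,
    extract_spaced_kmers,
)
from spacegt.genotyping import (
    GenotypingParams,
    calls_to_site_genotypes,
    genotype,
    genotype_posteriors,
    write_calls,
)
from spacegt.pangenome import (
    GraphError,
    VariantSite,
    build_graph,
    estimate_coverage,
    index_unique_kmers,
    read_panel_vcf,
)
from spacegt.seeds import contiguous_seed, parse_seed

from conftest import random_dna


def snp_site(chrom, pos, ref_base, alt_base, haps):
    return VariantSite(chrom, pos, ref_base, (alt_base,), tuple(haps))


# ---------------------------------------------------------------------------
# graph construction


def test_single_snp_gives_one_biallelic_bubble():
    rng = np.random.default_rng(0)
    ref = random_dna(200, rng)
    site = snp_site("c", 100, ref[100], "ACGT".replace(ref[100], "")[0], [0, 1, 0, 1])
    graph = build_graph({"c": ref}, [site], contiguous_seed(31))
    assert len(graph.bubbles) == 1
    bubble = graph.bubbles[0]
    assert len(bubble.alleles) == 2
    assert bubble.alleles[0] == ref[100]
    assert list(bubble.panel_alleles) == [0, 1, 0, 1]


def test_nearby_snps_merge_into_one_bubble_with_haplotype_alleles():
    rng = np.random.default_rng(1)
    ref = random_dna(300, rng)
    a1 = "ACGT".replace(ref[100], "")[0]
    a2 = "ACGT".replace(ref[103], "")[0]
    # 6 haplotypes with three distinct two-SNP patterns: 00, 10, 11
    s1 = snp_site("c", 100, ref[100], a1, [0, 0, 1, 1, 1, 1])
    s2 = snp_site("c", 103, ref[103], a2, [0, 0, 0, 0, 1, 1])
    graph = build_graph({"c": ref}, [s1, s2], contiguous_seed(31))
    assert len(graph.bubbles) == 1
    bubble = graph.bubbles[0]
    assert (bubble.start, bubble.end) == (100, 104)
    assert len(bubble.alleles) == 3  # ref pattern, 10 pattern, 11 pattern
    assert bubble.allele_components[0] == (0, 0)
    assert set(bubble.allele_components[1:]) == {(1, 0), (1, 1)}


def test_distant_snps_stay_separate_bubbles():
    rng = np.random.default_rng(2)
    ref = random_dna(400, rng)
    sites = [
        snp_site("c", 100, ref[100], "ACGT".replace(ref[100], "")[0], [0, 1]),
        snp_site("c", 200, ref[200], "ACGT".replace(ref[200], "")[0], [1, 0]),
    ]
    graph = build_graph({"c": ref}, sites, contiguous_seed(31))
    assert len(graph.bubbles) == 2


def test_empty_panel_gives_empty_graph():
    graph = build_graph({"c": "ACGT" * 50}, [], contiguous_seed(5))
    assert graph.bubbles == []


def test_ref_mismatch_raises():
    ref = "A" * 100
    site = snp_site("c", 50, "C", "G", [0, 1])
    with pytest.raises(GraphError, match="REF mismatch"):
        build_graph({"c": ref}, [site], contiguous_seed(5))


def test_unphased_panel_vcf_rejected(tmp_path):
    vcf = tmp_path / "panel.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=c,length=100>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\n"
        "c\t10\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
    )
    with pytest.raises(GraphError, match="unphased"):
        read_panel_vcf(vcf)


def test_panel_vcf_missing_genotypes_dropped(tmp_path):
    vcf = tmp_path / "panel.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=c,length=100>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\n"
        "c\t10\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t.|.\n"
        "c\t20\t.\tC\tT\t.\tPASS\t.\tGT\t1|1\t0|0\n"
    )
    sites, samples = read_panel_vcf(vcf)
    assert samples == ["s0", "s1"]
    assert len(sites) == 1
    assert sites[0].start == 19
    assert sites[0].hap_alleles == (1, 1, 0, 0)


# ---------------------------------------------------------------------------
# unique k-mer index


def brute_multiplicities(graph, seed):
    """Naive canonical k-mer multiplicities over reference + alt paths."""
    counts = Counter()
    for chrom_seq in graph.reference.values():
        counts.update(canonicalize(k) for k in extract_spaced_kmers(chrom_seq, seed))
    flank = seed.l - 1
    for bubble in graph.bubbles:
        ref = graph.reference[bubble.chrom]
        left = ref[max(0, bubble.start - flank):bubble.start]
        right = ref[bubble.end:bubble.end + flank]
        for a in range(1, len(bubble.alleles)):
            path = left + bubble.alleles[a] + right
            counts.update(canonicalize(k) for k in extract_spaced_kmers(path, seed))
    return counts


def test_snp_alt_allele_owns_w_unique_kmers():
    """With unique flanks, a SNV is covered by exactly w alt k-mers."""
    rng = np.random.default_rng(3)
    ref = random_dna(400, rng)
    alt = "ACGT".replace(ref[200], "")[0]
    for pattern in ("1" * 11, "11011010101010011"):
        seed = parse_seed(pattern)
        graph = build_graph({"c": ref}, [snp_site("c", 200, ref[200], alt, [0, 1])], seed)
        index = index_unique_kmers(graph, seed)
        assert len(index.by_allele.get((0, 1), [])) == seed.w
        # and every indexed k-mer is globally unique per the naive oracle
        mult = brute_multiplicities(graph, seed)
        assert all(mult[k] == 1 for k in index.kmer_home)


def test_bubble_in_tandem_repeat_has_no_unique_kmers():
    rng = np.random.default_rng(4)
    unit = random_dna(150, rng)
    ref = random_dna(100, rng) + unit + unit + random_dna(100, rng)
    # SNV inside the first repeat copy: every window also occurs in copy 2
    pos = 100 + 40
    seed = contiguous_seed(15)
    alt = "ACGT".replace(ref[pos], "")[0]
    graph = build_graph({"c": ref}, [snp_site("c", pos, ref[pos], alt, [0, 1])], seed)
    index = index_unique_kmers(graph, seed)
    assert index.by_allele.get((0, 0), []) == []
    # ref-allele k-mers occur twice in the reference; alt k-mers are unique
    # only if the alt path itself is not repeated -- here it is not, so the
    # alt allele may keep k-mers, but none of the reference allele's survive


def test_identical_bubbles_share_no_unique_kmers():
    rng = np.random.default_rng(5)
    context = random_dna(120, rng)
    ref = random_dna(80, rng) + context + random_dna(60, rng) + context + random_dna(80, rng)
    seed = contiguous_seed(13)
    p1 = 80 + 60   # middle of first context copy
    p2 = 80 + 120 + 60 + 60
    assert ref[p1] == ref[p2]
    alt = "ACGT".replace(ref[p1], "")[0]
    sites = [
        snp_site("c", p1, ref[p1], alt, [0, 1]),
        snp_site("c", p2, ref[p2], alt, [1, 0]),
    ]
    graph = build_graph({"c": ref}, sites, seed)
    index = index_unique_kmers(graph, seed)
    # identical alt sequences in identical contexts: alt k-mers collide
    assert index.by_allele.get((0, 1), []) == []
    assert index.by_allele.get((1, 1), []) == []
    mult = brute_multiplicities(graph, seed)
    assert all(mult[k] == 1 for k in index.kmer_home)


# ---------------------------------------------------------------------------
# coverage estimation


def _toy_index(seed, kmer_counts, carriers=4, n_hap=4):
    from spacegt.pangenome import UniqueKmerIndex

    home = {k: (0, 0) for k in kmer_counts}
    return UniqueKmerIndex(seed, home, {(0, 0): list(kmer_counts)},
                           {(0, 0): carriers, (0, 1): n_hap - carriers})


def test_estimate_coverage_constant_counts():
    seed = contiguous_seed(3)
    kmers = {f"{a}{b}{c}": 30 for a in "AC" for b in "AC" for c in "AC"}
    index = _toy_index(seed, kmers)
    counts = KmerCountTable(seed, dict(kmers))
    assert estimate_coverage(index, counts) == 30.0


def test_estimate_coverage_mode_of_histogram():
    seed = contiguous_seed(3)
    values = [1] * 20 + [30] * 100 + [31] * 80
    kmers = {f"k{i}": v for i, v in enumerate(values)}  # distinct toy keys
    index = _toy_index(seed, kmers)
    counts = KmerCountTable(seed, dict(kmers))
    assert estimate_coverage(index, counts) == pytest.approx(30.0, abs=1.0)


def test_estimate_coverage_requires_index():
    from spacegt.pangenome import UniqueKmerIndex

    seed = contiguous_seed(3)
    with pytest.raises(ValueError):
        estimate_coverage(UniqueKmerIndex(seed, {}), KmerCountTable(seed))


# ---------------------------------------------------------------------------
# HMM genotyping vs brute-force path enumeration


def brute_genotype_posteriors(graph, counts, params, index):
    """Enumerate all ordered haplotype-pair paths exactly."""
    from spacegt.genotyping import _emission_matrix

    bubbles = graph.bubbles
    H = graph.n_haplotypes
    B = len(bubbles)
    have_data = counts.total() > 0
    emissions = []
    for i, b in enumerate(bubbles):
        informative = have_data and index.bubble_has_kmers(i, len(b.alleles))
        emissions.append(
            np.exp(_emission_matrix(b, i, index, counts, params, informative))
        )
    thetas = []
    for t in range(1, B):
        d = max(1, bubbles[t].start - bubbles[t - 1].end)
        thetas.append(1.0 - math.exp(-params.rho * d))

    def trans(theta, h, h2):
        return (1 - theta) * (h == h2) + theta / H

    states = list(itertools.product(range(H), repeat=2))
    marginals = [Counter() for _ in range(B)]
    total = 0.0
    for path in itertools.product(states, repeat=B):
        p = 1.0 / (H * H) * emissions[0][path[0]]
        for t in range(1, B):
            (a1, a2), (b1, b2) = path[t - 1], path[t]
            p *= trans(thetas[t - 1], a1, b1) * trans(thetas[t - 1], a2, b2)
            p *= emissions[t][path[t]]
        total += p
        for t, st in enumerate(path):
            marginals[t][st] += p
    out = []
    for t, m in enumerate(marginals):
        al = bubbles[t].panel_alleles
        agg = Counter()
        for (h1, h2), p in m.items():
            g = tuple(sorted((int(al[h1]), int(al[h2]))))
            agg[g] += p / total
        out.append(dict(agg))
    return out


def _random_graph_and_counts(rng, n_bubbles=3, n_hap=4, seed=None, coverage=20.0):
    seed = seed or contiguous_seed(9)
    ref = random_dna(200 * (n_bubbles + 1), rng)
    sites = []
    for i in range(n_bubbles):
        pos = 150 + 200 * i
        alt = "ACGT".replace(ref[pos], "")[0]
        haps = rng.integers(0, 2, size=n_hap)
        if haps.min() == haps.max():
            haps[0] = 1 - haps[0]
        sites.append(snp_site("c", pos, ref[pos], alt, haps.tolist()))
    graph = build_graph({"c": ref}, sites, seed)
    # synthesise counts for a random truth genotype
    truth = [tuple(sorted(rng.integers(0, 2, size=2).tolist())) for _ in sites]
    index = index_unique_kmers(graph, seed)
    counts = {}
    for i, g in enumerate(truth):
        for a in range(2):
            copies = g.count(a)
            mean = [0.05, coverage / 2, coverage][copies]
            for k in index.by_allele.get((i, a), []):
                counts[k] = int(rng.poisson(mean))
    counts = {k: v for k, v in counts.items() if v > 0}
    table = KmerCountTable(seed, counts, sum(counts.values()), 0)
    return graph, table, index, truth


@pytest.mark.parametrize("n_bubbles,n_hap", [(1, 2), (2, 4), (3, 4), (3, 3)])
def test_forward_backward_matches_path_enumeration(n_bubbles, n_hap):
    rng = np.random.default_rng(100 + n_bubbles + n_hap)
    graph, table, index, _ = _random_graph_and_counts(rng, n_bubbles, n_hap)
    params = GenotypingParams(index.seed, 20.0, epsilon=0.01, rho=1e-4)
    ours = genotype_posteriors(graph, table, params, index)
    brute = brute_genotype_posteriors(graph, table, params, index)
    for mine, ref_post in zip(ours, brute):
        assert mine is not None
        assert set(mine) == set(ref_post)
        for g, p in ref_post.items():
            assert mine[g] == pytest.approx(p, abs=1e-9)


def test_posteriors_normalise():
    rng = np.random.default_rng(42)
    graph, table, index, _ = _random_graph_and_counts(rng, 3, 4)
    params = GenotypingParams(index.seed, 20.0)
    for post in genotype_posteriors(graph, table, params, index):
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)


def test_single_bubble_het_call_matches_bayes_rule():
    """With alt and ref unique k-mers counted near c/2 each, the single
    biallelic bubble must be called heterozygous."""
    rng = np.random.default_rng(7)
    ref = random_dna(300, rng)
    alt = "ACGT".replace(ref[150], "")[0]
    seed = contiguous_seed(11)
    graph = build_graph({"c": ref}, [snp_site("c", 150, ref[150], alt, [0, 0, 1, 1])], seed)
    index = index_unique_kmers(graph, seed)
    c = 30.0
    counts = {}
    for a in range(2):
        for k in index.by_allele[(0, a)]:
            counts[k] = 15
    table = KmerCountTable(seed, counts, sum(counts.values()), 0)
    calls = genotype(graph, table, GenotypingParams(seed, c), index=index)
    assert calls[0].genotype == (0, 1)
    assert calls[0].posterior > 0.99
    brute = brute_genotype_posteriors(graph, table, GenotypingParams(seed, c), index)
    assert calls[0].posterior == pytest.approx(brute[0][(0, 1)], abs=1e-9)


def test_ld_fills_in_bubble_without_unique_kmers():
    """Perfect LD in the panel determines the genotype of an uninformative
    middle bubble from its decisively genotyped neighbours."""
    rng = np.random.default_rng(8)
    seed = contiguous_seed(9)
    ref = random_dna(800, rng)
    haps = [0, 0, 1, 1]  # two haplotype pairs in perfect LD across bubbles
    sites = []
    for pos in (200, 400, 600):
        alt = "ACGT".replace(ref[pos], "")[0]
        sites.append(snp_site("c", pos, ref[pos], alt, haps))
    graph = build_graph({"c": ref}, sites, seed)
    index = index_unique_kmers(graph, seed)
    # remove all middle-bubble evidence: the call must come from LD alone
    for a in range(2):
        for k in index.by_allele.pop((1, a), []):
            del index.kmer_home[k]
    c = 30.0
    counts = {}
    for i in (0, 2):  # flanking bubbles decisively heterozygous
        for a in range(2):
            for k in index.by_allele[(i, a)]:
                counts[k] = 15
    table = KmerCountTable(seed, counts, sum(counts.values()), 0)
    calls = genotype(graph, table, GenotypingParams(seed, c), index=index)
    assert [c_.genotype for c_ in calls] == [(0, 1), (0, 1), (0, 1)]
    brute = brute_genotype_posteriors(graph, table, GenotypingParams(seed, c), index)
    assert calls[1].posterior == pytest.approx(brute[1][(0, 1)], abs=1e-9)


def test_empty_counts_yield_prior_calls_and_single_bubble_undefined():
    rng = np.random.default_rng(9)
    seed = contiguous_seed(9)
    ref = random_dna(700, rng)
    haps = [0, 1, 0, 0]  # alt carried by 1 of 4 haplotypes
    sites = []
    for pos in (200, 450):
        alt = "ACGT".replace(ref[pos], "")[0]
        sites.append(snp_site("c", pos, ref[pos], alt, haps))
    graph = build_graph({"c": ref}, sites, seed)
    empty = KmerCountTable(seed)
    calls = genotype(graph, empty, GenotypingParams(seed, 1.0))
    # panel-frequency prior argmax: ref frequency 3/4 -> homozygous ref
    assert [c_.genotype for c_ in calls] == [(0, 0), (0, 0)]
    # a lone bubble has no LD context: undefined
    graph1 = build_graph({"c": ref}, sites[:1], seed)
    calls1 = genotype(graph1, empty, GenotypingParams(seed, 1.0))
    assert calls1[0].undefined
    assert calls1[0].genotype_class == "*|*"


def test_counts_seed_mismatch_rejected():
    rng = np.random.default_rng(10)
    graph, table, index, _ = _random_graph_and_counts(rng, 1, 2)
    wrong = GenotypingParams(parse_seed("101"), 20.0)
    with pytest.raises(ValueError, match="different seeds"):
        genotype(graph, table, wrong)


def test_contiguous_seed_path_equals_plain_kmer_counting():
    """The spaced machinery with an all-'1' pattern is byte-identical to a
    plain k-mer counter."""
    rng = np.random.default_rng(11)
    reads = [random_dna(90, rng) for _ in range(30)]
    k = 21
    plain = Counter()
    for read in reads:
        for i in range(len(read) - k + 1):
            plain.update([canonicalize(read[i:i + k])])
    table = count_sequences(reads, contiguous_seed(k))
    assert table.counts == dict(plain)


# ---------------------------------------------------------------------------
# VCF output


def test_write_calls_round_trip(tmp_path):
    rng = np.random.default_rng(12)
    seed = contiguous_seed(9)
    ref = random_dna(700, rng)
    haps = [0, 1, 1, 0]
    sites = []
    for pos in (200, 450):
        alt = "ACGT".replace(ref[pos], "")[0]
        sites.append(snp_site("c", pos, ref[pos], alt, haps))
    graph = build_graph({"c": ref}, sites, seed)
    index = index_unique_kmers(graph, seed)
    counts = {}
    for a in range(2):  # first bubble het, second left with no counts
        for k in index.by_allele[(0, a)]:
            counts[k] = 15
    table = KmerCountTable(seed, counts, sum(counts.values()), 0)
    calls = genotype(graph, table, GenotypingParams(seed, 30.0), index=index)
    out = tmp_path / "calls.vcf"
    write_calls(calls, graph, out, sample="s0")
    with pysam.VariantFile(str(out)) as vcf:
        records = list(vcf)
    assert len(records) == 2
    gts = [rec.samples["s0"]["GT"] for rec in records]
    assert gts[0] == (0, 1)
    site_gts = calls_to_site_genotypes(calls, graph)
    for rec, gt in zip(records, gts):
        key = (rec.chrom, rec.start, rec.ref, tuple(rec.alts))
        assert tuple(sorted(gt)) == site_gts[key]


def test_write_calls_undefined_is_missing_genotype(tmp_path):
    rng = np.random.default_rng(13)
    seed = contiguous_seed(9)
    ref = random_dna(400, rng)
    alt = "ACGT".replace(ref[200], "")[0]
    graph = build_graph({"c": ref}, [snp_site("c", 200, ref[200], alt, [0, 1])], seed)
    calls = genotype(graph, KmerCountTable(seed), GenotypingParams(seed, 1.0))
    assert calls[0].undefined
    out = tmp_path / "calls.vcf"
    write_calls(calls, graph, out)
    with pysam.VariantFile(str(out)) as vcf:
        rec = next(iter(vcf))
    assert rec.samples[0]["GT"] in ((None, None), (None,))
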