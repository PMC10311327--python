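"""Seed scoring and optimization.

Sensitivity of a seed is the probability that it hits at least once in a
homologous region: positions match independently with probability ``p``
(the similarity level) over ``L`` positions, and a *hit* is a placement of
the seed fully inside the region whose care positions all fall on matches.
The exact value is computed by dynamic programming over the deterministic
automaton of partial seed matches, which is exponential only in ``l - w``
in practice.

Seed optimization follows the overlap-complexity heuristic: sum, over all
relative shifts of the seed against itself, of 2 to the number of aligned
care-position pairs.  Low overlap complexity correlates with high
sensitivity, and regular (e.g. contiguous) seeds score worst.  A
hill-climbing search over care/don't-care swaps minimises it; the winning
base seed is mirror-extended into a palindromic seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seeds import Seed, mirror_extend

__all__ = [
    "SimilarityModel",
    "hit_probability",
    "overlap_complexity",
    "optimize_seed",
    "design_palindromic_seed",
]


@dataclass(frozen=True)
class SimilarityModel:
    """I.i.d. Bernoulli match model of a homologous region.

    p: per-position match probability (e.g. 0.95); L: region length.
    """

    p: float
    L: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("match probability must be in [0, 1]")
        if self.L < 1:
            raise ValueError("region length must be >= 1")


def hit_probability(seed: Seed, model: SimilarityModel) -> float:
    """Exact probability of >= 1 seed hit in the similarity region.

    All ``L - l + 1`` placements with the seed fully contained in the
    region count.  Implemented as a forward pass over the match/mismatch
    automaton: the state is the bitmask of currently-alive seed prefixes
    (shift-and with don't-care wildcards), with hits absorbing.  Returns 0
    when ``l > L`` by convention.
    """
    l = seed.l
    if l > model.L:
        return 0.0
    p = model.p
    q = 1.0 - p
    # bit j of a state: the length-(j+1) seed prefix matches the current
    # suffix.  A match symbol satisfies every pattern position, a mismatch
    # only don't-care positions.
    mask_match = (1 << l) - 1
    mask_mis = 0
    for j, c in enumerate(seed.pattern):
        if c == "0":
            mask_mis |= 1 << j
    hit_bit = 1 << (l - 1)
    states = {0: 1.0}
    p_hit = 0.0
    for _ in range(model.L):
        nxt: dict[int, float] = {}
        for state, prob in states.items():
            base = (state << 1) | 1
            for sym_mask, sym_p in ((mask_match, p), (mask_mis, q)):
                if sym_p == 0.0:
                    continue
                new = base & sym_mask
                if new & hit_bit:
                    p_hit += prob * sym_p
                else:
                    nxt[new] = nxt.get(new, 0.0) + prob * sym_p
        states = nxt
    return min(p_hit, 1.0)


def overlap_complexity(seed: Seed) -> int:
    """OC(s) = sum over shifts i in [-(l-1), l-1] of 2**sigma(i).

    sigma(i) counts positions at which both the seed and its copy shifted
    by ``i`` have a care position.  Exact integer; symmetric under seed
    reversal.
    """
    offs = set(seed.care_offsets)
    l = seed.l
    total = 0
    for shift in range(-(l - 1), l):
        sigma = sum(1 for o in offs if o + shift in offs)
        total += 1 << sigma
    return total


def _random_admissible(w: int, l: int, rng: np.random.Generator) -> Seed:
    interior = rng.choice(l - 2, size=w - 2, replace=False) if w > 2 else []
    bits = ["0"] * l
    bits[0] = bits[-1] = "1"
    for i in interior:
        bits[i + 1] = "1"
    return Seed("".join(bits))


def optimize_seed(w: int, l: int, model: SimilarityModel | None = None,
                  iterations: int = 10_000, rng_seed: int = 0) -> Seed:
    """Minimise overlap complexity by first-improvement hill climbing.

    Starts from a random admissible seed (endpoints forced to '1') and
    repeatedly swaps one interior care with one interior don't-care,
    accepting a move iff OC strictly decreases; neighbours are scanned in a
    randomised order and ``iterations`` bounds the total number of
    neighbour evaluations.  Deterministic given ``rng_seed``.  ``model`` is
    accepted for interface symmetry but OC alone drives the search.
    """
    if not 2 <= w <= l:
        raise ValueError("need 2 <= w <= l")
    rng = np.random.default_rng(rng_seed)
    current = _random_admissible(w, l, rng)
    if w == l or w == 2:
        return current  # search space is a single point
    current_oc = overlap_complexity(current)
    best, best_oc = current, current_oc
    evals = 0
    improved = True
    while improved and evals < iterations:
        improved = False
        bits = list(current.pattern)
        cares = [i for i in range(1, l - 1) if bits[i] == "1"]
        donts = [i for i in range(1, l - 1) if bits[i] == "0"]
        pairs = [(c, d) for c in cares for d in donts]
        rng.shuffle(pairs)
        for c, d in pairs:
            if evals >= iterations:
                break
            bits[c], bits[d] = "0", "1"
            cand = Seed("".join(bits))
            evals += 1
            cand_oc = overlap_complexity(cand)
            if cand_oc < current_oc:
                current, current_oc = cand, cand_oc
                if cand_oc < best_oc:
                    best, best_oc = cand, cand_oc
                improved = True
                break
            bits[c], bits[d] = "1", "0"
    return best


def design_palindromic_seed(w_base: int, l_range, model: SimilarityModel,
                            rng_seed: int = 0, iterations: int = 10_000,
                            return_candidates: bool = False):
    """Design a palindromic seed of weight ``2*w_base - 1``.

    For each candidate base length, runs :func:`optimize_seed`, scores the
    resulting base seed by exact sensitivity under ``model``, picks the
    most sensitive base (smallest length on ties) and mirror-extends it.
    """
    if w_base < 2:
        raise ValueError("base weight must be >= 2")
    lengths = sorted(set(int(l) for l in l_range))
    if not lengths or lengths[0] < w_base:
        raise ValueError("every candidate length must be >= w_base")
    child_seeds = np.random.SeedSequence(rng_seed).spawn(len(lengths))
    candidates = []
    for l, ss in zip(lengths, child_seeds):
        base = optimize_seed(w_base, l, model, iterations=iterations,
                             rng_seed=int(ss.generate_state(1)[0] % (2**31)))
        candidates.append(
            (base, overlap_complexity(base), hit_probability(base, model))
        )
    # highest sensitivity; ties (common when all are near 1) broken toward
    # lower overlap complexity, then the shorter base
    best_base, _, _ = max(
        candidates, key=lambda t: (t[2], -t[1], -t[0].l)
    )
    result = mirror_extend(best_base)
    if return_candidates:
        return result, candidates
    return result
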