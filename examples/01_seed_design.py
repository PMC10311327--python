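"""Seed algebra and design: combinatorics, sensitivity, mirror extension.

Builds the weight-31 palindromic spaced seed from its published 26-position
base pattern, and designs a small palindromic seed from scratch by overlap-
complexity hill climbing.
"""

from spacegt import (
    SimilarityModel,
    count_palindromic_seeds,
    design_palindromic_seed,
    hit_probability,
    is_palindromic,
    mirror_extend,
    parse_seed,
)

# Admissible palindromic seeds of weight 31: seeds start and end with '1'
# and must read the same in both directions, which collapses the usual
# binomial count dramatically.
for l in (41, 51):
    print(f"palindromic seeds with w=31, l={l}: {count_palindromic_seeds(l, 31):,}")

# The published base seed and its sensitivity: probability of at least one
# exact spaced-seed hit in a 76 bp homologous region at 95% identity.
base = parse_seed("11101110010101001101001111")
model = SimilarityModel(p=0.95, L=76)
print(f"base seed  {base} (w={base.w}, l={base.l})")
print(f"sensitivity at p=0.95, L=76: {hit_probability(base, model):.4f}")

s1 = mirror_extend(base)
print(f"mirrored   {s1} (w={s1.w}, l={s1.l}, palindromic={is_palindromic(s1)})")

# A from-scratch design at desk scale: base weight 5 gives a final weight-9
# palindromic seed; candidates are scored by exact sensitivity.
seed, candidates = design_palindromic_seed(
    5, range(5, 10), SimilarityModel(0.9, 30), rng_seed=1, return_candidates=True
)
print("\nsmall design (w_base=5):")
for cand, oc, sens in candidates:
    print(f"  base {cand.pattern:<10} OC={oc:<6} sensitivity={sens:.4f}")
print(f"chosen palindromic seed: {seed} (w={seed.w})")
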