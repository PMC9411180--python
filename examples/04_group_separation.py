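"""Test habitat separation in topospace with PERMANOVA and classify sizes.

Simulates trait tables under Brownian motion on a birth-death tree with an
additive fossorial/non-fossorial offset, projects them with PCA, and runs
the seeded PERMANOVA (Euclidean distances, free label permutations). Also
shows the miniaturization workflow: find the break in a skull-length
distribution and classify taxa against it.
"""

import numpy as np

from skullnet import (
    TraitSimSpec,
    classify_size,
    convex_hull_overlap,
    find_distribution_break,
    generate_pure_birth_tree,
    pairwise_permanova,
    pca_correlation,
    permanova,
    simulate_bm_traits,
)

tree = generate_pure_birth_tree(45, seed=3)
tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
rng = np.random.default_rng(3)
habitat = dict(zip(tips, rng.choice(
    ["fossorial", "semi-fossorial", "non-fossorial"], size=len(tips),
    p=[0.5, 0.15, 0.35])))
effects = {"fossorial": (-1.5,) * 7, "semi-fossorial": (0.0,) * 7,
           "non-fossorial": (1.5,) * 7}
traits = simulate_bm_traits(TraitSimSpec(
    tree=tree, group_effects=effects, group_of_tip=habitat, seed=4))

scores = pca_correlation(traits.drop(columns="group")).scores
labels = traits["group"]
res = permanova(scores, labels, n_permutations=9999, seed=0)
print(f"omnibus PERMANOVA: F_{res.df_between},{res.df_within} = "
      f"{res.f_statistic:.3f}, p = {res.p_value:.4f} "
      f"({res.n_permutations} permutations)")
for pair in pairwise_permanova(scores, labels, n_permutations=9999, seed=0):
    print(f"  {pair.groups[0]} vs {pair.groups[1]}: "
          f"F_{pair.df_between},{pair.df_within} = {pair.f_statistic:.3f}, "
          f"p = {pair.p_value:.4f}")

hulls = convex_hull_overlap(scores, labels)
a = hulls["intersections"][("fossorial", "non-fossorial")]
print(f"fossorial x non-fossorial hull overlap on PC1-PC2: {a:.3f}")

# miniaturization: break in the skull-length distribution, then classify
lengths = np.round(np.concatenate([rng.uniform(6, 11.7, 25),
                                   rng.uniform(14.1, 40, 20)]), 2)
brk = find_distribution_break(lengths, min_gap=1.0)
print(f"largest skull-length gap: {brk[0]:.2f} to {brk[1]:.2f} mm")
classes = classify_size(dict(zip(tips, lengths)), lower=brk[0], upper=brk[1])
n_min = sum(c.size_class == "miniaturized" for c in classes)
print(f"{n_min} of {len(classes)} taxa classified miniaturized")
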