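"""Compare hidden vs. marked enhancers on conservation and repeat content.

Generates a synthetic bundle with a conservation uplift inside active
enhancers, scores mean phastCons-style conservation per element for hidden
enhancers, marked enhancers and a length-matched random genomic background,
tests the distributions with two-sample Kolmogorov-Smirnov, and tallies
repeat-class composition for both groups.
"""

import numpy as np

from hidden_enhancers import (
    GeneratorConfig,
    build_mark_matrix,
    classify,
    compare_conservation,
    generate,
    mean_score,
    repeat_composition,
    sample_background,
)

bundle = generate(GeneratorConfig(seed=11, n_elements=300, hidden_fraction=0.2))
records = classify(build_mark_matrix(bundle.elements, bundle.peaksets))
by_id = {el.id: el for el in bundle.elements}

hidden_ids = set(records.loc[records["category"] == "HIDDEN", "element_id"])
marked_ids = set(records["element_id"]) - hidden_ids
hidden_scores = [mean_score(by_id[i].interval, bundle.conservation) for i in hidden_ids]
marked_scores = [mean_score(by_id[i].interval, bundle.conservation) for i in marked_ids]

background = sample_background(
    2_000, [el.interval for el in bundle.elements], bundle.genome, seed=12, assembly=bundle.assembly
)
bg_scores = [mean_score(iv, bundle.conservation) for iv in background]

print(f"mean conservation: hidden {np.mean(hidden_scores):.3f}  "
      f"marked {np.mean(marked_scores):.3f}  background {np.mean(bg_scores):.3f}")
d_hm, p_hm = compare_conservation(hidden_scores, marked_scores)
d_hb, p_hb = compare_conservation(hidden_scores, bg_scores)
print(f"KS hidden vs marked:     D = {d_hm:.3f}, p = {p_hm:.3g}")
print(f"KS hidden vs background: D = {d_hb:.3f}, p = {p_hb:.3g}")

_, hidden_rep = repeat_composition([by_id[i].interval for i in hidden_ids], bundle.repeats)
_, marked_rep = repeat_composition([by_id[i].interval for i in marked_ids], bundle.repeats)
print("\nrepeat-class proportions (hidden vs marked):")
for cls in hidden_rep.index:
    print(f"  {cls:6s} {hidden_rep.loc[cls, 'proportion']:.2f}  vs  "
          f"{marked_rep.loc[cls, 'proportion']:.2f}")
print()
print(
    "Hidden and marked enhancers share the conservation uplift (large KS D and\n"
    "tiny p only against random background, not against each other) and show\n"
    "similar repeat composition -- the hallmarks of bona fide elements."
)
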