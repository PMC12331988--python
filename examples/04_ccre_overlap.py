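"""Overlap hidden enhancers and transgenic negatives with a cCRE catalog.

Broad candidate cis-regulatory element (cCRE) catalogs aggregate chromatin
signatures across hundreds of cell types. This example lifts both element
sets onto the catalog assembly (recording lift-over failures) and asks
whether catalog membership separates true hidden enhancers from elements
that tested negative in vivo.
"""

from hidden_enhancers import build_fixture, ccre_overlap_analysis

bundle = build_fixture("ccre_catalog")
hidden = [el for el in bundle.elements if el.id.startswith("chid")]
negatives = [el for el in bundle.elements if el.id.startswith("neg")]

out = ccre_overlap_analysis(hidden, negatives, bundle.ccre, chains=bundle.chains)

print(f"hidden enhancers: {out['hidden_n_input']} input, "
      f"{out['hidden_n_unmappable']} unmappable, {out['hidden_n_mappable']} analysed")
print(f"  overlapping an enhancer-like cCRE: {out['hidden_n_overlap']} ({out['hidden_percent']}%)")
print(f"transgenic negatives: {out['negative_n_mappable']} analysed")
print(f"  overlapping an enhancer-like cCRE: {out['negative_n_overlap']} ({out['negative_percent']}%)")
print()
print(
    "A high hidden-enhancer rate looks encouraging until compared with the\n"
    "negative controls: when most in vivo-negative elements also overlap the\n"
    "catalog, membership alone has little predictive power for activity."
)
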