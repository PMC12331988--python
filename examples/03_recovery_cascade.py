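"""Run the three-stage recovery cascade over a hidden-enhancer cohort.

Hidden enhancers (active in vivo, no tissue-matched canonical mark) are
re-examined against earlier-stage bulk marks (E10.5 H3K27ac/H3K4me1), then
single-cell accessibility data (forebrain/hindbrain), then tissue-matched
human chromatin data (human-derived elements only, lifted mm10 -> hg38).
"""

from hidden_enhancers import build_fixture, run_cascade, stages_from_bundle

bundle = build_fixture("cascade_308")
lookup = {el.id: el for el in bundle.elements}
hidden = [(lookup[r.element_id], r.tissue) for r in bundle.ground_truth.itertuples()]

result = run_cascade(hidden, stages_from_bundle(bundle))
s = result.summary

print(f"starting hidden set: {s['n_input']} element-tissue activities")
for state in ("RECOVERED_EARLIER_BULK", "RECOVERED_SINGLE_CELL", "RECOVERED_CROSS_SPECIES", "UNRECOVERED"):
    print(f"  {state:26s} {s[state]:4d} ({s[state + '_pct']}% of starting set)")
print(f"assessed with single-cell data: {s['SINGLE_CELL_assessed']}")
print(f"assessed with human data:       {s['CROSS_SPECIES_assessed']}")
print(f"unrecovered despite >=2 complementary data types available: {s['unrecovered_ge2_types_available']}")
print(f"unrecovered and lacking single-cell data:                   {s['unrecovered_no_single_cell']}")
print()
print(
    "Recovery is attributed to the first stage that finds an overlapping peak;\n"
    "percentages follow the starting-set convention, so stage shares can be\n"
    "compared directly even though later stages see fewer survivors."
)
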