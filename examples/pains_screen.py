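"""Screen a compound set against the combined 480-filter PAINS catalogue
and compare two screening runs with a concordance report.
"""

from molscreen import concordance_report, default_catalogue, make_fixture_set, screen_set

catalogue = default_catalogue()
print(f"catalogue: {len(catalogue)} filters, families {sorted(catalogue.families())}")

bench = make_fixture_set("mixed_bench", 19, rng_seed=7)
summary = screen_set(bench, catalogue)
print(f"flagged {summary.n_flagged} of {summary.n_compounds} compounds")
for fid, count in sorted(summary.hits_per_filter.items()):
    print(f"  {fid}: {count} compound(s)")

# concordance of two runs (here: the same engine twice -> perfect agreement;
# in practice the second summary would come from another screening tool run
# over the same library)
other = screen_set(bench, catalogue)
matching, only_a, only_b = concordance_report(summary, other)
print(f"concordance: matching={matching} only_a={only_a} only_b={only_b}")
# matching + only_a always equals the first run's flagged count.
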