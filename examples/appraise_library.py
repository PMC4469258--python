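"""Appraise a small library: descriptors, likeness verdicts, PAINS flags.

Builds the packaged mixed benchmark set (interference exemplars + clean
drugs), runs the full appraisal task, and prints one line per compound.
"""

from molscreen import appraise_set, make_fixture_set

cset = make_fixture_set("mixed_bench", 10, rng_seed=7)
appraise_set(cset)

print(f"{'id':8s} {'name':24s} {'MW':>7s} {'logP':>6s} {'drug_like':>9s} {'PAINS':>5s}")
for rec in cset:
    d = rec.descriptors
    verdict = rec.likeness["drug_like"]
    print(f"{rec.compound_id:8s} {rec.name:24s} {d.mw:7.2f} {d.logp:6.2f} "
          f"{'pass' if verdict.passed else 'FAIL':>9s} "
          f"{'yes' if rec.pains_flagged else 'no':>5s}")

# MW/logP feed the Lipinski-style rules; a "yes" in the PAINS column means at
# least one of the 480 interference filters matched, so any assay activity of
# that compound deserves suspicion before follow-up.
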