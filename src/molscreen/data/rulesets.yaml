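# Built-in likeness rule sets.  Bounds are the community-standard values:
# Lipinski's rule of five (one violation tolerated, per the original "more
# than one" failure criterion), lead-likeness, and the rule of three for
# fragments.  Edit or copy this file and pass it via --ruleset to use
# different thresholds.
drug_like:
  max_violations: 1
  rules:
    - {descriptor: mw, comparator: le, bound: 500}
    - {descriptor: logp, comparator: le, bound: 5}
    - {descriptor: hbd, comparator: le, bound: 5}
    - {descriptor: hba, comparator: le, bound: 10}
lead_like:
  max_violations: 0
  rules:
    - {descriptor: mw, comparator: le, bound: 450}
    - {descriptor: logp, comparator: le, bound: 4}
    - {descriptor: hbd, comparator: le, bound: 4}
    - {descriptor: hba, comparator: le, bound: 8}
    - {descriptor: rotatable_bonds, comparator: le, bound: 8}
fragment_like:
  max_violations: 0
  rules:
    - {descriptor: mw, comparator: le, bound: 300}
    - {descriptor: logp, comparator: le, bound: 3}
    - {descriptor: hbd, comparator: le, bound: 3}
    - {descriptor: hba, comparator: le, bound: 3}
    - {descriptor: rotatable_bonds, comparator: le, bound: 3}
    - {descriptor: tpsa, comparator: le, bound: 60}
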