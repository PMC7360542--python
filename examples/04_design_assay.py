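"""Design a locus-specific KASP assay and audit it in silico.

End to end: simulate an allopolyploid locus with a guaranteed
discriminating column, decode the probe, profile the homeologs, place the
two tailed allele-specific primers and the common primer, and scan the
whole assembly for every feasible amplicon.
"""

from polykasp import SimConfig, simulate_polyploid_locus, simulate_probe_context
from polykasp.pipeline import design_for_probe
from polykasp.primers import specificity_audit

cfg = SimConfig(seed=1, offtarget_states=("T", "G"))
assemblies, truth = simulate_polyploid_locus(cfg)
record = simulate_probe_context(truth, rng=cfg.rng())

assay = design_for_probe(record, assemblies)
if assay.failed:
    print("design failed:", assay.failure_reason.value)
else:
    print("specificity class:", assay.specificity_class.value)
    print("allele A primer (tailed):", assay.primer_a_tailed)
    print("allele B primer (tailed):", assay.primer_b_tailed)
    print("common primer:          ", assay.common.sequence)
    print(f"Tm: A {assay.primer_a.tm:.1f}  B {assay.primer_b.tm:.1f}  "
          f"common {assay.common.tm:.1f} degC")
    print("amplicon length:", assay.amplicon_len_a, "bp")
    report = specificity_audit(assay, assemblies)
    print("feasible amplicons anywhere in the assembly:", report.n_feasible)
# Exactly one feasible amplicon means the assay amplifies the target
# locus only — a homeolog-proof genotyping marker.
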