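"""Predict array cluster layouts under the dual-color dosage model.

Reproduces the hemi-SNP reasoning for a probe that binds three
homeologous copies: the target locus segregates, the other two copies
are fixed, and every sample's signal is the count of green (A/T) and red
(C/G) nucleotides over all six alleles.
"""

from polykasp import (
    check_declaration,
    enumerate_compositions,
    predict_layout,
    signal_equivalents,
)

# a simple SNP: one bound copy, three clusters
simple = predict_layout(enumerate_compositions(1, ("A", "G")))
print("simple SNP:", simple.snp_class.value,
      sorted((p.green_equiv, p.red_equiv) for p in simple.clusters))

# hemi-SNP: three bound copies, off-targets fixed at T/T and G/G
comps = enumerate_compositions(3, ("A", "G"), ["TT", "GG"])
for c in comps:
    pt = signal_equivalents(c)
    print(f"  {c.label}: composition {c.flattened} -> "
          f"({pt.green_equiv} green, {pt.red_equiv} red)")
layout = predict_layout(comps)
print("hemi layout:", layout.snp_class.value,
      "| heterozygous-position clusters:",
      len(layout.heterozygous_position_clusters))

# a T/G declaration yields the identical layout (T and A share the green
# channel): without Sanger data the declaration is color-ambiguous
declared = enumerate_compositions(3, ("T", "G"), ["TT", "GG"])
lay = predict_layout(declared)
print("declared T/G without Sanger:",
      check_declaration(lay, declared, ("T", "G")).value)
print("declared T/G with Sanger A/G:",
      check_declaration(lay, declared, ("T", "G"), ("A", "G")).value)
# The contradicted case is exactly how a triallelic hemi-SNP hides a
# wrong allele call behind a normal-looking cluster layout.
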