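"""Decode an array probe's TOP/BOT strand designations.

Builds one manifest record the way array providers publish them — a
101 bp context with a bracketed SNP and two strand columns — and decodes
it onto the design strand.
"""

from polykasp import ProbeRecord, Strand, classify_strand, decode_probe

left = "GCTAGGTTACCGGATTCAAGCCTTAGACCGTTAGGCATCATTGCACCTAG"
right = "TTGACCTAGGCATTACGGACCTTAGGCAATTGACCGGTATTACCGGTAAC"
context = f"{left}[A/G]{right}"

print("submitted context:", context[:30], "...")
print("TOP/BOT designation:", classify_strand(context).value)

record = ProbeRecord(
    probe_id="example_probe",
    context_seq=context,
    customer_strand=Strand.TOP,
    ilmn_strand=Strand.TOP,
    declared_alleles=("A", "G"),
)
decoded = decode_probe(record)
print("50 bp probe (3' end adjacent to the SNP):", decoded.probe_seq_50)
print("design-strand alleles:", "/".join(decoded.design_strand_alleles))
print("channel map:", decoded.channel_map)
# The probe is the 50 bases 5' of the SNP on the design strand; A and T
# read out in the green channel, C and G in red — the fact that makes
# hemi-SNP layouts ambiguous between same-color allele pairs.
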