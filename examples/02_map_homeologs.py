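"""Find every homeologous copy of a probe target and profile them.

Simulates a hexaploid-style locus (three homeologous copies at 5%
divergence), then searches the probe context against the assembly and
builds the joint alignment profile used for primer placement.
"""

from polykasp import SimConfig, simulate_polyploid_locus, simulate_probe_context
from polykasp.pipeline import profile_probe

cfg = SimConfig(seed=7, offtarget_states=("T", "G"))
assemblies, truth = simulate_polyploid_locus(cfg)
record = simulate_probe_context(truth, rng=cfg.rng())

decoded, profile = profile_probe(record, assemblies)
print(f"copies found: {profile.copy_count}")
for hit in profile.hits:
    print(f"  {hit.chrom}:{hit.start}-{hit.end}({hit.strand}) "
          f"identity {hit.percent_identity:.3f}  E {hit.evalue:.2e}")
print(f"variant columns in the joint alignment: {len(profile.variant_columns)}")
print(f"SNP column: {profile.snp_column}, target alleles "
      f"{'/'.join(profile.target_alleles)}")
# Each variant column is a candidate discriminating site: a primer whose
# 3' end covers one can distinguish the target locus from its homeologs.
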