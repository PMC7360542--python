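"""Published wheat root-biomass haploblock data used as worked inputs.

Two haploblocks on wheat chromosome 5B, associated with root dry biomass,
as genotyped on the 90 K Infinium array in a 215-accession winter wheat
panel: per-haplotype allele strings with printed frequencies (``-`` marks
an array "Null" call), and the per-probe declared allele pairs alongside
the Sanger-resolved target-locus (5B) alleles.  These are inputs to the
correction and concordance operations, encoded from the published tables.
"""

from __future__ import annotations

from .qc import HaplotypeTable

PANEL_N = 215

RDMA_PROBES = (
    "GENE-2890_482",
    "Excalibur_c25522_755",
    "Kukri_c46570_214",
    "RAC875_c12293_588",
    "RAC875_c18088_2222",
    "BobWhite_c43_86",
    "RAC875_c18088_950",
    "RAC875_c24226_1356",
    "Excalibur_c60554_394",
)

#: haplotype, allele string (one char per probe, '-' = Null), frequency %
RDMA_ROWS = (
    ("h1", "GCAGGGCAG", 86.5),
    ("h2", "ATGAAATCT", 8.4),
    ("h3", "GCAGGG-AG", 1.9),
    ("h4", "GCAGGGC-G", 1.4),
    ("h5", "GCAGGGCA-", 0.9),
    ("h6", "GCAGG-CAG", 0.5),
    ("h7", "-CAGGG---", 0.5),
)

RDMB_PROBES = (
    "BS00022231_51",
    "BS00022477_51",
    "BS00029852_51",
    "BS00110293_51",
    "IACX6288",
    "Tdurum_contig48959_1172",
)

RDMB_ROWS = (
    ("h1", "GAGATG", 74.4),
    ("h2", "AGTGCG", 13.5),
    ("h3", "GGTGCT", 5.1),
    ("h4", "GA-ATG", 4.2),
    ("h5", "AGTG-G", 0.9),
    ("h6", "GGTG-T", 0.5),
    ("h7", "GAGA-G", 0.5),
    ("h8", "GAGGCT", 0.5),
    ("h9", "G--ATG", 0.5),
)


def haploblock_rdma() -> HaplotypeTable:
    return HaplotypeTable.from_frequencies(
        "Hap-5B-RDMa", RDMA_PROBES, list(RDMA_ROWS), PANEL_N
    )


def haploblock_rdmb() -> HaplotypeTable:
    return HaplotypeTable.from_frequencies(
        "Hap-5B-RDMb", RDMB_PROBES, list(RDMB_ROWS), PANEL_N
    )


#: probe -> (declared allele pair from the array manifest,
#:           Sanger-resolved target-locus allele pair on 5B)
PROBE_ALLELES: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "GENE-2890_482": (("A", "G"), ("G", "A")),
    "Excalibur_c25522_755": (("T", "C"), ("C", "T")),
    "Kukri_c46570_214": (("A", "G"), ("A", "G")),
    "RAC875_c12293_588": (("A", "G"), ("G", "A")),
    "RAC875_c18088_2222": (("A", "G"), ("G", "A")),
    "BobWhite_c43_86": (("A", "G"), ("G", "A")),
    "RAC875_c18088_950": (("T", "C"), ("C", "T")),
    "RAC875_c24226_1356": (("A", "C"), ("A", "C")),
    # declared as T/G from the customer-submitted variation; Sanger showed
    # the 5B target locus actually segregates A/G (triallelic hemi-SNP)
    "Excalibur_c60554_394": (("T", "G"), ("G", "A")),
    "BS00022231_51": (("A", "G"), ("A", "G")),
    "BS00022477_51": (("A", "G"), ("A", "G")),
    "BS00029852_51": (("T", "G"), ("G", "T")),
    "BS00110293_51": (("A", "G"), ("A", "G")),
    "IACX6288": (("T", "C"), ("T", "C")),
    "Tdurum_contig48959_1172": (("T", "G"), ("G", "T")),
}


def reported_alleles() -> dict[str, tuple[str, str]]:
    return {k: v[0] for k, v in PROBE_ALLELES.items()}


def sanger_alleles() -> dict[str, tuple[str, str]]:
    return {k: v[1] for k, v in PROBE_ALLELES.items()}
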