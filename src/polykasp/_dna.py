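"""Small DNA string helpers shared across modules."""

from __future__ import annotations

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                           "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

UNAMBIGUOUS = frozenset("ACGT")
IUPAC = frozenset("ACGTRYSWKMBDHVN")

#: dual-color detection chemistry: A and T share the green channel (Cy3/FAM
#: side), C and G share the red channel (Cy5/HEX side).
CHANNEL = {"A": "green", "T": "green", "C": "red", "G": "red"}

#: same-color partner under the two-channel chemistry
COLOR_PARTNER = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(base: str) -> str:
    return base.translate(COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def is_dna(seq: str, alphabet: frozenset = IUPAC) -> bool:
    return all(c in alphabet for c in seq.upper())
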