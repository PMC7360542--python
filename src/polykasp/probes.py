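"""Array-probe manifest parsing and TOP/BOT strand decoding.

Illumina Infinium probes are published as a bracketed context sequence,
``<50bp flank>[X/Y]<50bp flank>``, together with two strand designations
("Customer Strand" and "ILMN Strand").  Because the same SNP can be reported
from either strand of the genome, Illumina normalises allele reporting with
the TOP/BOT convention: the designation is a deterministic function of the
SNP pair and, for ambiguous pairs, of the flanking sequence.  Reconciling the
two designations recovers the strand on which the 50 bp hybridisation probe
was actually designed, and hence which physical nucleotides the reported
A/B alleles correspond to.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

from ._dna import CHANNEL, UNAMBIGUOUS, IUPAC, complement, revcomp


class Strand(str, Enum):
    TOP = "TOP"
    BOT = "BOT"

    def flipped(self) -> "Strand":
        return Strand.BOT if self is Strand.TOP else Strand.TOP


class SourceType(str, Enum):
    GENOMIC = "genomic"
    TRANSCRIPT = "transcript"


class ProbeError(ValueError):
    """Base class for probe decoding errors; carries a stable code."""

    code = "PROBE_ERROR"


class UnresolvableStrand(ProbeError):
    code = "UNRESOLVABLE_STRAND"


class MalformedContext(ProbeError):
    code = "MALFORMED_CONTEXT"


@dataclass(frozen=True)
class ProbeRecord:
    """One array probe as published: bracketed context plus manifest strands."""

    probe_id: str
    context_seq: str
    customer_strand: Strand
    ilmn_strand: Strand
    declared_alleles: tuple[str, str]
    source_type: SourceType = SourceType.GENOMIC

    def __post_init__(self) -> None:
        left, snp, right = split_context(self.context_seq)
        if len(left) != len(right) or len(left) < 50:
            raise MalformedContext(
                f"{self.probe_id}: flanks must be equal length >= 50 "
                f"(got {len(left)}/{len(right)})"
            )
        a, b = (x.upper() for x in self.declared_alleles)
        if {a, b} != set(snp):
            raise MalformedContext(
                f"{self.probe_id}: declared alleles {a}/{b} are not a "
                f"permutation of the bracketed pair {snp[0]}/{snp[1]}"
            )
        object.__setattr__(self, "declared_alleles", (a, b))

    @property
    def snp_alleles(self) -> tuple[str, str]:
        _, snp, _ = split_context(self.context_seq)
        return snp


@dataclass(frozen=True)
class DecodedProbe:
    """A probe resolved onto its design strand.

    ``probe_seq_50`` is the hybridisation probe: 50 bases on the design
    strand with the 3' end immediately adjacent to the SNP.  ``channel_map``
    is fixed by the chemistry: A/T read out in the green channel, C/G in red.
    """

    probe_id: str
    probe_seq_50: str
    design_strand_alleles: tuple[str, str]
    reference_strand_alleles: tuple[str, str]
    design_context: str  # full context on the design strand, brackets removed
    snp_index: int  # 0-based index of the SNP in design_context
    source_type: SourceType = SourceType.GENOMIC
    channel_map: dict = field(
        default_factory=lambda: dict(CHANNEL), compare=False, repr=False
    )


def split_context(context: str) -> tuple[str, tuple[str, str], str]:
    """Split ``LEFT[X/Y]RIGHT`` into (left, (X, Y), right); validate."""
    s = context.strip().upper()
    lb, rb = s.find("["), s.find("]")
    if lb < 0 or rb < 0 or rb < lb:
        raise MalformedContext(f"no [X/Y] bracket in {context[:40]!r}")
    body = s[lb + 1 : rb]
    parts = body.split("/")
    if len(parts) != 2 or any(len(p) != 1 for p in parts):
        raise MalformedContext(f"bad bracket body {body!r}")
    x, y = parts
    if x == y or x not in UNAMBIGUOUS or y not in UNAMBIGUOUS:
        raise MalformedContext(f"bracket alleles must be distinct ACGT, got {body!r}")
    left, right = s[:lb], s[rb + 1 :]
    for flank in (left, right):
        if not all(c in IUPAC for c in flank):
            raise MalformedContext("non-IUPAC letters in flank")
    return left, (x, y), right


def classify_strand(context_seq: str) -> Strand:
    """TOP/BOT designation of a bracketed context sequence.

    Unambiguous SNP pairs decide directly: {A,C} and {A,G} are TOP, {T,C}
    and {T,G} are BOT.  Ambiguous pairs ({A,T}, {C,G}) are resolved by
    walking outward from the SNP one position at a time and inspecting the
    (5' base, 3' base) pair at each distance; the first pair with one base
    in {A,T} and the other in {C,G} decides — A/T on the 5' side means TOP.
    """
    left, (x, y), right = split_context(context_seq)
    pair = {x, y}
    if pair in ({"A", "C"}, {"A", "G"}):
        return Strand.TOP
    if pair in ({"T", "C"}, {"T", "G"}):
        return Strand.BOT
    # ambiguous {A,T} or {C,G}: outward walk
    for i in range(1, min(len(left), len(right)) + 1):
        five, three = left[-i], right[i - 1]
        five_at, three_at = five in "AT", three in "AT"
        five_cg, three_cg = five in "CG", three in "CG"
        if five_at and three_cg:
            return Strand.TOP
        if five_cg and three_at:
            return Strand.BOT
    raise UnresolvableStrand(
        "flanks exhausted without an informative A/T-vs-C/G pair"
    )


def decode_probe(
    record: ProbeRecord,
    report_strand: Strand = Strand.TOP,
    probe_flank: str = "5prime",
) -> DecodedProbe:
    """Resolve a :class:`ProbeRecord` onto its design strand.

    When the customer strand and the Illumina design strand disagree, the
    submitted context is reverse-complemented (and the declared alleles
    complemented) before the probe is read off.  The probe is the 50 bases
    5'-adjacent to the SNP on the design strand; ``probe_flank="3prime"``
    instead takes the reverse complement of the 3' flank (a probe on the
    opposite strand whose 3' end is likewise adjacent to the SNP).

    ``reference_strand_alleles`` re-expresses the declared pair on the
    requested TOP/BOT reporting strand.
    """
    if probe_flank not in ("5prime", "3prime"):
        raise ValueError("probe_flank must be '5prime' or '3prime'")
    left, (x, y), right = split_context(record.context_seq)
    alleles = record.declared_alleles
    if record.customer_strand != record.ilmn_strand:
        left, right = revcomp(right), revcomp(left)
        x, y = complement(x), complement(y)
        alleles = (complement(alleles[0]), complement(alleles[1]))
    design_context = left + x + right  # arbitrary allele at the SNP slot
    snp_index = len(left)
    if probe_flank == "5prime":
        probe_seq = left[-50:]
    else:
        probe_seq = revcomp(right[:50])
    if record.ilmn_strand == report_strand:
        ref_alleles = alleles
    else:
        ref_alleles = (complement(alleles[0]), complement(alleles[1]))
    return DecodedProbe(
        probe_id=record.probe_id,
        probe_seq_50=probe_seq,
        design_strand_alleles=alleles,
        reference_strand_alleles=ref_alleles,
        design_context=design_context,
        snp_index=snp_index,
        source_type=record.source_type,
    )


@dataclass(frozen=True)
class RowError:
    row: int  # 1-based data row number (header excluded)
    code: str
    message: str


@dataclass
class ManifestResult:
    records: list[ProbeRecord]
    errors: list[RowError]

    def __iter__(self) -> Iterator[ProbeRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


MANIFEST_COLUMNS = (
    "probe_id",
    "context_seq",
    "customer_strand",
    "ilmn_strand",
    "allele_a",
    "allele_b",
    "source_type",
)


def read_probe_manifest(path) -> ManifestResult:
    """Read a TSV probe manifest; malformed rows are collected, not fatal."""
    records: list[ProbeRecord] = []
    errors: list[RowError] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            warnings.warn(f"{path}: empty manifest", stacklevel=2)
            return ManifestResult([], [])
        rownum = 0
        for row in reader:
            rownum += 1
            missing = [c for c in MANIFEST_COLUMNS[:6] if not (row.get(c) or "").strip()]
            if missing:
                errors.append(
                    RowError(rownum, "MISSING_FIELD", f"missing {', '.join(missing)}")
                )
                continue
            try:
                records.append(
                    ProbeRecord(
                        probe_id=row["probe_id"].strip(),
                        context_seq=row["context_seq"].strip(),
                        customer_strand=Strand(row["customer_strand"].strip().upper()),
                        ilmn_strand=Strand(row["ilmn_strand"].strip().upper()),
                        declared_alleles=(
                            row["allele_a"].strip().upper(),
                            row["allele_b"].strip().upper(),
                        ),
                        source_type=SourceType(
                            (row.get("source_type") or "genomic").strip().lower()
                        ),
                    )
                )
            except (ProbeError, ValueError) as exc:
                code = getattr(exc, "code", "MALFORMED_CONTEXT")
                errors.append(RowError(rownum, code, str(exc)))
        if rownum == 0:
            warnings.warn(f"{path}: manifest has a header but no rows", stacklevel=2)
    return ManifestResult(records, errors)


def write_decoded_tsv(decoded: list[DecodedProbe], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["probe_id", "probe_seq_50", "design_allele_a", "design_allele_b",
             "top_allele_a", "top_allele_b", "source_type"]
        )
        for d in decoded:
            w.writerow(
                [d.probe_id, d.probe_seq_50, *d.design_strand_alleles,
                 *d.reference_strand_alleles, d.source_type.value]
            )
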