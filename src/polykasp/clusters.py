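"""Two-channel dosage model for array cluster layouts in polyploids.

An Infinium-style probe reads out every genomic copy it hybridises to, and
the two-color chemistry collapses nucleotides into channels: A and T are
measured in the green channel, C and G in red.  A sample's expected signal
is therefore a pair of integer "signal equivalents" — counts of green- and
red-channel nucleotides over the diploid alleles of all bound copies.  A
probe bound to a single locus gives the familiar three-cluster layout;
a probe bound to several homeologous copies gives dosage-shifted clusters
(hemi-SNPs), and a same-color misread of the true allele (a "triallelic"
hemi-SNP) produces a layout indistinguishable from the correct one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from ._dna import CHANNEL, COLOR_PARTNER, UNAMBIGUOUS


class SnpClass(str, Enum):
    SIMPLE = "simple"
    HEMI_ONE_HET = "hemi_biallelic_one_het"
    HEMI_TWO_HET = "hemi_biallelic_two_het"
    HEMI_TRIALLELIC = "hemi_triallelic_ambiguous"
    UNCLASSIFIED = "unclassified"


class DeclarationStatus(str, Enum):
    CONFIRMED = "confirmed"
    COLOR_AMBIGUOUS = "color_ambiguous"
    CONTRADICTED = "contradicted"


class MissingOfftargetState(ValueError):
    code = "MISSING_OFFTARGET_STATE"


@dataclass(frozen=True)
class AlleleComposition:
    """Diploid alleles of one genotype class at every bound copy.

    ``flattened`` concatenates the two alleles of each bound copy in locus
    order, e.g. ``"AATTGG"`` for a hexaploid sample bound at three copies.
    ``target_index`` marks which locus is the segregating target.
    """

    label: str
    loci: tuple[str, ...]
    alleles: tuple[tuple[str, str], ...]
    target_index: int = 0

    def __post_init__(self):
        for pair in self.alleles:
            for a in pair:
                if a not in UNAMBIGUOUS:
                    raise ValueError(f"non-ACGT allele {a!r}")

    @property
    def flattened(self) -> str:
        return "".join(a + b for a, b in self.alleles)

    @property
    def copy_count(self) -> int:
        return len(self.alleles)


@dataclass(frozen=True)
class SignalPoint:
    green_equiv: int
    red_equiv: int

    @property
    def magnitude(self) -> int:
        return self.green_equiv + self.red_equiv

    @property
    def theta(self) -> float:
        if self.magnitude == 0:
            raise ZeroDivisionError("theta undefined at zero magnitude")
        return self.red_equiv / self.magnitude

    @property
    def is_heterozygous_position(self) -> bool:
        return self.green_equiv > 0 and self.red_equiv > 0


def signal_equivalents(comp: AlleleComposition | str) -> SignalPoint:
    """Count green (A/T) and red (C/G) nucleotides in a composition."""
    flat = comp if isinstance(comp, str) else comp.flattened
    flat = flat.upper()
    if not set(flat) <= UNAMBIGUOUS:
        raise ValueError(f"composition {flat!r} contains non-ACGT characters")
    green = sum(1 for c in flat if CHANNEL[c] == "green")
    return SignalPoint(green_equiv=green, red_equiv=len(flat) - green)


@dataclass
class ClusterLayout:
    """Distinct signal points and the genotype classes mapping to each."""

    clusters: dict[SignalPoint, tuple[str, ...]]
    snp_class: SnpClass
    class_points: dict[str, SignalPoint]
    copy_count: int
    declaration_status: DeclarationStatus | None = None

    @property
    def heterozygous_position_clusters(self) -> list[SignalPoint]:
        return [p for p in self.clusters if p.is_heterozygous_position]

    def same_points(self, other: "ClusterLayout") -> bool:
        """Identical layout: the same ordered class -> point mapping."""
        return [p for p in self.class_points.values()] == [
            p for p in other.class_points.values()
        ]


def enumerate_compositions(
    loci: list[str] | int,
    target_alleles: tuple[str, str],
    offtarget_alleles: dict | list | None = None,
    target_index: int = 0,
) -> list[AlleleComposition]:
    """The three diploid genotype classes at the target locus.

    Off-target copies are fixed at the supplied (monomorphic) diploid
    states; every bound copy other than the target must have one, else
    :class:`MissingOfftargetState` is raised.
    """
    if isinstance(loci, int):
        loci = [f"copy{i}" for i in range(loci)]
    loci = list(loci)
    x, y = (a.upper() for a in target_alleles)
    fixed: dict[int, tuple[str, str]] = {}
    if offtarget_alleles is None:
        offtarget_alleles = {}
    if isinstance(offtarget_alleles, dict):
        items = offtarget_alleles.items()
    else:
        items = (
            (i, s) for i, s in zip(
                (j for j in range(len(loci)) if j != target_index),
                offtarget_alleles,
            )
        )
    for i, state in items:
        s = state.upper()
        fixed[i] = (s[0], s[1]) if len(s) == 2 else (s, s)
    missing = [i for i in range(len(loci)) if i != target_index and i not in fixed]
    if missing:
        raise MissingOfftargetState(
            f"no fixed allele state for bound copies {missing}"
        )
    out = []
    for label, pair in ((f"{x}{x}", (x, x)), (f"{x}{y}", (x, y)), (f"{y}{y}", (y, y))):
        alleles = tuple(
            pair if i == target_index else fixed[i] for i in range(len(loci))
        )
        out.append(
            AlleleComposition(
                label=label, loci=tuple(loci), alleles=alleles,
                target_index=target_index,
            )
        )
    return out


def predict_layout(compositions: list[AlleleComposition]) -> ClusterLayout:
    """Cluster layout implied by the dosage model.

    Classification follows the observed cluster geometry: a single bound
    copy is a simple SNP (three clusters); with multiple copies, the two
    homozygous classes land either on one pure-color and one mixed cluster
    (one heterozygous-position cluster) or on two mixed clusters.  If any
    off-target locus is polymorphic across the supplied compositions the
    taxonomy does not apply and the layout is left unclassified.
    """
    if len(compositions) < 2:
        raise ValueError("need at least two genotype classes")
    copy_count = compositions[0].copy_count
    tidx = compositions[0].target_index
    class_points = {c.label: signal_equivalents(c) for c in compositions}
    clusters: dict[SignalPoint, tuple[str, ...]] = {}
    for label, pt in class_points.items():
        clusters[pt] = clusters.get(pt, ()) + (label,)

    offtarget_polymorphic = any(
        len({c.alleles[i] for c in compositions}) > 1
        for i in range(copy_count)
        if i != tidx
    )
    if offtarget_polymorphic:
        cls = SnpClass.UNCLASSIFIED
    elif copy_count == 1:
        cls = SnpClass.SIMPLE
    else:
        homs = [compositions[0], compositions[-1]]
        mixed = [class_points[c.label].is_heterozygous_position for c in homs]
        if all(mixed):
            cls = SnpClass.HEMI_TWO_HET
        elif any(mixed):
            cls = SnpClass.HEMI_ONE_HET
        else:
            cls = SnpClass.UNCLASSIFIED
    return ClusterLayout(
        clusters=clusters, snp_class=cls, class_points=class_points,
        copy_count=copy_count,
    )


def _relabel(comp: AlleleComposition, old: str, new: str) -> AlleleComposition:
    """Substitute the target-locus allele ``old`` -> ``new`` in one class."""
    pair = tuple(new if a == old else a for a in comp.alleles[comp.target_index])
    alleles = tuple(
        pair if i == comp.target_index else p for i, p in enumerate(comp.alleles)
    )
    return AlleleComposition(
        label=comp.label, loci=comp.loci, alleles=alleles,
        target_index=comp.target_index,
    )


def check_declaration(
    layout: ClusterLayout,
    compositions: list[AlleleComposition],
    declared_alleles: tuple[str, str],
    sanger_target_alleles: tuple[str, str] | None = None,
) -> DeclarationStatus:
    """Can the declared allele pair be trusted, given the layout?

    A same-color substitution of a declared allele (A<->T or C<->G) that
    reproduces the identical layout means the two-channel chemistry cannot
    distinguish the declared pair from the substituted one: the declaration
    is ``color_ambiguous`` unless Sanger-resolved target alleles are
    supplied.  Sanger alleles differing in identity from the declaration
    make it ``contradicted``; matching ones make it ``confirmed``.  A
    single bound copy is exempt: there the declared pair is anchored by the
    submitted probe context itself, not inferred from cluster positions.
    ``compositions`` must represent the declared hypothesis (target pairs
    built from ``declared_alleles``).
    """
    declared = tuple(a.upper() for a in declared_alleles)
    if sanger_target_alleles is not None:
        sanger = {a.upper() for a in sanger_target_alleles}
        if sanger != set(declared):
            status = DeclarationStatus.CONTRADICTED
        else:
            status = DeclarationStatus.CONFIRMED
        layout.declaration_status = status
        return status
    if layout.copy_count == 1:
        layout.declaration_status = DeclarationStatus.CONFIRMED
        return DeclarationStatus.CONFIRMED
    for which in (0, 1):
        old = declared[which]
        new = COLOR_PARTNER[old]
        if new in declared:
            continue
        if not any(old in c.alleles[c.target_index] for c in compositions):
            continue  # substitution would be a no-op
        alt = [_relabel(c, old, new) for c in compositions]
        if all(
            signal_equivalents(a) == layout.class_points[c.label]
            for a, c in zip(alt, compositions)
        ):
            layout.declaration_status = DeclarationStatus.COLOR_AMBIGUOUS
            if layout.snp_class is SnpClass.HEMI_TWO_HET:
                layout.snp_class = SnpClass.HEMI_TRIALLELIC
            return DeclarationStatus.COLOR_AMBIGUOUS
    layout.declaration_status = DeclarationStatus.CONFIRMED
    return DeclarationStatus.CONFIRMED


@dataclass
class ConcordanceSummary:
    confirmed: int = 0
    contradicted: int = 0
    unresolvable: int = 0
    contradicted_probes: list[str] = field(default_factory=list)
    unmatched_probes: list[str] = field(default_factory=list)


def concordance_table(
    reported: dict[str, tuple[str, str]],
    sanger: dict[str, tuple[str, str] | None],
) -> ConcordanceSummary:
    """Compare declared allele pairs with Sanger-resolved target alleles.

    A probe is contradicted when the two pairs differ as nucleotide sets;
    probes without a resolved Sanger pair are unresolvable; probes present
    on only one side are listed as unmatched (not fatal).
    """
    summary = ConcordanceSummary()
    for pid in reported.keys() | sanger.keys():
        if pid not in reported or pid not in sanger:
            summary.unmatched_probes.append(pid)
            continue
        sg = sanger[pid]
        if sg is None:
            summary.unresolvable += 1
            continue
        if {a.upper() for a in reported[pid]} == {a.upper() for a in sg}:
            summary.confirmed += 1
        else:
            summary.contradicted += 1
            summary.contradicted_probes.append(pid)
    summary.unmatched_probes.sort()
    summary.contradicted_probes.sort()
    return summary
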