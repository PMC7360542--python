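"""Constraint-based KASP primer placement over a homeolog profile.

A KASP assay is two tailed allele-specific primers (differing only in
their 3'-terminal base, which sits exactly on the SNP) and one common
primer on the opposite strand.  In a polyploid the common primer decides
specificity: if it can prime on a homeologous copy, the off-target locus
amplifies and homozygous samples drift into heterozygous cluster
positions.  This module automates the visual placement strategy: enumerate
every candidate window over the profile's target row, exclude windows
crossing indel segments or intron-classified gaps, score each candidate
against every off-target copy with 3'-weighted mismatch counts, and keep
only designs whose common primer discriminates all off-targets.

Placement rules rather than thermodynamic rejection drive selection:
homopolymers and mild secondary structure are soft penalties, never
exclusions, because over-restrictive filtering discards primers that work.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from Bio.SeqUtils import MeltingTemp

from ._dna import UNAMBIGUOUS, revcomp
from .mapping import GenomeAssembly, HomeologProfile
from .probes import DecodedProbe


class FailureReason(str, Enum):
    NO_UNIQUE_SITE = "NO_UNIQUE_SITE"
    INTRON_SPAN = "INTRON_SPAN"
    INDEL_REGION = "INDEL_REGION"
    SNP_COLUMN_LOST = "SNP_COLUMN_LOST"
    NO_CANDIDATE_IN_TM_RANGE = "NO_CANDIDATE_IN_TM_RANGE"


class SpecificityClass(str, Enum):
    LOCUS_SPECIFIC = "locus_specific"
    SEMI_SPECIFIC = "semi_specific"
    NONSPECIFIC = "nonspecific"


class Role(str, Enum):
    ALLELE_A = "allele_specific_A"
    ALLELE_B = "allele_specific_B"
    COMMON = "common"


# Fluorophore tail sequences are chemistry constants of the KASP system
# (FAM- and HEX-compatible universal tails), not data derived from any
# particular study; both are configurable.
FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
HEX_TAIL = "GAAGGTCGGAGTCAACGGATT"


@dataclass
class PrimerParams:
    len_min: int = 18
    len_max: int = 30
    tm_min: float = 54.0
    tm_max: float = 60.0
    tm_opt: float = 57.0  # anchored to the 57 C annealing/elongation step
    amp_min: int = 50
    amp_max: int = 120
    max_amp_diff: int = 10
    tail_a: str = FAM_TAIL
    tail_b: str = HEX_TAIL
    w_terminal: float = 4.0  # 3'-terminal-base mismatch
    w_near: float = 2.0  # positions 2-5 from the 3' end
    w_far: float = 1.0
    absent_site_weight: float = 6.0  # off-target copy with no alignable site
    homopolymer_len: int = 5  # runs at/above this length are penalised
    homopolymer_penalty: float = 0.5  # per excess base, soft
    min_gap: int = 30  # gap width separating haplotype indels from introns
    # Tm solution conditions (PCR-mix-like): mM monovalent, mM Mg2+, mM
    # dNTPs, nM primer; passed to the nearest-neighbor model
    tm_na: float = 50.0
    tm_mg: float = 1.5
    tm_dntps: float = 0.6
    tm_dnac1: float = 50.0

    @classmethod
    def from_toml(cls, path) -> "PrimerParams":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {k: v for k, v in data.get("primers", data).items()
                 if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class OfftargetReport:
    mismatches: int | None  # None: no alignable site on this copy
    mismatches_3p5: int = 0
    terminal_mismatch: bool = False
    overlaps_indel: bool = False
    spans_intron: bool = False

    @property
    def absent(self) -> bool:
        return self.mismatches is None


@dataclass
class PrimerCandidate:
    sequence: str  # 5'->3', untailed
    placement: tuple[str, str, int, int, str]  # assembly, chrom, start, end, strand
    role: Role
    tm: float
    offtarget_report: dict[int, OfftargetReport]
    columns: tuple[int, int]  # inclusive MSA column interval
    msa_strand: str  # '+' same orientation as the profile frame
    soft_penalty: float = 0.0
    allele: str | None = None

    @property
    def uniqueness_score(self) -> float:
        return self._uniqueness

    _uniqueness: float = 0.0

    def discriminates_all(self) -> bool:
        return all(
            r.absent or (r.mismatches or 0) >= 1
            for r in self.offtarget_report.values()
        ) if self.offtarget_report else True

    def blocked_3p_all(self) -> bool:
        return all(
            r.absent or r.mismatches_3p5 >= 1
            for r in self.offtarget_report.values()
        ) if self.offtarget_report else True


@dataclass
class KaspAssay:
    assay_id: str
    probe_id: str
    primer_a: PrimerCandidate | None = None
    primer_b: PrimerCandidate | None = None
    common: PrimerCandidate | None = None
    tail_a: str = FAM_TAIL
    tail_b: str = HEX_TAIL
    amplicon_len_a: int | None = None
    amplicon_len_b: int | None = None
    specificity_class: SpecificityClass | None = None
    failure_reason: FailureReason | None = None
    amp_diff_flag: bool = False

    @property
    def primer_a_tailed(self) -> str | None:
        return self.tail_a + self.primer_a.sequence if self.primer_a else None

    @property
    def primer_b_tailed(self) -> str | None:
        return self.tail_b + self.primer_b.sequence if self.primer_b else None

    @property
    def failed(self) -> bool:
        return self.failure_reason is not None


def _soft_penalty(seq: str, params: PrimerParams) -> float:
    pen, run = 0.0, 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run >= params.homopolymer_len:
            pen += params.homopolymer_penalty
    # permissive 3' self-dimer check: last 4 bases complementary elsewhere
    tail = revcomp(seq[-4:])
    if tail in seq[:-4]:
        pen += 0.5
    return pen


def _column_masks(profile: HomeologProfile, params: PrimerParams):
    """Columns under short (indel) and long (intron-classified) gap runs.

    Gap runs are taken per row, over each row's aligned span, so a long
    intron gap in one row is recognised even where the other rows'
    (mutually unalignable) intron sequences fragment the joint segments.
    """
    indel_cols: set[int] = set()
    intron_cols: set[int] = set()
    for row in profile.msa:
        lo, hi = row.span
        c = lo
        while c < hi:
            if row.seq[c] == "-":
                start = c
                while c < hi and row.seq[c] == "-":
                    c += 1
                cols = range(start, c)
                if c - start >= params.min_gap:
                    intron_cols.update(cols)
                else:
                    indel_cols.update(cols)
            else:
                c += 1
    return indel_cols, intron_cols


def _tm(seq: str, params: "PrimerParams") -> float:
    """Nearest-neighbor Tm under the configured PCR-mix conditions."""
    return float(
        MeltingTemp.Tm_NN(
            seq, Na=params.tm_na, Mg=params.tm_mg, dNTPs=params.tm_dntps,
            dnac1=params.tm_dnac1, dnac2=0, saltcorr=7,
        )
    )


def _window_report(
    profile: HomeologProfile,
    cols: list[int],
    primer_bases: list[str],
    three_prime_at_start: bool,
    indel_cols: set[int],
    intron_cols: set[int],
) -> dict[int, OfftargetReport]:
    """Score the primer window against every off-target copy row."""
    reports: dict[int, OfftargetReport] = {}
    n = len(cols)
    for row_idx in range(2, len(profile.msa)):
        row = profile.msa[row_idx]
        covered = sum(
            1 for c in cols if row.span[0] <= c < row.span[1]
        )
        if covered < n:
            reports[row_idx - 1] = OfftargetReport(mismatches=None)
            continue
        mm = mm35 = 0
        term = False
        overlaps_indel = False
        for j, c in enumerate(cols):
            dist = (j + 1) if three_prime_at_start else (n - j)
            base = row.seq[c]
            if base == "-":
                overlaps_indel = True
            if base != primer_bases[j]:
                mm += 1
                if dist <= 5:
                    mm35 += 1
                if dist == 1:
                    term = True
        reports[row_idx - 1] = OfftargetReport(
            mismatches=mm, mismatches_3p5=mm35, terminal_mismatch=term,
            overlaps_indel=overlaps_indel,
        )
    return reports


def _uniqueness(report: dict[int, OfftargetReport], cols_n: int,
                three_prime_at_start: bool, profile, cols, primer_bases,
                params: PrimerParams) -> float:
    score = 0.0
    for row_off, rep in report.items():
        if rep.absent:
            score += params.absent_site_weight
            continue
        row = profile.msa[row_off + 1]
        for j, c in enumerate(cols):
            dist = (j + 1) if three_prime_at_start else (len(cols) - j)
            if row.seq[c] != primer_bases[j]:
                if dist == 1:
                    score += params.w_terminal
                elif dist <= 5:
                    score += params.w_near
                else:
                    score += params.w_far
    return score


@dataclass
class _Exclusions:
    intron: int = 0
    indel: int = 0
    tm: int = 0
    nonunique: int = 0


def _target_window(profile: HomeologProfile, c_lo: int, c_hi: int):
    """Target-row bases for an inclusive gapless column window, or None."""
    row = profile.msa[1]
    if c_lo < row.span[0] or c_hi >= row.span[1] or c_lo < 0 or c_hi >= profile.ncols:
        return None
    bases = []
    for c in range(c_lo, c_hi + 1):
        b = row.seq[c]
        if b == "-" or b not in UNAMBIGUOUS:
            return None
        bases.append(b)
    return bases


def enumerate_allele_primers(
    profile: HomeologProfile,
    target_alleles: tuple[str, str] | None = None,
    params: PrimerParams | None = None,
    orientation: str = "forward",
    excl: _Exclusions | None = None,
) -> list[PrimerCandidate]:
    """Allele-specific candidates ending 3' exactly on the SNP.

    ``orientation="forward"`` places the primer on the profile strand with
    the window extending 5' of the SNP; ``"reverse"`` places it on the
    opposite strand.  Windows overlapping indel segments or
    intron-classified gap columns are excluded; homopolymers are only
    penalised.  Each candidate carries a per-copy off-target report.
    """
    params = params or PrimerParams()
    excl = excl if excl is not None else _Exclusions()
    alleles = tuple(a.upper() for a in (target_alleles or profile.target_alleles))
    indel_cols, intron_cols = _column_masks(profile, params)
    snp = profile.snp_column
    out: list[PrimerCandidate] = []
    for L in range(params.len_min, params.len_max + 1):
        if orientation == "forward":
            c_lo, c_hi = snp - L + 1, snp
            three_at_start = False
        else:
            c_lo, c_hi = snp, snp + L - 1
            three_at_start = True
        cols = list(range(c_lo, c_hi + 1))
        winset = set(cols)
        if winset & intron_cols:
            excl.intron += 1
            continue
        bases = _target_window(profile, c_lo, c_hi)
        if bases is None:
            if winset & indel_cols:
                excl.indel += 1
            continue
        overlaps_indel = bool(winset & indel_cols)  # soft flag for AS primers
        snp_j = cols.index(snp)
        allele_seqs = []
        for allele in alleles:
            pbases = list(bases)
            pbases[snp_j] = allele
            seq = "".join(pbases)
            if orientation == "reverse":
                seq = revcomp(seq)
            allele_seqs.append((allele, pbases, seq, _tm(seq, params)))
        # both allele-specific primers share the placement, and their 3'
        # end is locked onto the SNP, so Tm deviation is a soft penalty
        # here (hard rejection would discard workable position-constrained
        # primers); the common primer keeps the hard Tm gate instead
        mean_tm = sum(t for *_, t in allele_seqs) / 2
        tm_pen = 0.5 * max(0.0, params.tm_min - mean_tm, mean_tm - params.tm_max)
        for which, (allele, pbases, seq, tm) in enumerate(allele_seqs):
            report = _window_report(
                profile, cols, pbases, three_at_start, indel_cols, intron_cols
            )
            for rep in report.values():
                rep.spans_intron = False
            asm, chrom, g0, g1, hstrand = profile.genomic_interval(1, c_lo, c_hi + 1)
            msa_strand = "+" if orientation == "forward" else "-"
            gstrand = hstrand if msa_strand == "+" else ("-" if hstrand == "+" else "+")
            cand = PrimerCandidate(
                sequence=seq,
                placement=(asm, chrom, g0, g1, gstrand),
                role=Role.ALLELE_A if which == 0 else Role.ALLELE_B,
                tm=tm,
                offtarget_report=report,
                columns=(c_lo, c_hi),
                msa_strand=msa_strand,
                soft_penalty=_soft_penalty(seq, params)
                + (0.5 if overlaps_indel else 0.0)
                + tm_pen,
                allele=allele,
            )
            cand._uniqueness = _uniqueness(
                report, L, three_at_start, profile, cols, pbases, params
            )
            out.append(cand)
    out.sort(key=lambda c: (-c._uniqueness, abs(c.tm - params.tm_opt),
                            c.soft_penalty, c.columns, c.role.value))
    return out


def enumerate_common_primers(
    profile: HomeologProfile,
    params: PrimerParams | None = None,
    orientation: str = "forward",
    excl: _Exclusions | None = None,
) -> list[PrimerCandidate]:
    """Common-primer candidates on the strand opposite the AS orientation.

    Candidates sit downstream of the SNP (for forward AS) within reach of
    the amplicon-length limits, hard-exclude indel and intron columns, and
    are ranked by a uniqueness score that weights off-target mismatches at
    the 3' terminus highest.  When off-target copies exist, only candidates
    with at least one mismatch (or no alignable site) against *every*
    off-target copy are retained — a common primer that matches a copy
    perfectly cannot give a locus-specific assay.
    """
    params = params or PrimerParams()
    excl = excl if excl is not None else _Exclusions()
    indel_cols, intron_cols = _column_masks(profile, params)
    snp = profile.snp_column
    has_offtargets = len(profile.msa) > 2
    out: list[PrimerCandidate] = []
    # distance (in target-row bases) from the SNP to the common primer's 5'
    # end, bounded so some AS length lands the amplicon inside the limits
    dmin = max(1, params.amp_min - params.len_max + 1)
    dmax = params.amp_max - params.len_min + 1
    for L in range(params.len_min, params.len_max + 1):
        for dist in range(dmin, dmax + 1):
            if orientation == "forward":
                # common on '-' strand, 5' end `dist` bases right of the SNP
                c_hi = snp + dist
                c_lo = c_hi - L + 1
                if c_lo <= snp:
                    continue
                three_at_start = True
            else:
                c_lo = snp - dist
                c_hi = c_lo + L - 1
                if c_hi >= snp:
                    continue
                three_at_start = False
            cols = list(range(c_lo, c_hi + 1))
            winset = set(cols)
            bases = _target_window(profile, c_lo, c_hi)
            if bases is None:
                if winset & intron_cols:
                    excl.intron += 1
                elif winset & indel_cols:
                    excl.indel += 1
                continue
            report = _window_report(
                profile, cols, bases, three_at_start, indel_cols, intron_cols
            )
            discriminates = (not has_offtargets) or all(
                r.absent or (r.mismatches or 0) >= 1 for r in report.values()
            )
            if winset & intron_cols:
                # a window that would have discriminated but crosses an
                # intron is a unique site lost to the intron
                excl.intron += 1 if discriminates else 0
                excl.nonunique += 0 if discriminates else 1
                continue
            if winset & indel_cols:  # hard exclude for the common primer
                excl.indel += 1 if discriminates else 0
                excl.nonunique += 0 if discriminates else 1
                continue
            if not discriminates:
                excl.nonunique += 1
                continue
            seq = "".join(bases)
            if orientation == "forward":
                seq = revcomp(seq)
            tm = _tm(seq, params)
            if not (params.tm_min <= tm <= params.tm_max):
                excl.tm += 1
                continue
            asm, chrom, g0, g1, hstrand = profile.genomic_interval(1, c_lo, c_hi + 1)
            msa_strand = "-" if orientation == "forward" else "+"
            gstrand = hstrand if msa_strand == "+" else ("-" if hstrand == "+" else "+")
            cand = PrimerCandidate(
                sequence=seq,
                placement=(asm, chrom, g0, g1, gstrand),
                role=Role.COMMON,
                tm=tm,
                offtarget_report=report,
                columns=(c_lo, c_hi),
                msa_strand=msa_strand,
                soft_penalty=_soft_penalty(seq, params),
            )
            cand._uniqueness = _uniqueness(
                report, L, three_at_start, profile, cols, bases, params
            )
            out.append(cand)
    out.sort(key=lambda c: (-c._uniqueness, abs(c.tm - params.tm_opt),
                            c.soft_penalty, c.columns))
    return out


def _amplicon_len(profile: HomeologProfile, as_cand: PrimerCandidate,
                  common: PrimerCandidate) -> int:
    row = profile.msa[1]
    lo = min(as_cand.columns[0], common.columns[0])
    hi = max(as_cand.columns[1], common.columns[1])
    return sum(1 for c in range(lo, hi + 1) if row.seq[c] != "-")


def design_assay(
    probe: DecodedProbe,
    profile: HomeologProfile,
    params: PrimerParams | None = None,
    assay_id: str | None = None,
) -> KaspAssay:
    """Select the best compatible (allele A, allele B, common) triple.

    Both orientations are tried; the pairing maximising the common
    primer's uniqueness score (ties broken by Tm proximity, soft
    penalties, then column-lexicographic order) wins.  Failures are
    returned as a structured reason on the assay, never raised, so batch
    designs always complete.
    """
    params = params or PrimerParams()
    assay = KaspAssay(
        assay_id=assay_id or f"kasp_{probe.probe_id}",
        probe_id=probe.probe_id,
        tail_a=params.tail_a,
        tail_b=params.tail_b,
    )
    excl = _Exclusions()
    best = None
    for orientation in ("forward", "reverse"):
        as_cands = enumerate_allele_primers(
            profile, None, params, orientation, excl
        )
        if not as_cands:
            continue
        commons = enumerate_common_primers(profile, params, orientation, excl)
        if not commons:
            continue
        by_role: dict[tuple, dict[Role, PrimerCandidate]] = {}
        for c in as_cands:
            by_role.setdefault(c.columns, {})[c.role] = c
        for cols, pair in sorted(by_role.items()):
            if Role.ALLELE_A not in pair or Role.ALLELE_B not in pair:
                continue
            a, b = pair[Role.ALLELE_A], pair[Role.ALLELE_B]
            for cm in commons:
                amp = _amplicon_len(profile, a, cm)
                if not (params.amp_min <= amp <= params.amp_max):
                    continue
                key = (
                    0 if cm.blocked_3p_all() else 1,  # prefer locus-specific
                    -cm._uniqueness,
                    -(a._uniqueness + b._uniqueness),
                    abs(cm.tm - params.tm_opt) + abs(a.tm - params.tm_opt),
                    cm.soft_penalty + a.soft_penalty + b.soft_penalty,
                    orientation,
                    cols,
                    cm.columns,
                )
                if best is None or key < best[0]:
                    best = (key, a, b, cm, amp)
    if best is None:
        if excl.intron > 0:
            assay.failure_reason = FailureReason.INTRON_SPAN
        elif excl.indel > 0:
            assay.failure_reason = FailureReason.INDEL_REGION
        elif excl.nonunique > 0 or excl.tm == 0:
            assay.failure_reason = FailureReason.NO_UNIQUE_SITE
        else:
            assay.failure_reason = FailureReason.NO_CANDIDATE_IN_TM_RANGE
        return assay
    _, a, b, cm, amp = best
    assay.primer_a, assay.primer_b, assay.common = a, b, cm
    assay.amplicon_len_a = assay.amplicon_len_b = amp
    assay.amp_diff_flag = abs(assay.amplicon_len_a - assay.amplicon_len_b) > params.max_amp_diff
    if cm.blocked_3p_all():
        assay.specificity_class = SpecificityClass.LOCUS_SPECIFIC
    elif cm.discriminates_all():
        assay.specificity_class = SpecificityClass.SEMI_SPECIFIC
    else:
        assay.specificity_class = SpecificityClass.NONSPECIFIC
    return assay


# ---------------------------------------------------------------------------
# in-silico specificity audit


@dataclass
class Placement:
    assembly: str
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int
    productive: bool  # perfect 3'-terminal-5 match and <= k total mismatches


@dataclass
class Amplicon:
    allele: str
    assembly: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AuditReport:
    placements: dict[str, list[Placement]]
    amplicons: list[Amplicon]
    broken_design: bool = False

    @property
    def n_feasible(self) -> int:
        return len(self.amplicons)

    def classify(self) -> SpecificityClass:
        if self.n_feasible <= 1:
            return SpecificityClass.LOCUS_SPECIFIC
        return SpecificityClass.SEMI_SPECIFIC


_CODE = {c: i for i, c in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _scan_primer(primer: str, seq: str, max_mm: int):
    """All (offset, mismatches) of primer against seq, forward orientation."""
    L, N = len(primer), len(seq)
    if N < L:
        return []
    s = _encode(seq)
    p = _encode(primer)
    counts = np.zeros(N - L + 1, dtype=np.int32)
    for j in range(L):
        counts += s[j : N - L + 1 + j] != p[j]
    idx = np.nonzero(counts <= max_mm)[0]
    return [(int(i), int(counts[i])) for i in idx]


def _placements_for(
    primer: str, assemblies: list[GenomeAssembly], max_mm: int
) -> list[Placement]:
    out = []
    L = len(primer)
    for asm in assemblies:
        for chrom, seq in asm.sequences.items():
            for strand in "+-":
                target = seq if strand == "+" else revcomp(seq)
                for off, mm in _scan_primer(primer, target, max_mm):
                    window = target[off : off + L]
                    tail_ok = window[-5:] == primer[-5:]
                    if strand == "+":
                        g0, g1 = off, off + L
                    else:
                        g0, g1 = len(seq) - off - L, len(seq) - off
                    out.append(
                        Placement(asm.name, chrom, g0, g1, strand, mm,
                                  productive=tail_ok and mm <= max_mm)
                    )
    return out


def specificity_audit(
    assay: KaspAssay,
    assemblies: list[GenomeAssembly],
    max_mm: int = 3,
    max_len_factor: float = 1.5,
) -> AuditReport:
    """Exhaustive scan for feasible amplicons anywhere in the assemblies.

    A placement is *productive* when the primer's 3'-terminal 5 bases match
    perfectly and total mismatches are <= ``max_mm`` (a 3'-proximal
    mismatch blocks extension in allele-specific PCR).  A feasible amplicon
    pairs a productive allele-specific placement with a productive,
    convergent common-primer placement at most ``max_len_factor`` times the
    intended amplicon length.
    """
    if assay.failed:
        raise ValueError("cannot audit a failed assay")
    prim = {
        "A": assay.primer_a.sequence,
        "B": assay.primer_b.sequence,
        "common": assay.common.sequence,
    }
    placements = {
        name: _placements_for(seq, assemblies, max_mm) for name, seq in prim.items()
    }
    max_len = int(max_len_factor * (assay.amplicon_len_a or 0)) or 10_000
    amplicons: list[Amplicon] = []
    for allele in "AB":
        for p_as in placements[allele]:
            if not p_as.productive:
                continue
            for p_c in placements["common"]:
                if not p_c.productive:
                    continue
                if (p_as.assembly, p_as.chrom) != (p_c.assembly, p_c.chrom):
                    continue
                if p_as.strand == p_c.strand:
                    continue
                # convergent: each primer's 3' end points toward the other
                if p_as.strand == "+":
                    if p_c.start < p_as.start:
                        continue
                    length = p_c.end - p_as.start
                else:
                    if p_as.end < p_c.end:
                        continue
                    length = p_as.end - p_c.start
                if 0 < length <= max_len:
                    amplicons.append(
                        Amplicon(allele, p_as.assembly, p_as.chrom,
                                 min(p_as.start, p_c.start),
                                 max(p_as.end, p_c.end))
                    )
    any_placed = any(placements.values())
    return AuditReport(
        placements=placements,
        amplicons=amplicons,
        broken_design=not any_placed or not amplicons,
    )


ASSAY_TSV_HEADER = (
    "assay_id\tprobe_id\tprimer_a_tailed\tprimer_b_tailed\tcommon\tchrom\t"
    "pos_1based\tamplicon_len_a\tamplicon_len_b\ttm_a\ttm_b\ttm_common\t"
    "specificity_class\tfailure_reason"
)


def assay_tsv_row(assay: KaspAssay) -> str:
    if assay.failed:
        return "\t".join(
            [assay.assay_id, assay.probe_id] + [""] * 10
            + ["", assay.failure_reason.value]
        )
    chrom = assay.primer_a.placement[1]
    pos = assay.primer_a.placement[3]  # 1-based position of the SNP (3' end)
    return "\t".join(
        [
            assay.assay_id, assay.probe_id,
            assay.primer_a_tailed, assay.primer_b_tailed, assay.common.sequence,
            chrom, str(pos),
            str(assay.amplicon_len_a), str(assay.amplicon_len_b),
            f"{assay.primer_a.tm:.1f}", f"{assay.primer_b.tm:.1f}",
            f"{assay.common.tm:.1f}",
            assay.specificity_class.value, "",
        ]
    )
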