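"""Seeded allopolyploid fixtures: loci, probes, and signal clouds.

Real validation of a KASP design pipeline needs an allopolyploid genome;
this module fabricates the smallest one with the right structure: a base
locus duplicated into homeologous copies at a tunable point-divergence
rate, a biallelic target SNP segregating only on the target copy (the
off-target copies fixed, as homeologs are within a species), optional
introns inserted into the genomic copies while the probe context is
emitted intron-free (the transcript-derived probe situation), optional
haplotype deletions at preset sizes, and an optional engineered
discriminating column that guarantees a locus-unique primer window.

Every stochastic choice consumes one owned seeded generator, so identical
configurations are bit-identical.  A truth record lists every engineered
feature for round-trip tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._dna import revcomp
from .clusters import ClusterLayout
from .mapping import GenomeAssembly
from .probes import ProbeRecord, SourceType, classify_strand
from .qc import FluorescencePoint

BASES = np.array(list("ACGT"))


class ConfigConflict(ValueError):
    code = "CONFIG_CONFLICT"


@dataclass
class SimConfig:
    seed: int = 0
    n_copies: int = 3
    locus_len: int = 2000
    divergence: float = 0.05
    snp_pos: int | None = None  # position in the base locus; default: centre
    target_alleles: tuple[str, str] = ("A", "G")
    # homozygous state of each off-target copy at the SNP column, in copy
    # order with the target copy skipped, e.g. ("T", "G") for a hexaploid
    offtarget_states: tuple[str, ...] | None = None
    introns: tuple[tuple[int, int], ...] = ()  # (context offset 0..100, length)
    copy_deletions: tuple[tuple[int, int, int], ...] = ()  # (copy, offset from SNP, length)
    # engineered discriminating columns at +offset and -offset from the SNP
    # (every off-target copy differs from the target there), guaranteeing a
    # locus-unique primer window on at least one side; None disables
    unique_site_offset: int | None = 35
    sigma: float = 0.03  # channel noise, fraction of full scale
    mixture_ratios: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    scale: float = 1000.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class LocusTruth:
    assembly_name: str
    chroms: list[str]
    target_copy: int
    snp_positions: list[int]  # final genomic SNP position per copy
    target_alleles: tuple[str, str]
    offtarget_states: dict[int, str]
    # per copy: sorted context-frame offsets (relative to the SNP) where the
    # copy differs from the target copy, within the +/-150 window
    variant_offsets: dict[int, list[int]]
    introns: list[tuple[int, int]]  # (context offset, length)
    copy_deletions: list[tuple[int, int, int]]
    context_left: str  # 50 bp 5' of the SNP, target copy, + strand, intron-free
    context_right: str

    def context_bracketed(self) -> str:
        x, y = self.target_alleles
        return f"{self.context_left}[{x}/{y}]{self.context_right}"

    def to_json(self) -> str:
        d = asdict(self)
        d["variant_offsets"] = {str(k): v for k, v in d["variant_offsets"].items()}
        d["offtarget_states"] = {str(k): v for k, v in d["offtarget_states"].items()}
        return json.dumps(d)


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, base: str, avoid: str | None = None) -> str:
    choices = [b for b in "ACGT" if b != base and b != avoid]
    return choices[rng.integers(0, len(choices))]


def simulate_polyploid_locus(
    config: SimConfig,
) -> tuple[list[GenomeAssembly], LocusTruth]:
    """One target locus plus homeologous copies, with engineered truth.

    The target copy carries ``target_alleles[0]`` at the SNP; each
    off-target copy is fixed at its configured (or drawn) state.  Copies
    other than the target accumulate substitutions at ``divergence`` per
    site.  Introns are inserted into every genomic copy (independent
    random sequence, shared position and length); the emitted probe
    context skips them.  ``copy_deletions`` remove bases from single
    copies, e.g. the 8/36/53 bp haplotype-deletion presets.
    """
    rng = config.rng()
    n = config.locus_len
    snp = config.snp_pos if config.snp_pos is not None else n // 2
    if not 150 <= snp <= n - 150:
        raise ConfigConflict("SNP must sit at least 150 bp from the locus ends")
    x, y = (a.upper() for a in config.target_alleles)
    if x == y or x not in "ACGT" or y not in "ACGT":
        raise ConfigConflict(f"bad target alleles {config.target_alleles}")
    for copy_i, off, length in config.copy_deletions:
        # deletion interval is [snp+off, snp+off+length)
        if -length < off <= 0:
            raise ConfigConflict("deletion overlaps the SNP")
    for off, _len in config.introns:
        if not 0 < off <= 100:
            raise ConfigConflict("intron offset must fall inside the 101 bp context")

    base = _random_seq(rng, n)
    base[snp] = x

    n_off = config.n_copies - 1
    if config.offtarget_states is None:
        states = tuple(str(_random_seq(rng, 1)[0]) for _ in range(n_off))
    else:
        states = tuple(s[0].upper() for s in config.offtarget_states)
        if len(states) != n_off:
            raise ConfigConflict(
                f"{len(states)} off-target states for {n_off} off-target copies"
            )

    copies: list[np.ndarray] = [base.copy()]
    variant_offsets: dict[int, list[int]] = {}
    offtarget_states: dict[int, str] = {}
    for i in range(1, config.n_copies):
        cp = base.copy()
        nsub = rng.binomial(n, config.divergence)
        pos = rng.choice(n, size=nsub, replace=False)
        offsets = set()
        for p in sorted(int(q) for q in pos):
            if p == snp:
                continue
            cp[p] = _mutate(rng, str(base[p]))
            if abs(p - snp) <= 150:
                offsets.add(p - snp)
        state = states[i - 1]
        cp[snp] = state
        offtarget_states[i] = state
        if state != x:
            offsets.add(0)
        if config.unique_site_offset is not None:
            for sign in (+1, -1):
                p = snp + sign * config.unique_site_offset
                cp[p] = _mutate(rng, str(base[p]))
                offsets.add(sign * config.unique_site_offset)
        variant_offsets[i] = sorted(offsets)
        copies.append(cp)

    # intron-free context from the target copy, before intron insertion
    context_left = "".join(copies[0][snp - 50 : snp])
    context_right = "".join(copies[0][snp + 1 : snp + 51])

    letters = ["A", "B", "D"] + [chr(ord("E") + i) for i in range(max(0, config.n_copies - 3))]
    chrom_names = [f"chr5{letters[i]}" for i in range(config.n_copies)]
    # copy order == chromosome-name order; copy 0 is the target locus
    sequences: dict[str, str] = {}
    snp_positions: list[int] = []
    deletions = [tuple(d) for d in config.copy_deletions]
    for i, cp in enumerate(copies):
        seq = "".join(cp)
        edits = []  # (position, del_len, insert_seq)
        for copy_i, off, length in deletions:
            if copy_i == i:
                edits.append((snp + off, length, ""))
        for off, length in config.introns:
            pos = snp - 50 + off
            intron_seq = "".join(_random_seq(rng, length))
            edits.append((pos, 0, intron_seq))
        edits.sort()
        out = []
        cursor = 0
        shift_before_snp = 0
        for pos, dlen, ins in edits:
            if pos < cursor:
                raise ConfigConflict("overlapping edits in one copy")
            out.append(seq[cursor:pos])
            out.append(ins)
            cursor = pos + dlen
            if pos <= snp:
                shift_before_snp += len(ins) - dlen
        out.append(seq[cursor:])
        sequences[chrom_names[i]] = "".join(out)
        snp_positions.append(snp + shift_before_snp)

    assembly = GenomeAssembly(name="sim", sequences=sequences)
    truth = LocusTruth(
        assembly_name="sim",
        chroms=chrom_names,
        target_copy=0,
        snp_positions=snp_positions,
        target_alleles=(x, y),
        offtarget_states=offtarget_states,
        variant_offsets=variant_offsets,
        introns=[tuple(i) for i in config.introns],
        copy_deletions=deletions,
        context_left=context_left,
        context_right=context_right,
    )
    return [assembly], truth


def simulate_probe_context(
    truth: LocusTruth,
    source_type: SourceType = SourceType.TRANSCRIPT,
    rng: np.random.Generator | None = None,
    probe_id: str = "sim_probe",
) -> ProbeRecord:
    """A manifest record for the engineered SNP, on a random strand.

    The submitted context is the intron-free target-copy context, possibly
    reverse-complemented; the TOP/BOT designations are emitted so that
    decoding recovers the original (+ strand) design context and alleles.
    """
    rng = rng or np.random.default_rng(0)
    flip = bool(rng.integers(0, 2))
    context = truth.context_bracketed()
    x, y = truth.target_alleles
    if flip:
        left, right = truth.context_left, truth.context_right
        context = (
            revcomp(right) + f"[{revcomp(x)}/{revcomp(y)}]" + revcomp(left)
        )
        x, y = revcomp(x), revcomp(y)
    cs = classify_strand(context)
    ilmn = cs.flipped() if flip else cs
    return ProbeRecord(
        probe_id=probe_id,
        context_seq=context,
        customer_strand=cs,
        ilmn_strand=ilmn,
        declared_alleles=(x, y),
        source_type=source_type,
    )


#: endpoint-plateau exponent: competitive PCR run to the plateau reports
#: allele presence, not template dosage, so a template fraction r maps to
#: an amplified fraction r^g / (r^g + (1-r)^g) with g < 1
SATURATION_GAMMA = 0.3


def saturated_fraction(ratio: float, gamma: float = SATURATION_GAMMA) -> float:
    a = ratio**gamma
    b = (1.0 - ratio) ** gamma
    return a / (a + b)


def simulate_signal_cloud(
    layout: ClusterLayout,
    n_per_class: int = 40,
    sigma: float = 0.03,
    mixtures: tuple[float, ...] = (),
    rng: np.random.Generator | None = None,
    scale: float = 1000.0,
    n_ntc: int = 3,
) -> tuple[list[FluorescencePoint], list[str]]:
    """Gaussian clouds around the layout's signal-equivalent centroids.

    Mixture samples emulate artificial heterozygotes: DNA from the two
    homozygous classes combined at template ratio r, amplified to the
    endpoint plateau (see :func:`saturated_fraction`), so every ratio in
    1:9-9:1 lands near the heterozygous position.  Returns points plus
    truth labels (class label, ``mix:<r>``, or ``NTC``).
    """
    rng = rng or np.random.default_rng(0)
    denom = 2 * layout.copy_count
    cents = {
        label: np.array([pt.green_equiv, pt.red_equiv]) / denom * scale
        for label, pt in layout.class_points.items()
    }
    points: list[FluorescencePoint] = []
    labels: list[str] = []
    i = 0
    for label, c in cents.items():
        for _ in range(n_per_class):
            xy = np.maximum(c + rng.normal(0.0, sigma * scale, size=2), 0.0)
            points.append(FluorescencePoint(f"s{i:04d}", float(xy[0]), float(xy[1])))
            labels.append(label)
            i += 1
    class_labels = list(cents)
    hom1, hom2 = cents[class_labels[0]], cents[class_labels[-1]]
    for r in mixtures:
        w = saturated_fraction(float(r))
        c = w * hom1 + (1 - w) * hom2
        for _ in range(max(1, n_per_class // 4)):
            xy = np.maximum(c + rng.normal(0.0, sigma * scale, size=2), 0.0)
            points.append(FluorescencePoint(f"s{i:04d}", float(xy[0]), float(xy[1])))
            labels.append(f"mix:{r:g}")
            i += 1
    for _ in range(n_ntc):
        xy = np.abs(rng.normal(0.0, 0.02 * scale, size=2))
        points.append(
            FluorescencePoint(f"ntc{i:04d}", float(xy[0]), float(xy[1]), is_ntc=True)
        )
        labels.append("NTC")
        i += 1
    return points, labels
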