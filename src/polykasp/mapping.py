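"""Homeolog discovery and joint profiling of a probe's target region.

In an allopolyploid, a 101 bp probe context typically matches two or more
homeologous loci at 90–99% identity.  This module finds every such copy
across one or more assemblies (both strands), keeps hits passing identity
and E-value filters, and assembles the extracted regions plus the probe
context into a star multiple alignment anchored on the best hit.  The
profile annotates variant columns (candidate discriminating sites for
primer placement), indel segments, and intron interruptions — the three
features that decide whether a locus-specific KASP assay is designable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

from ._dna import revcomp
from .align import ChainedAlignment, Run, Scoring, chained_local_align, seed_windows
from .probes import DecodedProbe


class SnpColumnLost(ValueError):
    code = "SNP_COLUMN_LOST"


@dataclass
class GenomeAssembly:
    name: str
    sequences: dict[str, str]

    @classmethod
    def from_fasta(cls, path, name: str | None = None) -> "GenomeAssembly":
        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            cid = rec.id.split()[0]
            if cid in seqs:
                raise ValueError(f"duplicate chromosome id {cid!r} in {path}")
            seqs[cid] = str(rec.seq).upper()
        return cls(name=name or str(path), sequences=seqs)

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for cid, seq in self.sequences.items():
                fh.write(f">{cid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class HomeologHit:
    """One genomic copy of the query region.

    ``aligned_blocks`` are gapless runs in an *oriented* frame: query
    coordinates vs positions along the target strand that matches the query
    (for '-' hits, positions along the reverse complement of the
    chromosome).  ``start``/``end`` are genomic, forward-strand, 0-based
    half-open.  ``percent_identity`` is matches over aligned query columns;
    target-side gaps (introns) are excluded from the denominator.
    """

    assembly: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    percent_identity: float
    score: float
    evalue: float
    aligned_blocks: list[Run]
    chrom_length: int
    snp_target_pos: int | None = None  # genomic forward coordinate, or None

    @property
    def gap_lengths(self) -> list[int]:
        return [
            nxt.tstart - prv.tend
            for prv, nxt in zip(self.aligned_blocks, self.aligned_blocks[1:])
        ]

    def oriented_interval(self) -> tuple[int, int]:
        """Hit interval in the oriented (query-strand) frame."""
        s = self.aligned_blocks[0].tstart
        e = self.aligned_blocks[-1].tend
        return s, e

    def to_genomic(self, oriented_pos: int) -> int:
        if self.strand == "+":
            return oriented_pos
        return self.chrom_length - 1 - oriented_pos


def _hit_from_chain(
    chain: ChainedAlignment,
    assembly: str,
    chrom: str,
    strand: str,
    chrom_len: int,
    qlen: int,
    total_n: int,
    scoring: Scoring,
    snp_query_pos: int | None,
) -> HomeologHit:
    s, e = chain.tstart, chain.tend
    if strand == "+":
        gstart, gend = s, e
    else:
        gstart, gend = chrom_len - e, chrom_len - s
    snp_pos = None
    if snp_query_pos is not None:
        for r in chain.runs:
            if r.qstart <= snp_query_pos < r.qend:
                oriented = r.tstart + (snp_query_pos - r.qstart)
                snp_pos = oriented if strand == "+" else chrom_len - 1 - oriented
                break
    return HomeologHit(
        assembly=assembly,
        chrom=chrom,
        start=gstart,
        end=gend,
        strand=strand,
        percent_identity=chain.identity,
        score=chain.score,
        evalue=scoring.evalue(chain.score, qlen, total_n),
        aligned_blocks=chain.runs,
        chrom_length=chrom_len,
        snp_target_pos=snp_pos,
    )


def search_homeologs(
    query: str,
    assemblies: list[GenomeAssembly],
    min_identity: float = 0.80,
    max_evalue: float = 1e-5,
    scoring: Scoring | None = None,
    k: int = 12,
    snp_query_pos: int | None = None,
    dedup_slop: int = 10,
) -> list[HomeologHit]:
    """All genomic copies of ``query`` passing both retention filters.

    Seed-and-extend on both strands of every chromosome; hits must pass
    BOTH ``min_identity`` (over aligned query columns) and ``max_evalue``.
    Overlapping same-strand hits within ``dedup_slop`` bp merge, keeping
    the higher score.  Result is sorted by identity descending, ties by
    (assembly, chrom, start).
    """
    if len(query) < 31:
        raise ValueError("query must be at least 31 bp")
    if not assemblies:
        raise ValueError("at least one assembly required")
    scoring = scoring or Scoring()
    query = query.upper()
    total_n = sum(len(s) for a in assemblies for s in a.sequences.values())
    hits: list[HomeologHit] = []
    for asm in assemblies:
        for chrom, seq in asm.sequences.items():
            for strand in "+-":
                target = seq if strand == "+" else revcomp(seq)
                for ws, we in seed_windows(query, target, k=k):
                    chain = chained_local_align(query, target[ws:we], scoring)
                    if chain is None:
                        continue
                    chain.runs = [
                        Run(r.qstart, r.qend, r.tstart + ws, r.tend + ws)
                        for r in chain.runs
                    ]
                    hit = _hit_from_chain(
                        chain, asm.name, chrom, strand, len(seq),
                        len(query), total_n, scoring, snp_query_pos,
                    )
                    if hit.percent_identity >= min_identity and hit.evalue <= max_evalue:
                        hits.append(hit)
    hits = _dedup(hits, dedup_slop)
    hits.sort(key=lambda h: (-h.percent_identity, h.assembly, h.chrom, h.start))
    return hits


def _dedup(hits: list[HomeologHit], slop: int) -> list[HomeologHit]:
    kept: list[HomeologHit] = []
    for h in sorted(hits, key=lambda x: (-x.score, x.assembly, x.chrom, x.start)):
        dup = False
        for k_ in kept:
            if (
                (h.assembly, h.chrom, h.strand) == (k_.assembly, k_.chrom, k_.strand)
                and h.start < k_.end + slop
                and k_.start < h.end + slop
            ):
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


def detect_intron_gaps(
    hit: HomeologHit, min_gap: int = 30
) -> list[tuple[int, int]]:
    """Putative introns: target-side gaps >= ``min_gap`` between blocks.

    Returns (query position of the junction, target gap length) in query
    order.  A gap this large in a genomic hit of a transcript-derived probe
    is interpreted as an intron interrupting the probe context.
    """
    out = []
    for prv, nxt in zip(hit.aligned_blocks, hit.aligned_blocks[1:]):
        tgap = nxt.tstart - prv.tend
        qgap = nxt.qstart - prv.qend
        if tgap - qgap >= min_gap:
            out.append((prv.qend, tgap))
    return out


@dataclass
class MsaRow:
    label: str
    seq: str  # gapped, length = profile ncols
    span: tuple[int, int]  # [first, last+1) aligned column range
    hit_index: int | None = None  # None for the query row
    extract_offset: int = 0  # oriented-frame start of the extracted region


@dataclass
class HomeologProfile:
    """Joint alignment of a probe context with all of its genomic copies."""

    probe_id: str
    hits: list[HomeologHit]
    msa: list[MsaRow]  # row 0 = query context; row 1 = target locus (best hit)
    snp_column: int
    target_alleles: tuple[str, str]
    variant_columns: list[tuple[int, dict[int, str]]]
    indel_segments: list[tuple[tuple[int, int], frozenset[int]]]
    intron_flags: list[bool]
    ref_col_pos: list[int | None] = field(repr=False, default_factory=list)
    source_type: str = "genomic"

    @property
    def copy_count(self) -> int:
        return len(self.hits)

    @property
    def ncols(self) -> int:
        return len(self.msa[0].seq) if self.msa else 0

    def column_bases(self, col: int) -> dict[int, str]:
        out = {}
        for i, row in enumerate(self.msa):
            if row.span[0] <= col < row.span[1] and row.seq[col] != "-":
                out[i] = row.seq[col]
        return out

    def genomic_interval(self, row_index: int, col_start: int, col_end: int):
        """Map a column interval on a hit row to (assembly, chrom, start, end, strand)."""
        row = self.msa[row_index]
        if row.hit_index is None:
            raise ValueError("query row has no genomic placement")
        hit = self.hits[row.hit_index]
        # count of non-gap bases before col_start gives local offset
        local0 = row.extract_offset + sum(
            1 for c in row.seq[:col_start] if c != "-"
        )
        nbases = sum(1 for c in row.seq[col_start:col_end] if c != "-")
        o_start, o_end = local0, local0 + nbases
        if hit.strand == "+":
            g = (o_start, o_end)
        else:
            g = (hit.chrom_length - o_end, hit.chrom_length - o_start)
        return hit.assembly, hit.chrom, g[0], g[1], hit.strand


def _oriented_chrom(assembly: GenomeAssembly, hit: HomeologHit) -> str:
    seq = assembly.sequences[hit.chrom]
    return seq if hit.strand == "+" else revcomp(seq)


def build_profile(
    probe: DecodedProbe,
    hits: list[HomeologHit],
    assemblies: list[GenomeAssembly],
    pad: int = 150,
    min_gap: int = 30,
    scoring: Scoring | None = None,
) -> HomeologProfile:
    """Star multiple alignment of the probe context and all hit regions.

    Each hit region is extracted with ``pad`` bp of flanking sequence
    (oriented to the query strand).  The best hit's extraction is the
    alignment reference; every other row (including the probe context) is
    placed by chained local alignment against it.  Insertions relative to
    the reference get their own columns; unalignable excess in substituted
    regions is paired left-to-right (adequate at homeolog-level divergence).
    """
    if not hits:
        raise ValueError("build_profile requires at least one hit")
    scoring = scoring or Scoring()
    asm_map = {a.name: a for a in assemblies}

    extracts: list[tuple[str, int]] = []  # (sequence, oriented offset)
    for hit in hits:
        oriented = _oriented_chrom(asm_map[hit.assembly], hit)
        s, e = hit.oriented_interval()
        lo, hi = max(0, s - pad), min(len(oriented), e + pad)
        extracts.append((oriented[lo:hi], lo))

    ref_seq, ref_off = extracts[0]
    query_seq = probe.design_context

    # chained alignment of every row against the reference extraction
    row_seqs = [query_seq] + [x[0] for x in extracts]
    row_offsets = [0] + [x[1] for x in extracts]
    row_chains: list[ChainedAlignment | None] = []
    for i, seq in enumerate(row_seqs):
        if i == 1:
            row_chains.append(
                ChainedAlignment(
                    runs=[Run(0, len(ref_seq), 0, len(ref_seq))],
                    score=float(len(ref_seq)),
                    matches=len(ref_seq),
                    query_columns=len(ref_seq),
                )
            )
        else:
            row_chains.append(chained_local_align(seq, ref_seq, scoring))

    # per-row (row_base_interval -> ref_base_interval) pairings incl. naive
    # pairing inside substituted regions; insertions collected per ref pos
    paired: list[list[tuple[int, int, int]] | None] = []  # (qpos, refpos) pairs stored as runs
    insertions: dict[int, int] = {}  # ref position -> max inserted length
    row_ins: list[dict[int, tuple[int, int]]] = []  # refpos -> (qstart, qend)

    for chain in row_chains:
        if chain is None:
            paired.append(None)
            row_ins.append({})
            continue
        runs = []
        ins: dict[int, tuple[int, int]] = {}
        prev = None
        for r in chain.runs:
            if prev is not None:
                qgap = r.qstart - prev.qend
                tgap = r.tstart - prev.tend
                npair = min(qgap, tgap)
                if npair > 0:
                    runs.append((prev.qend, prev.qend + npair, prev.tend))
                if qgap > tgap:  # insertion relative to the reference
                    ins[r.tstart] = (prev.qend + npair, r.qstart)
                    insertions[r.tstart] = max(
                        insertions.get(r.tstart, 0), qgap - npair
                    )
            runs.append((r.qstart, r.qend, r.tstart))
            prev = r
        paired.append(runs)
        row_ins.append(ins)

    # column layout: insertion columns precede the reference base they sit before
    ncols_ref = len(ref_seq)
    col_of_ref: list[int] = []
    ins_col_start: dict[int, int] = {}
    col = 0
    for p in range(ncols_ref + 1):
        if p in insertions:
            ins_col_start[p] = col
            col += insertions[p]
        if p < ncols_ref:
            col_of_ref.append(col)
            col += 1
    ncols = col
    ref_col_pos: list[int | None] = [None] * ncols
    for p, c in enumerate(col_of_ref):
        ref_col_pos[c] = p

    rows: list[MsaRow] = []
    labels = [f"query:{probe.probe_id}"] + [
        f"{h.assembly}:{h.chrom}:{h.start}-{h.end}({h.strand})" for h in hits
    ]
    for i, (seq, runs) in enumerate(zip(row_seqs, paired)):
        buf = ["-"] * ncols
        if runs is None:
            rows.append(MsaRow(labels[i], "".join(buf), (0, 0),
                               None if i == 0 else i - 1, row_offsets[i]))
            continue
        first_col, last_col = ncols, 0
        for qs, qe, ts in runs:
            for j in range(qe - qs):
                c = col_of_ref[ts + j]
                buf[c] = seq[qs + j]
                first_col = min(first_col, c)
                last_col = max(last_col, c)
        for refpos, (qs, qe) in row_ins[i].items():
            c0 = ins_col_start[refpos]
            for j in range(qe - qs):
                buf[c0 + j] = seq[qs + j]
                first_col = min(first_col, c0 + j)
                last_col = max(last_col, c0 + j)
        rows.append(
            MsaRow(labels[i], "".join(buf), (first_col, last_col + 1),
                   None if i == 0 else i - 1, row_offsets[i])
        )

    # SNP column: probe.snp_index through the query row pairing
    snp_col = None
    if paired[0] is not None:
        for qs, qe, ts in paired[0]:
            if qs <= probe.snp_index < qe:
                snp_col = col_of_ref[ts + (probe.snp_index - qs)]
                break
    if snp_col is None:
        raise SnpColumnLost(
            f"{probe.probe_id}: SNP position unalignable against the reference copy"
        )

    variant_columns = []
    for c in range(ncols):
        bases = {}
        for i, row in enumerate(rows):
            if row.span[0] <= c < row.span[1] and row.seq[c] != "-":
                bases[i] = row.seq[c]
        if len(set(bases.values())) > 1:
            variant_columns.append((c, bases))

    # indel segments: maximal runs of columns with a constant non-empty set
    # of rows gapped inside their aligned span
    indel_segments: list[tuple[tuple[int, int], frozenset[int]]] = []
    cur_set: frozenset[int] | None = None
    cur_start = 0
    for c in range(ncols + 1):
        gapped = frozenset(
            i for i, row in enumerate(rows)
            if c < ncols and row.span[0] <= c < row.span[1] and row.seq[c] == "-"
        ) if c < ncols else frozenset()
        if gapped != (cur_set or frozenset()):
            if cur_set:
                indel_segments.append(((cur_start, c), cur_set))
            cur_set = gapped or None
            cur_start = c
    intron_flags = [bool(detect_intron_gaps(h, min_gap)) for h in hits]

    return HomeologProfile(
        probe_id=probe.probe_id,
        hits=hits,
        msa=rows,
        snp_column=snp_col,
        target_alleles=probe.design_strand_alleles,
        variant_columns=variant_columns,
        indel_segments=indel_segments,
        intron_flags=intron_flags,
        ref_col_pos=ref_col_pos,
        source_type=probe.source_type.value,
    )


def hits_to_bed(hits: list[HomeologHit], name: str = "hit") -> str:
    """6-column BED (0-based half-open), score = identity in thousandths."""
    lines = []
    for h in hits:
        lines.append(
            "\t".join(
                [h.chrom, str(h.start), str(h.end),
                 f"{name}|{h.assembly}", str(int(round(h.percent_identity * 1000))),
                 h.strand]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
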