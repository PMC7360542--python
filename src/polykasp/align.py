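"""Seed-and-extend local alignment with large-gap (intron) chaining.

The search problem here is small but structured: a ~101 bp probe context
against a handful of multi-kilobase homeologous loci.  Exact k-mer seeds
locate candidate regions; each region is refined with an affine-gap local
alignment (Gotoh, via Bio.Align.PairwiseAligner); and co-linear local
alignments separated by a large target-side gap — an intron interrupting a
transcript-derived probe — are chained into a single spliced hit, because a
single affine alignment would truncate at the intron (a 120 bp gap costs
far more than the downstream match can repay under the default scheme).

Scoring (documented, configurable): match +1, mismatch -1, a gap of length
L scores -(2 + 0.5·L).  Percent identity is computed over aligned query
columns (query bases inside the chained alignment); target-only gap columns
— including intron gaps — do not enter the denominator.  Significance uses
a Karlin–Altschul style E-value, E = K·m·n·exp(-lambda·S), with (K, lambda)
calibrated for the fixed scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0  # charged once per gap, on top of per-base extension
    gap_extend: float = -0.5
    # Karlin-Altschul surrogate constants for this scheme (uniform base
    # composition; lambda solves sum p_i p_j exp(lambda s_ij) = 1 for the
    # ungapped +1/-1 scheme, K is the conventional pre-factor).
    ka_lambda: float = math.log(3.0)
    ka_k: float = 0.3

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        # PairwiseAligner charges open_gap_score for the first gap base
        a.open_gap_score = self.gap_open + self.gap_extend
        a.extend_gap_score = self.gap_extend
        return a

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.ka_k * m * n * math.exp(-self.ka_lambda * score)


@dataclass(frozen=True)
class Run:
    """One gapless aligned run: query[qstart:qend] <-> target[tstart:tend]."""

    qstart: int
    qend: int
    tstart: int
    tend: int

    def __post_init__(self):
        assert self.qend - self.qstart == self.tend - self.tstart


@dataclass
class ChainedAlignment:
    """Co-linear gapless runs on one target region, possibly spliced."""

    runs: list[Run]
    score: float
    matches: int
    query_columns: int  # query bases covered by runs

    @property
    def identity(self) -> float:
        return self.matches / self.query_columns if self.query_columns else 0.0

    @property
    def qstart(self) -> int:
        return self.runs[0].qstart

    @property
    def qend(self) -> int:
        return self.runs[-1].qend

    @property
    def tstart(self) -> int:
        return self.runs[0].tstart

    @property
    def tend(self) -> int:
        return self.runs[-1].tend


def _count_matches(query: str, target: str, runs: list[Run]) -> int:
    m = 0
    for r in runs:
        m += sum(
            1
            for a, b in zip(query[r.qstart : r.qend], target[r.tstart : r.tend])
            if a == b
        )
    return m


def local_align(query: str, target: str, scoring: Scoring | None = None):
    """Best affine-gap local alignment as (runs, score); None if score <= 0."""
    scoring = scoring or Scoring()
    if not query or not target:
        return None
    aligner = scoring.aligner()
    try:
        aln = aligner.align(query, target)[0]
    except IndexError:
        return None
    if aln.score <= 0:
        return None
    runs = [
        Run(int(q0), int(q1), int(t0), int(t1))
        for (q0, q1), (t0, t1) in zip(aln.aligned[0], aln.aligned[1])
    ]
    return runs, float(aln.score)


def chained_local_align(
    query: str,
    target: str,
    scoring: Scoring | None = None,
    max_splice_gap: int = 5000,
    max_query_gap: int = 10,
    min_segment_score: float = 10.0,
    max_segments: int = 8,
) -> ChainedAlignment | None:
    """Chain co-linear local alignments across large target-side gaps.

    Local segments are collected by repeated best-local-alignment with
    query masking, then the highest-scoring co-linear chain is selected
    (query and target both advancing between segments, query gap
    <= ``max_query_gap``, target gap <= ``max_splice_gap``).  The chain
    score sums segment scores; the spliced gap itself is annotated, not
    scored, mirroring how a spliced aligner treats introns.  Boundary
    wobble around large gaps is refined to the maximum-match split.
    """
    scoring = scoring or Scoring()
    masked = list(query)
    segments: list[tuple[list[Run], float]] = []
    for _ in range(max_segments):
        res = local_align("".join(masked), target, scoring)
        if res is None or res[1] < min_segment_score:
            break
        runs, score = res
        segments.append((runs, score))
        for r in runs:
            for i in range(r.qstart, r.qend):
                masked[i] = "x"
    if not segments:
        return None

    # co-linear DP chaining over segments ordered by query start
    segments.sort(key=lambda s: s[0][0].qstart)
    n = len(segments)
    best_val = [s[1] for s in segments]
    prev_idx = [-1] * n
    for j in range(n):
        sj = segments[j][0]
        for i in range(j):
            si = segments[i][0]
            qgap = sj[0].qstart - si[-1].qend
            tgap = sj[0].tstart - si[-1].tend
            if qgap < 0 or qgap > max_query_gap:
                continue
            if tgap < 0 or tgap > max_splice_gap:
                continue
            cand = best_val[i] + segments[j][1]
            if cand > best_val[j]:
                best_val[j] = cand
                prev_idx[j] = i
    jbest = max(range(n), key=lambda j: best_val[j])
    chain_idx = []
    while jbest != -1:
        chain_idx.append(jbest)
        jbest = prev_idx[jbest]
    chain_idx.reverse()

    all_runs = [r for j in chain_idx for r in segments[j][0]]
    all_runs = _refine_splice_boundaries(query, target, all_runs)
    qcols = sum(r.qend - r.qstart for r in all_runs)
    return ChainedAlignment(
        runs=all_runs,
        score=_rescore(query, target, all_runs, scoring),
        matches=_count_matches(query, target, all_runs),
        query_columns=qcols,
    )


_SPLICE_MIN = 20  # target-gap excess at/above which boundaries are refined


def _refine_splice_boundaries(
    query: str, target: str, runs: list[Run]
) -> list[Run]:
    """Re-split query bases around large target gaps to maximise matches.

    A local aligner extends noisily into an intron, which wobbles the
    junction by a few bases; for every adjacent run pair with a large
    target-side gap, the combined query span is re-partitioned into a
    gapless left piece (anchored at the left run's target start) and a
    gapless right piece (anchored at the right run's target end) at the
    split with the most matches (ties: rightmost split).
    """
    runs = [r for r in runs if r.qend > r.qstart]
    for _ in range(20):  # bounded restarts; converges in a couple of passes
        refined = False
        for i in range(len(runs) - 1):
            a, b = runs[i], runs[i + 1]
            tgap = b.tstart - a.tend
            qgap = b.qstart - a.qend
            if qgap < 0 or tgap - qgap < _SPLICE_MIN:
                continue
            q0, q1 = a.qstart, b.qend
            t0, t1 = a.tstart, b.tend
            span = q1 - q0
            if t1 - span < t0:  # not enough target room for a clean split
                continue
            best_l, best_m = 0, -1
            for l in range(span + 1):
                m = sum(
                    1 for j in range(l) if query[q0 + j] == target[t0 + j]
                ) + sum(
                    1
                    for j in range(span - l)
                    if query[q0 + l + j] == target[t1 - (span - l) + j]
                )
                if m >= best_m:
                    best_m, best_l = m, l
            new_a = Run(q0, q0 + best_l, t0, t0 + best_l)
            new_b = Run(q0 + best_l, q1, t1 - (span - best_l), t1)
            if (new_a, new_b) == (a, b):
                continue
            pieces = [p for p in (new_a, new_b) if p.qend > p.qstart]
            runs = runs[:i] + pieces + runs[i + 2 :]
            refined = True
            break
        if not refined:
            break
    # merge runs that became contiguous
    merged: list[Run] = []
    for r in runs:
        if merged and merged[-1].qend == r.qstart and merged[-1].tend == r.tstart:
            merged[-1] = Run(merged[-1].qstart, r.qend, merged[-1].tstart, r.tend)
        else:
            merged.append(r)
    return merged


def _rescore(query: str, target: str, runs: list[Run], scoring: Scoring) -> float:
    """Chain score: per-run match/mismatch plus affine costs for small gaps;
    splice-classified target gaps are annotated, not scored."""
    score = 0.0
    prev: Run | None = None
    for r in runs:
        for a, b in zip(query[r.qstart : r.qend], target[r.tstart : r.tend]):
            score += scoring.match if a == b else scoring.mismatch
        if prev is not None:
            qgap = r.qstart - prev.qend
            tgap = r.tstart - prev.tend
            if qgap > 0:
                score += scoring.gap_open + scoring.gap_extend * qgap
            if 0 < tgap - qgap < _SPLICE_MIN:
                score += scoring.gap_open + scoring.gap_extend * tgap
        prev = r
    return score


# ---------------------------------------------------------------------------
# seeding


def seed_windows(
    query: str,
    target: str,
    k: int = 12,
    band: int = 60,
    min_seeds: int = 1,
    merge_gap: int = 600,
) -> list[tuple[int, int]]:
    """Candidate target windows from exact k-mer seed diagonals.

    Seed clusters closer than ``len(query) + merge_gap`` merge into one
    window, so a locus hit through a moderate intron still yields a single
    window covering both exon-side seed clusters.
    """
    if len(query) < k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        index.setdefault(query[i : i + k], []).append(i)
    tpos: list[int] = []
    for j in range(len(target) - k + 1):
        if target[j : j + k] in index:
            tpos.append(j)
    if len(tpos) < min_seeds:
        return []
    windows: list[tuple[int, int]] = []
    gap_merge = len(query) + merge_gap
    start = prev = tpos[0]
    for p in tpos[1:]:
        if p - prev > gap_merge:
            windows.append((start, prev + k))
            start = p
        prev = p
    windows.append((start, prev + k))
    # pad each window by the query length so local alignment can extend
    pad = len(query) + band
    return [(max(0, s - pad), min(len(target), e + pad)) for s, e in windows]
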