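"""Endpoint genotype calling, failure-mode modelling, and Null correction.

Three QC layers around a KASP assay:

* :func:`call_genotypes` turns two-channel endpoint fluorescence into
  AA/AB/BB calls by 1-D clustering on the normalised coordinate
  theta = red / (green + red); low-magnitude points (relative to the
  no-template controls) become ``missing`` — a KASP pipeline never emits a
  "Null" allele.
* :func:`simulate_failure_mode` reproduces the known wrong-clustering
  mechanisms — a common primer binding a second locus, preferential
  amplification of one allele after a 3'-terminal mismatch, a 5' deletion
  under the common primer, or allelic product-size differences — as
  per-allele efficiency factors and predicts which cluster each true
  genotype lands in.
* :func:`collapse_null_haplotypes` merges array haplotype rows containing
  "Null" calls into the unique Null-free haplotype matching at every
  non-Null position, recomputes frequencies, and flags artifacts: the
  correction that removes spurious low-frequency haplotypes from
  array-derived haploblock tables.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans


class TooFewPoints(ValueError):
    code = "TOO_FEW_POINTS"


class DegenerateClusters(ValueError):
    code = "DEGENERATE_CLUSTERS"


@dataclass(frozen=True)
class FluorescencePoint:
    sample_id: str
    x: float  # green-channel endpoint intensity
    y: float  # red-channel endpoint intensity
    is_ntc: bool = False

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("non-finite intensity")
        if self.x < 0 or self.y < 0:
            raise ValueError("negative intensity")

    @property
    def magnitude(self) -> float:
        return self.x + self.y

    @property
    def theta(self) -> float:
        return self.y / (self.x + self.y)


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    call: str  # AA / AB / BB / missing
    cluster_index: int | None
    confidence: float


def call_genotypes(
    points: list[FluorescencePoint],
    expected_thetas: list[float] | None = None,
    k: int = 3,
    seed: int = 0,
    ntc_sigma_factor: float = 3.0,
) -> list[GenotypeCall]:
    """Cluster endpoint signals on theta and label AA/AB/BB by theta order.

    NTC wells are never genotyped.  Points with magnitude below the NTC
    centroid plus ``ntc_sigma_factor`` NTC spreads are ``missing``.  The
    remaining points are clustered with seeded k-means (k from the
    expected layout when given); clusters are labelled in ascending theta
    (green-dominant first).  Confidence is the relative margin between the
    nearest and second-nearest centroid.
    """
    ntc = [p for p in points if p.is_ntc]
    data = [p for p in points if not p.is_ntc]
    if expected_thetas is not None:
        k = len(expected_thetas)
    if len(data) < k and expected_thetas is None:
        raise TooFewPoints(f"{len(data)} informative points for k={k}")

    if ntc:
        mags = np.array([p.magnitude for p in ntc])
        floor = float(mags.mean() + ntc_sigma_factor * (mags.std() if len(ntc) > 1 else 0.05 * mags.mean()))
    else:
        floor = 0.0

    calls: list[GenotypeCall] = []
    informative = [p for p in data if p.magnitude > floor]
    dropped = [p for p in data if p.magnitude <= floor]

    if expected_thetas is not None and len(informative) < k:
        centroids = np.array(sorted(expected_thetas))
    elif informative:
        thetas = np.array([[p.theta] for p in informative])
        km = KMeans(n_clusters=min(k, len(informative)), n_init=10,
                    random_state=seed)
        km.fit(thetas)
        centroids = np.sort(km.cluster_centers_.ravel())
    else:
        centroids = np.array([])

    if centroids.size >= 2 and np.min(np.diff(centroids)) < 1e-3:
        raise DegenerateClusters(
            f"cluster centroids collapse: {np.round(centroids, 4).tolist()}"
        )
    labels = ["AA", "AB", "BB"] if centroids.size == 3 else [
        f"C{i}" for i in range(centroids.size)
    ]
    if centroids.size == 2:
        labels = ["AA", "BB"]

    for p in informative:
        d = np.abs(centroids - p.theta)
        order = np.argsort(d)
        ci = int(order[0])
        if centroids.size > 1:
            margin = float(d[order[1]] - d[order[0]])
            gap = float(d[order[1]] + d[order[0]]) or 1.0
            conf = margin / gap
        else:
            conf = 1.0
        calls.append(GenotypeCall(p.sample_id, labels[ci], ci, conf))
    for p in dropped:
        calls.append(GenotypeCall(p.sample_id, "missing", None, 0.0))
    for p in ntc:
        calls.append(GenotypeCall(p.sample_id, "missing", None, 0.0))
    order = {p.sample_id: i for i, p in enumerate(points)}
    calls.sort(key=lambda c: order[c.sample_id])
    return calls


# ---------------------------------------------------------------------------
# failure-mode amplification model


@dataclass(frozen=True)
class AlleleTemplate:
    """Per-allele template descriptor under the designed primers."""

    common_3p_mismatches: int = 0  # under the common primer's 3'-terminal bases
    deletion_5p: int = 0  # bp deleted at the common primer's 5' overhang
    amplicon_len: int = 0


@dataclass
class AmplificationScenario:
    allele_a: AlleleTemplate
    allele_b: AlleleTemplate
    # constant off-target signal (green, red) from a common primer binding a
    # second locus (the hemi-SNP failure mode); zero for a specific assay
    offtarget_signal: tuple[float, float] = (0.0, 0.0)
    w3: float = 2.0
    wd: float = 3.0
    ws: float = 1.0

    def efficiency(self, tmpl: AlleleTemplate, other: AlleleTemplate) -> float:
        """Relative amplification factor in (0, 1]; equal templates map to 1
        when symmetric.  Purely a qualitative mechanism for the direction
        and size of cluster displacement, not a kinetic model.
        """
        dlen = abs(tmpl.amplicon_len - other.amplicon_len)
        longer = tmpl.amplicon_len >= other.amplicon_len
        size_term = self.ws * max(dlen - 10, 0) / 50 if longer and dlen else 0.0
        return math.exp(
            -(
                self.w3 * tmpl.common_3p_mismatches
                + self.wd * min(tmpl.deletion_5p, 20) / 20
                + size_term
            )
        )


@dataclass(frozen=True)
class DisplacedPoint:
    genotype: str
    x: float
    y: float
    predicted_call: str

    @property
    def theta(self) -> float:
        return self.y / (self.x + self.y)


def simulate_failure_mode(
    scenario: AmplificationScenario,
    allele_thetas: tuple[float, float] = (0.0, 1.0),
    scale: float = 1.0,
) -> list[DisplacedPoint]:
    """Predicted positions and calls of AA/AB/BB under a failure scenario.

    Allele signals are scaled by the scenario's efficiency factors; the
    off-target term adds constant signal to every sample.  A genotype is
    predicted to be mis-called when its displaced theta falls inside
    another cluster's assignment radius (half the undistorted
    inter-centroid gap).
    """
    th_a, th_b = allele_thetas
    f_a = scenario.efficiency(scenario.allele_a, scenario.allele_b)
    f_b = scenario.efficiency(scenario.allele_b, scenario.allele_a)
    base = {
        "AA": (2 * f_a, 0.0),
        "AB": (f_a, f_b),
        "BB": (0.0, 2 * f_b),
    }

    def to_xy(wa: float, wb: float) -> tuple[float, float]:
        # allele A contributes at theta th_a, allele B at th_b
        x = scale * (wa * (1 - th_a) + wb * (1 - th_b)) + scenario.offtarget_signal[0]
        y = scale * (wa * th_a + wb * th_b) + scenario.offtarget_signal[1]
        return x, y

    undistorted = {
        "AA": (2 * (1 - th_a) * scale + 0, 2 * th_a * scale),
        "AB": ((1 - th_a) * scale + (1 - th_b) * scale, th_a * scale + th_b * scale),
        "BB": (2 * (1 - th_b) * scale, 2 * th_b * scale),
    }
    cents = {
        g: y / (x + y) if (x + y) else 0.0 for g, (x, y) in undistorted.items()
    }
    out = []
    for g, (wa, wb) in base.items():
        x, y = to_xy(wa, wb)
        theta = y / (x + y) if x + y else 0.0
        call = g
        for other, c in cents.items():
            if other == g:
                continue
            gap = abs(c - cents[g]) or 1.0
            if abs(theta - c) <= gap / 2 and abs(theta - c) < abs(theta - cents[g]):
                call = other
        out.append(DisplacedPoint(genotype=g, x=x, y=y, predicted_call=call))
    return out


# ---------------------------------------------------------------------------
# Null-allele haplotype collapse


NULL = "Null"


@dataclass
class HaplotypeRow:
    name: str
    alleles: tuple[str, ...]  # tokens in {A, C, G, T, Null}
    count: int
    frequency: float = 0.0  # percent
    merged_from: tuple[str, ...] = ()
    needs_sequencing: bool = False
    ambiguous_matches: tuple[str, ...] = ()

    @property
    def has_null(self) -> bool:
        return NULL in self.alleles

    def matches_at_non_null(self, other: "HaplotypeRow") -> bool:
        return all(
            a == b for a, b in zip(self.alleles, other.alleles) if a != NULL
        )


@dataclass
class HaplotypeTable:
    block_id: str
    probe_ids: tuple[str, ...]
    rows: list[HaplotypeRow]
    n: int = 0

    def __post_init__(self):
        for r in self.rows:
            if len(r.alleles) != len(self.probe_ids):
                raise ValueError(
                    f"row {r.name}: {len(r.alleles)} alleles for "
                    f"{len(self.probe_ids)} probes"
                )
        if not self.n:
            self.n = sum(r.count for r in self.rows)
        self.recompute_frequencies()

    @classmethod
    def from_frequencies(
        cls, block_id: str, probe_ids, rows: list[tuple[str, str | tuple, float]],
        n: int,
    ) -> "HaplotypeTable":
        """Reconstruct integer counts from printed percentages at panel size n
        (nearest integer)."""
        hrows = []
        for name, alleles, pct in rows:
            toks = _tokens(alleles)
            hrows.append(
                HaplotypeRow(name=name, alleles=toks,
                             count=int(round(pct * n / 100.0)))
            )
        return cls(block_id=block_id, probe_ids=tuple(probe_ids), rows=hrows, n=n)

    def recompute_frequencies(self) -> None:
        total = sum(r.count for r in self.rows)
        for r in self.rows:
            r.frequency = round(100.0 * r.count / total, 1) if total else 0.0

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.rows)


def _tokens(alleles) -> tuple[str, ...]:
    if isinstance(alleles, str):
        # single-character tokens; '-' or '0' denote Null
        return tuple(NULL if c in "-0N" else c.upper() for c in alleles)
    return tuple(NULL if a in ("-", "0", "N", NULL) else str(a).upper() for a in alleles)


def collapse_null_haplotypes(table: HaplotypeTable) -> HaplotypeTable:
    """Merge Null-containing rows into their unique Null-free match.

    Every row with >= 1 Null merges into the single Null-free row agreeing
    at all non-Null positions (counts added).  Rows matching no Null-free
    row are retained and flagged ``needs_sequencing``; rows matching two or
    more are retained with the ambiguity recorded.  Null-free rows are
    always retained, regardless of frequency.  Idempotent, and conserves
    the total count exactly.
    """
    clean = [r for r in table.rows if not r.has_null]
    merged: dict[str, HaplotypeRow] = {
        r.name: replace(r, merged_from=(), ambiguous_matches=())
        for r in clean
    }
    retained: list[HaplotypeRow] = []
    for row in table.rows:
        if not row.has_null:
            continue
        matches = [c for c in clean if row.matches_at_non_null(c)]
        if len(matches) == 1:
            tgt = merged[matches[0].name]
            tgt.count += row.count
            tgt.merged_from = tgt.merged_from + (row.name,)
        elif not matches:
            retained.append(replace(row, needs_sequencing=True))
        else:
            retained.append(
                replace(row, ambiguous_matches=tuple(m.name for m in matches))
            )
    out_rows = [merged[r.name] for r in clean] + retained
    out = HaplotypeTable(
        block_id=table.block_id, probe_ids=table.probe_ids,
        rows=out_rows, n=table.n,
    )
    return out


@dataclass
class ArtifactSummary:
    low_frequency_rows: int
    low_frequency_with_null: int
    low_frequency_surviving: int
    ambiguous_collapses: int
    rows_needing_sequencing: int


def artifact_report(
    table: HaplotypeTable, threshold: float = 5.0
) -> ArtifactSummary:
    """Low-frequency (< threshold %, strict) haplotype accounting.

    A low-frequency row *survives* when the collapse keeps it as a
    distinct haplotype (it is Null-free, or has no unique Null-free
    match) rather than merging it away.
    """
    corrected = collapse_null_haplotypes(table)
    surviving_names = {r.name for r in corrected.rows}
    low = [r for r in table.rows if r.frequency < threshold]
    with_null = [r for r in low if r.has_null]
    surviving = [r for r in low if r.name in surviving_names]
    return ArtifactSummary(
        low_frequency_rows=len(low),
        low_frequency_with_null=len(with_null),
        low_frequency_surviving=len(surviving),
        ambiguous_collapses=sum(
            1 for r in corrected.rows if r.ambiguous_matches
        ),
        rows_needing_sequencing=sum(
            1 for r in corrected.rows if r.needs_sequencing
        ),
    )


# ---------------------------------------------------------------------------
# file interfaces


def read_signals_csv(path) -> dict[str, list[FluorescencePoint]]:
    """CSV with columns sample_id, assay_id, x, y, is_ntc -> points per assay."""
    out: dict[str, list[FluorescencePoint]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["assay_id"], []).append(
                FluorescencePoint(
                    sample_id=row["sample_id"],
                    x=float(row["x"]),
                    y=float(row["y"]),
                    is_ntc=row.get("is_ntc", "0").strip().lower()
                    in ("1", "true", "yes"),
                )
            )
    return out


def write_calls_tsv(calls: dict[str, list[GenotypeCall]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sample_id", "assay_id", "call", "confidence"])
        for assay_id, cl in calls.items():
            for c in cl:
                w.writerow([c.sample_id, assay_id, c.call, f"{c.confidence:.3f}"])


def read_haplotype_tsv(path, block_id: str = "block", n: int | None = None) -> HaplotypeTable:
    """TSV: haplotype name column, one column per probe, count or frequency."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        value_col = "count" if "count" in cols else "frequency"
        probe_cols = [
            c for c in cols
            if c not in ("haplotype", "count", "frequency", "merged_from", "flags")
        ]
        raw = list(reader)
    if value_col == "count":
        rows = [
            HaplotypeRow(
                name=r["haplotype"],
                alleles=_tokens([r[c] for c in probe_cols]),
                count=int(r["count"]),
            )
            for r in raw
        ]
        return HaplotypeTable(block_id=block_id, probe_ids=tuple(probe_cols), rows=rows)
    if n is None:
        raise ValueError("panel size n required to reconstruct counts from frequencies")
    freq_rows = [
        (r["haplotype"], [r[c] for c in probe_cols], float(r["frequency"]))
        for r in raw
    ]
    return HaplotypeTable.from_frequencies(block_id, probe_cols, freq_rows, n)


def write_haplotype_tsv(table: HaplotypeTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["haplotype", *table.probe_ids, "count", "frequency",
                    "merged_from", "flags"])
        for r in table.rows:
            flags = []
            if r.needs_sequencing:
                flags.append("needs_sequencing")
            if r.ambiguous_matches:
                flags.append("AMBIGUOUS_COLLAPSE:" + "|".join(r.ambiguous_matches))
            w.writerow(
                [r.name, *r.alleles, r.count, f"{r.frequency:.1f}",
                 "|".join(r.merged_from), ";".join(flags)]
            )
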