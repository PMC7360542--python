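"""End-to-end convenience: probe record -> profile -> designed assay."""

from __future__ import annotations

from .align import Scoring
from .mapping import GenomeAssembly, HomeologProfile, build_profile, search_homeologs
from .primers import KaspAssay, PrimerParams, design_assay, FailureReason
from .probes import DecodedProbe, ProbeRecord, decode_probe


def profile_probe(
    record: ProbeRecord | DecodedProbe,
    assemblies: list[GenomeAssembly],
    min_identity: float = 0.80,
    max_evalue: float = 1e-5,
    scoring: Scoring | None = None,
    pad: int = 150,
    min_gap: int = 30,
) -> tuple[DecodedProbe, HomeologProfile | None]:
    """Decode, search all assemblies, and build the homeolog profile.

    Returns ``(decoded, None)`` when no hit passes the retention filters.
    """
    decoded = record if isinstance(record, DecodedProbe) else decode_probe(record)
    hits = search_homeologs(
        decoded.design_context,
        assemblies,
        min_identity=min_identity,
        max_evalue=max_evalue,
        scoring=scoring,
        snp_query_pos=decoded.snp_index,
    )
    if not hits:
        return decoded, None
    profile = build_profile(
        decoded, hits, assemblies, pad=pad, min_gap=min_gap, scoring=scoring
    )
    return decoded, profile


def design_for_probe(
    record: ProbeRecord | DecodedProbe,
    assemblies: list[GenomeAssembly],
    params: PrimerParams | None = None,
    **profile_kwargs,
) -> KaspAssay:
    decoded, profile = profile_probe(record, assemblies, **profile_kwargs)
    if profile is None:
        assay = KaspAssay(
            assay_id=f"kasp_{decoded.probe_id}", probe_id=decoded.probe_id
        )
        assay.failure_reason = FailureReason.NO_UNIQUE_SITE
        return assay
    return design_assay(decoded, profile, params)
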