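"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (plain dynamic
programming, exhaustive enumeration, naive scans) and deliberately shares
no code with the package internals it checks.
"""

from __future__ import annotations

GAP_OPEN = 2.0  # a gap of length L costs GAP_OPEN + L * GAP_EXT
GAP_EXT = 0.5
MATCH = 1.0
MISMATCH = -1.0


def smith_waterman_score(query: str, target: str) -> float:
    """Best local affine-gap alignment score, full O(nm) Gotoh DP."""
    n, m = len(query), len(target)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                H[i][j - 1] - GAP_OPEN - GAP_EXT, E[i][j - 1] - GAP_EXT
            )
            F[i][j] = max(
                H[i - 1][j] - GAP_OPEN - GAP_EXT, F[i - 1][j] - GAP_EXT
            )
            s = MATCH if query[i - 1] == target[j - 1] else MISMATCH
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


CHANNEL_OF = {"A": "green", "T": "green", "C": "red", "G": "red"}


def count_signals(flat: str) -> tuple[int, int]:
    """(green, red) equivalents by explicit per-character counting."""
    g = r = 0
    for c in flat:
        if CHANNEL_OF[c] == "green":
            g += 1
        else:
            r += 1
    return g, r


def layout_by_enumeration(compositions: list[str]) -> dict[tuple[int, int], list[str]]:
    """Cluster map from brute-force counting of each composition string."""
    clusters: dict[tuple[int, int], list[str]] = {}
    for flat in compositions:
        pt = count_signals(flat)
        clusters.setdefault(pt, []).append(flat)
    return clusters


def scan_placements(primer: str, seq: str, max_mm: int) -> list[tuple[int, int]]:
    """Naive character-by-character scan: all (offset, mismatches)."""
    L = len(primer)
    out = []
    for off in range(len(seq) - L + 1):
        mm = sum(1 for a, b in zip(primer, seq[off : off + L]) if a != b)
        if mm <= max_mm:
            out.append((off, mm))
    return out


def low_frequency_scan(rows, threshold: float = 5.0):
    """(n_low, n_low_with_null) by a plain row scan.

    ``rows`` is a list of (alleles tuple, frequency) pairs.
    """
    low = [(a, f) for a, f in rows if f < threshold]
    with_null = [(a, f) for a, f in low if "Null" in a]
    return len(low), len(with_null)
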