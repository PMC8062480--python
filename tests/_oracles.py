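"""Independent brute-force oracles used to cross-check the implementation.

Kept deliberately simple and separate from the package: plain-Python dynamic
programming with dictionaries and loops, no numba, no shared code paths.
"""

from __future__ import annotations


def brute_force_sw(seq_a: str, seq_b: str, score, gap_open: int = 11,
                   gap_extend: int = 1) -> int:
    """Best local affine-gap alignment score; gap of length k costs open+k*ext.

    ``score(a, b)`` gives the substitution score of two residue characters.
    """
    la, lb = len(seq_a), len(seq_b)
    NEG = float("-inf")
    H = [[0.0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          F[i][j - 1] - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + score(seq_a[i - 1], seq_b[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return int(best)


def compose_position_maps(*maps: dict) -> dict:
    """Compose per-position maps left to right, dropping unmapped positions."""
    if not maps:
        return {}
    out = dict(maps[0])
    for m in maps[1:]:
        out = {k: m[v] for k, v in out.items() if v in m}
    return out
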