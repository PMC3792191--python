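"""Independent brute-force reference implementations for small test cases.

Everything here is written in plain Python loops over explicit pair
enumerations, deliberately sharing no code path with the package's
vectorized implementation.
"""

from __future__ import annotations

import math

ORACLE_ALPHABET = "ACDEFGHIKLMNPQRSTVWYZ"


def brute_pair_index(first: str, second: str) -> int:
    """1-based row-major rank of an ordered pair over the 21-letter alphabet."""
    return ORACLE_ALPHABET.index(first) * 21 + ORACLE_ALPHABET.index(second) + 1


def brute_pair_frequencies(windows: list[str], gap: int) -> list[list[float]]:
    """441 x n_subsites frequency table by triple loop over pairs and subsites."""
    length = len(windows[0])
    n_sub = length - gap - 1
    table = [[0.0] * n_sub for _ in range(441)]
    for j in range(n_sub):  # subsite, 0-based
        for i in range(441):  # pair rank, 0-based
            first = ORACLE_ALPHABET[i // 21]
            second = ORACLE_ALPHABET[i % 21]
            count = sum(
                1 for w in windows if w[j] == first and w[j + gap + 1] == second
            )
            table[i][j] = count / len(windows)
    return table


def brute_psdp(windows_pos: list[str], windows_neg: list[str], gap: int) -> list[list[float]]:
    fp = brute_pair_frequencies(windows_pos, gap)
    fn = brute_pair_frequencies(windows_neg, gap)
    return [[a - b for a, b in zip(ra, rb)] for ra, rb in zip(fp, fn)]


def brute_encode(window: str, z0: list[list[float]], z1: list[list[float]]) -> list[float]:
    """Feature vector: gap-0 entries at subsites 1..L-1 then gap-1 at 1..L-2."""
    length = len(window)
    psi = []
    for u in range(length - 1):
        psi.append(z0[brute_pair_index(window[u], window[u + 1]) - 1][u])
    for u in range(length - 2):
        psi.append(z1[brute_pair_index(window[u], window[u + 2]) - 1][u])
    return psi


def brute_norm(vectors: list[list[float]]) -> list[float]:
    return [sum(col) / len(vectors) for col in zip(*vectors)]


def brute_distance(a: list[float], b: list[float]) -> float:
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def brute_predict(window: str, pos: list[str], neg: list[str]) -> tuple[str, float, float]:
    """Train-and-classify one query entirely through the brute-force path."""
    z0 = brute_psdp(pos, neg, 0)
    z1 = brute_psdp(pos, neg, 1)
    psi = brute_encode(window, z0, z1)
    norm_pos = brute_norm([brute_encode(w, z0, z1) for w in pos])
    norm_neg = brute_norm([brute_encode(w, z0, z1) for w in neg])
    d_pos = brute_distance(psi, norm_pos)
    d_neg = brute_distance(psi, norm_neg)
    label = "SNO" if d_pos < d_neg else "non-SNO"
    return label, d_pos, d_neg
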