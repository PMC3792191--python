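"""Position-specific dipeptide propensity (PSDP) encoding.

For a window of length ``L`` (21 by default) there are ``L-1`` starting
positions ("subsites") for adjacent residue pairs (gap 0) and ``L-2`` for
pairs separated by one residue (gap 1).  For each class of training windows
we tally, per subsite, the occurrence frequency of each of the 441 ordered
pairs; the PSDP matrix is the positive-class frequency minus the
negative-class frequency, so each entry lies in [-1, 1] and measures how
much more often a pair occupies a subsite among true SNO contexts.

A window is encoded by reading, for every subsite, the PSDP entry of the
pair it actually carries there: L-1 gap-0 components followed by L-2 gap-1
components, a 39-dimensional pairwise-coupling vector at the default
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DimensionMismatchError, EmptyDatasetError, IncompatibleMatricesError
from .windows import N_PAIRS, N_RESIDUES, PeptideWindow, pair_label, windows_to_codes


def _pair_codes(codes: np.ndarray, gap: int) -> np.ndarray:
    """0-based pair index at every subsite of every window.

    ``codes`` is (n, L); the result is (n, L - gap - 1) with entries in
    0..440: row-major rank of (R_j, R_{j+gap+1}).
    """
    step = gap + 1
    return codes[:, : codes.shape[1] - step] * N_RESIDUES + codes[:, step:]


@dataclass
class PairFrequencyMatrix:
    """Per-subsite occurrence frequencies of the 441 ordered pairs.

    ``values[i, j]`` is the fraction of tallied windows whose pair starting at
    subsite ``j+1`` has 1-based pair index ``i+1``.  Raw counts are retained
    so exact rational recomputation is possible.
    """

    gap: int
    values: np.ndarray  # (441, n_subsites) float64
    counts: np.ndarray  # (441, n_subsites) int64
    n_samples: int

    @property
    def n_subsites(self) -> int:
        return self.values.shape[1]


@dataclass
class PSDPMatrix:
    """Positive-minus-negative pair frequencies: 441 rows, one column per subsite."""

    gap: int
    values: np.ndarray  # (441, n_subsites) float64, entries in [-1, 1]

    @property
    def n_subsites(self) -> int:
        return self.values.shape[1]

    def to_tsv(self) -> str:
        """Serialize as TSV: row label = 2-letter pair, one column per subsite."""
        header = "pair\t" + "\t".join(
            f"subsite_{j + 1}" for j in range(self.n_subsites)
        )
        lines = [header]
        for i in range(N_PAIRS):
            row = "\t".join(repr(float(v)) for v in self.values[i])
            lines.append(f"{pair_label(i + 1)}\t{row}")
        return "\n".join(lines) + "\n"


@dataclass
class FeatureVector:
    """The pairwise-coupling representation of one window."""

    components: np.ndarray  # (omega,) float64

    @property
    def omega(self) -> int:
        return self.components.shape[0]


def pair_frequencies(
    windows: Sequence[PeptideWindow] | np.ndarray,
    gap: int,
    smoothing: float = 0.0,
) -> PairFrequencyMatrix:
    """Tally per-subsite pair frequencies over a set of windows.

    ``windows`` may be a list of :class:`PeptideWindow` or a pre-built
    (n, L) integer code matrix.  ``smoothing`` adds the given pseudocount to
    every (pair, subsite) cell before normalizing (default 0: unseen pairs
    have frequency exactly 0).
    """
    if gap not in (0, 1):
        raise IncompatibleMatricesError(f"gap must be 0 or 1, got {gap}")
    codes = windows if isinstance(windows, np.ndarray) else windows_to_codes(windows)
    if codes.shape[0] == 0:
        raise EmptyDatasetError("pair frequencies are undefined for an empty window set")
    n, length = codes.shape
    pairs = _pair_codes(codes, gap)
    n_sub = pairs.shape[1]
    counts = np.zeros((N_PAIRS, n_sub), dtype=np.int64)
    cols = np.broadcast_to(np.arange(n_sub), pairs.shape)
    np.add.at(counts, (pairs.ravel(), cols.ravel()), 1)
    if smoothing:
        values = (counts + smoothing) / (n + smoothing * N_PAIRS)
    else:
        values = counts / n
    return PairFrequencyMatrix(gap=gap, values=values, counts=counts, n_samples=n)


def psdp(freq_pos: PairFrequencyMatrix, freq_neg: PairFrequencyMatrix) -> PSDPMatrix:
    """Propensity matrix: elementwise positive minus negative frequency."""
    if freq_pos.gap != freq_neg.gap or freq_pos.values.shape != freq_neg.values.shape:
        raise IncompatibleMatricesError(
            f"incompatible matrices: gaps {freq_pos.gap}/{freq_neg.gap}, "
            f"shapes {freq_pos.values.shape}/{freq_neg.values.shape}"
        )
    return PSDPMatrix(gap=freq_pos.gap, values=freq_pos.values - freq_neg.values)


def encode_codes(codes: np.ndarray, z0: PSDPMatrix, z1: PSDPMatrix) -> np.ndarray:
    """Vectorized encoding of an (n, L) code matrix into (n, omega) features."""
    if z0.gap != 0 or z1.gap != 1:
        raise IncompatibleMatricesError("expected a gap-0 and a gap-1 PSDP matrix")
    length = codes.shape[1]
    if z0.n_subsites != length - 1 or z1.n_subsites != length - 2:
        raise DimensionMismatchError(
            f"window length {length} does not match PSDP subsite counts "
            f"({z0.n_subsites}, {z1.n_subsites})"
        )
    p0 = _pair_codes(codes, 0)
    p1 = _pair_codes(codes, 1)
    psi0 = z0.values[p0, np.arange(p0.shape[1])]
    psi1 = z1.values[p1, np.arange(p1.shape[1])]
    return np.concatenate([psi0, psi1], axis=1)


def encode(window: PeptideWindow, z0: PSDPMatrix, z1: PSDPMatrix) -> FeatureVector:
    """Encode one window against trained PSDP matrices.

    Component u (1-based) is the z0 entry at (pair index of R_u R_{u+1},
    subsite u) for u <= L-1, then the z1 entry at (pair index of
    R_{u'} R_{u'+2}, subsite u') with u' = u - (L-1) for the remaining L-2
    components.
    """
    codes = window.codes()[None, :]
    return FeatureVector(components=encode_codes(codes, z0, z1)[0])
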