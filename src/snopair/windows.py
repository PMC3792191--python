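"""Residue and pair alphabets, and cysteine-centered peptide windows.

A candidate S-nitrosylation site is a cysteine together with its local
sequence context.  The context is captured as a fixed-length window of
``2*xi + 1`` residues centered on the cysteine (``xi = 10`` by default, so
21-mers).  Positions that fall outside the parent protein are filled with the
dummy pad residue ``Z``, which is treated as a 21st alphabet member
throughout: residues are ranked alphabetically A..Y = 1..20 and Z = 21, and
ordered residue pairs are ranked row-major, AA = 1, AC = 2, ..., ZY = 440,
ZZ = 441.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ConfigError,
    InconsistentAnnotationError,
    InvalidResidueError,
    NotACysteineError,
    PositionOutOfRangeError,
)

#: The 20 native amino acids in alphabetic single-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Dummy pad residue standing in for positions beyond the protein termini.
PAD_SYMBOL = "Z"

#: Full 21-letter alphabet: amino acids ranked 1..20, pad ranked 21.
ALPHABET = AMINO_ACIDS + PAD_SYMBOL

#: Number of alphabet members (20 amino acids + pad).
N_RESIDUES = len(ALPHABET)

#: Number of ordered residue pairs (21 * 21).
N_PAIRS = N_RESIDUES * N_RESIDUES

#: IUPAC ambiguity/rare codes that may appear in real FASTA but have no rank.
AMBIGUOUS_RESIDUES = frozenset("BJOUX")

#: Class labels for a cysteine site.
SNO = "SNO"
NON_SNO = "non-SNO"
LABELS = (SNO, NON_SNO)

_RANK = {aa: i + 1 for i, aa in enumerate(ALPHABET)}


def index_residue(residue: str, context: str = "") -> int:
    """Rank of a residue in the 21-letter alphabet (1-based).

    'A' -> 1, 'C' -> 2, ..., 'Y' -> 20, 'Z' -> 21.  Raises
    :class:`InvalidResidueError` for anything else; ``context`` is appended to
    the message to locate the offending character.
    """
    try:
        return _RANK[residue]
    except KeyError:
        where = f" ({context})" if context else ""
        raise InvalidResidueError(
            f"invalid residue {residue!r}{where}: expected one of {ALPHABET}"
        ) from None


def index_pair(first: str, second: str) -> int:
    """Rank of an ordered residue pair, row-major over the alphabet (1-based).

    AA -> 1, AC -> 2, ..., ZY -> 440, ZZ -> 441.
    """
    return (index_residue(first) - 1) * N_RESIDUES + index_residue(second)


def pair_from_index(index: int) -> tuple[str, str]:
    """Inverse of :func:`index_pair`."""
    if not 1 <= index <= N_PAIRS:
        raise ValueError(f"pair index {index} outside 1..{N_PAIRS}")
    i, j = divmod(index - 1, N_RESIDUES)
    return ALPHABET[i], ALPHABET[j]


def pair_label(index: int) -> str:
    """Two-letter label of a pair index, e.g. 1 -> 'AA'."""
    return "".join(pair_from_index(index))


@dataclass(frozen=True)
class WindowConfig:
    """Geometry of the cysteine-centered window.

    Parameters
    ----------
    xi:
        Flank length in residues on each side of the cysteine.
    pad_symbol:
        Character used for positions beyond the protein termini; must not be
        one of the 20 native amino-acid letters.
    min_protein_length_warning:
        Proteins shorter than this are flagged as fragments at prediction
        time (a warning, not an error).
    """

    xi: int = 10
    pad_symbol: str = PAD_SYMBOL
    min_protein_length_warning: int = 50

    def __post_init__(self) -> None:
        if self.xi < 1:
            raise ConfigError(f"xi must be >= 1, got {self.xi}")
        if len(self.pad_symbol) != 1 or self.pad_symbol in AMINO_ACIDS:
            raise ConfigError(
                f"pad symbol {self.pad_symbol!r} must be a single character "
                "outside the 20 native amino-acid letters"
            )

    @property
    def window_length(self) -> int:
        return 2 * self.xi + 1

    @property
    def center_index(self) -> int:
        """1-based index of the central cysteine (xi + 1)."""
        return self.xi + 1

    def n_subsites(self, gap: int) -> int:
        """Number of pair starting positions for a given gap (0 or 1)."""
        if gap not in (0, 1):
            raise ConfigError(f"gap must be 0 or 1, got {gap}")
        return self.window_length - (gap + 2) + 1

    @property
    def omega(self) -> int:
        """Feature-vector dimension: gap-0 plus gap-1 subsites (39 at xi=10)."""
        return self.n_subsites(0) + self.n_subsites(1)


DEFAULT_CONFIG = WindowConfig()


def clean_sequence(sequence: str, map_ambiguous: bool = False, context: str = "") -> str:
    """Uppercase and validate a protein sequence.

    Non-standard letters (B, J, O, U, X) are rejected unless ``map_ambiguous``
    is set, in which case they are replaced by the pad symbol.  The pad symbol
    itself is never accepted inside a protein sequence.
    """
    seq = sequence.upper()
    if not seq:
        raise InvalidResidueError(f"empty sequence ({context})" if context else "empty sequence")
    out = []
    for pos, ch in enumerate(seq, start=1):
        if ch in AMINO_ACIDS:
            out.append(ch)
        elif ch in AMBIGUOUS_RESIDUES and map_ambiguous:
            out.append(PAD_SYMBOL)
        else:
            where = f"{context}, position {pos}" if context else f"position {pos}"
            hint = (
                "; pass map_ambiguous=True to replace B/J/O/U/X with the pad symbol"
                if ch in AMBIGUOUS_RESIDUES
                else ""
            )
            raise InvalidResidueError(f"invalid residue {ch!r} ({where}){hint}")
    return "".join(out)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession."""

    id: str
    sequence: str

    @classmethod
    def from_raw(cls, id: str, sequence: str, map_ambiguous: bool = False) -> "ProteinRecord":
        return cls(id=id, sequence=clean_sequence(sequence, map_ambiguous, context=f"protein {id}"))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """A labeled cysteine site: (protein accession, 1-based position, label)."""

    protein_id: str
    position: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ConfigError(f"unknown label {self.label!r}: expected one of {LABELS}")
        if self.position < 1:
            raise PositionOutOfRangeError(
                f"annotation position must be >= 1, got {self.position} "
                f"(protein {self.protein_id})"
            )


@dataclass(frozen=True)
class PeptideWindow:
    """A cysteine-centered window over the 21-letter alphabet.

    ``residues`` has odd length with 'C' at the center; provenance fields
    (parent protein, 1-based site position, class label) are optional.
    """

    residues: str
    protein_id: str | None = None
    site_position: int | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n < 3 or n % 2 == 0:
            raise ConfigError(f"window length must be odd and >= 3, got {n}")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in _RANK:
                raise InvalidResidueError(
                    f"invalid residue {ch!r} (window {self.residues!r}, position {pos})"
                )
        center = self.residues[n // 2]
        if center != "C":
            raise NotACysteineError(
                f"window center must be 'C', got {center!r} in {self.residues!r}"
            )
        if self.label is not None and self.label not in LABELS:
            raise ConfigError(f"unknown label {self.label!r}: expected one of {LABELS}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def center_index(self) -> int:
        """1-based index of the central cysteine."""
        return len(self.residues) // 2 + 1

    def codes(self) -> np.ndarray:
        """0-based integer codes of the residues (A=0 .. Z=20)."""
        return np.fromiter((_RANK[ch] - 1 for ch in self.residues), dtype=np.int64)


def windows_to_codes(windows: Sequence[PeptideWindow]) -> np.ndarray:
    """Stack windows into an (n, window_length) 0-based integer code matrix."""
    if not windows:
        return np.empty((0, 0), dtype=np.int64)
    return np.stack([w.codes() for w in windows])


def extract_window(
    protein: ProteinRecord, position: int, config: WindowConfig = DEFAULT_CONFIG
) -> PeptideWindow:
    """Extract the xi-flanked window around a cysteine of ``protein``.

    ``position`` is 1-based; positions outside the sequence contribute the pad
    symbol.  Raises if the position is out of range or not a cysteine.
    """
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        raise PositionOutOfRangeError(
            f"position {position} outside 1..{len(seq)} for protein {protein.id}"
        )
    if seq[position - 1] != "C":
        raise NotACysteineError(
            f"residue at position {position} of protein {protein.id} is "
            f"{seq[position - 1]!r}, not 'C'"
        )
    lo = position - 1 - config.xi
    hi = position - 1 + config.xi
    chars = [
        seq[i] if 0 <= i < len(seq) else config.pad_symbol for i in range(lo, hi + 1)
    ]
    return PeptideWindow(
        residues="".join(chars), protein_id=protein.id, site_position=position
    )


def enumerate_cysteine_windows(
    protein: ProteinRecord,
    annotations: Iterable[SiteAnnotation] | None = None,
    config: WindowConfig = DEFAULT_CONFIG,
) -> list[PeptideWindow]:
    """One labeled window per cysteine, in ascending position order.

    A cysteine is labeled SNO iff an annotation for this protein marks it SNO;
    every other cysteine is non-SNO.  Annotations pointing at non-cysteine
    residues raise :class:`InconsistentAnnotationError`.
    """
    sno_positions: set[int] = set()
    for ann in annotations or ():
        if ann.protein_id != protein.id:
            continue
        if ann.position > len(protein.sequence) or protein.sequence[ann.position - 1] != "C":
            residue = (
                protein.sequence[ann.position - 1]
                if ann.position <= len(protein.sequence)
                else "beyond sequence end"
            )
            raise InconsistentAnnotationError(
                f"annotation at position {ann.position} of protein {protein.id} "
                f"does not mark a cysteine ({residue!r})"
            )
        if ann.label == SNO:
            sno_positions.add(ann.position)
    out = []
    for pos0, ch in enumerate(protein.sequence):
        if ch != "C":
            continue
        position = pos0 + 1
        w = extract_window(protein, position, config)
        out.append(
            PeptideWindow(
                residues=w.residues,
                protein_id=protein.id,
                site_position=position,
                label=SNO if position in sno_positions else NON_SNO,
            )
        )
    return out
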