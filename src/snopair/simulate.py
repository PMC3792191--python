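"""Synthetic benchmark generator with a planted, position-specific signal.

Negative-class windows draw every non-center residue i.i.d. from a
background distribution over the 20 amino acids.  Positive-class windows
are identical except at a small set of biased positions flanking the
central cysteine, where a planted residue is emitted with probability
``effect_size + (1 - effect_size) * background(residue)``.  At
``effect_size = 0`` the two classes are exchangeable (a null dataset); at
``effect_size = 1`` the planted residues are deterministic and the classes
are separable.  Planting a marginal bias at single positions induces
class-dependent pair frequencies at every subsite overlapping a biased
position, exercising both the adjacent-pair and the next-nearest-pair
propensity pathways.

A protein mode emits whole sequences with multiple cysteines plus a site
annotation table, emulating whole-protein evaluation: each cysteine's
flanking context is drawn from the positive or negative window distribution
according to its label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .windows import (
    AMINO_ACIDS,
    NON_SNO,
    SNO,
    DEFAULT_CONFIG,
    PeptideWindow,
    ProteinRecord,
    SiteAnnotation,
    WindowConfig,
)

#: Approximate vertebrate proteome residue abundances (relative masses,
#: normalized internally), a realism preset for the background distribution.
NATURAL_ABUNDANCE = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.042,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}

DEFAULT_BIASED_POSITIONS = (8, 9, 12, 13)
DEFAULT_PLANTED_RESIDUES = {8: "L", 9: "K", 12: "D", 13: "F"}


@dataclass
class SyntheticConfig:
    """Settings for the planted-signal generator.

    ``biased_positions`` are 1-based window positions (never the center) and
    ``planted_residues`` maps each of them to the residue enriched in the
    positive class.  ``background`` maps the 20 amino acids to relative
    masses, normalized to probabilities (default uniform).
    """

    n_pos: int = 400
    n_neg: int = 400
    effect_size: float = 0.5
    biased_positions: tuple[int, ...] = DEFAULT_BIASED_POSITIONS
    planted_residues: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_RESIDUES)
    )
    background: dict[str, float] | None = None  # None = uniform
    seed: int = 0
    protein_mode: bool = False
    # protein-mode geometry
    n_proteins: int = 10
    sites_per_protein: int = 4
    sno_fraction: float = 0.4
    window_config: WindowConfig = field(default_factory=lambda: DEFAULT_CONFIG)

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_size <= 1.0:
            raise ConfigError(f"effect_size must be in [0, 1], got {self.effect_size}")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ConfigError("sample counts must be nonnegative")
        center = self.window_config.center_index
        for p in self.biased_positions:
            if p == center:
                raise ConfigError(f"biased position {p} is the center (always 'C')")
            if not 1 <= p <= self.window_config.window_length:
                raise ConfigError(
                    f"biased position {p} outside 1..{self.window_config.window_length}"
                )
            if p not in self.planted_residues:
                raise ConfigError(f"no planted residue given for biased position {p}")
        for pos, res in self.planted_residues.items():
            if res not in AMINO_ACIDS:
                raise ConfigError(f"planted residue {res!r} at position {pos} is not a native amino acid")
        if self.background is not None:
            missing = set(AMINO_ACIDS) - set(self.background)
            if missing or any(v < 0 for v in self.background.values()):
                raise ConfigError("background must assign a nonnegative mass to all 20 amino acids")
            if sum(self.background.values()) <= 0:
                raise ConfigError("background masses must have a positive sum")

    def background_vector(self) -> np.ndarray:
        """Background probabilities in alphabetic amino-acid order (normalized)."""
        if self.background is None:
            return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        v = np.asarray([self.background[a] for a in AMINO_ACIDS], dtype=float)
        return v / v.sum()


def _draw_windows(
    n: int, positive: bool, config: SyntheticConfig, rng: np.random.Generator
) -> list[PeptideWindow]:
    length = config.window_config.window_length
    center = config.window_config.center_index
    bg = config.background_vector()
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    if n == 0:
        return []
    chars = aa[rng.choice(len(aa), size=(n, length), p=bg)]
    chars[:, center - 1] = "C"
    if positive and config.effect_size > 0:
        for pos in config.biased_positions:
            hit = rng.random(n) < config.effect_size
            chars[hit, pos - 1] = config.planted_residues[pos]
    label = SNO if positive else NON_SNO
    return [PeptideWindow(residues="".join(row), label=label) for row in chars]


def generate_windows(
    config: SyntheticConfig,
) -> tuple[list[PeptideWindow], list[PeptideWindow]]:
    """Draw (positives, negatives), fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    positives = _draw_windows(config.n_pos, True, config, rng)
    negatives = _draw_windows(config.n_neg, False, config, rng)
    return positives, negatives


def generate_proteins(
    config: SyntheticConfig,
) -> tuple[list[ProteinRecord], list[SiteAnnotation]]:
    """Emit whole proteins with annotated cysteine sites.

    Each protein concatenates ``sites_per_protein`` window-length blocks, one
    cysteine per block; a ``sno_fraction`` of all sites (rounded down, at
    least one when any site exists) is SNO, with flanking context drawn from
    the positive window distribution and the rest from the negative one.
    """
    if not config.protein_mode:
        raise ConfigError("generate_proteins requires protein_mode=True")
    rng = np.random.default_rng(config.seed)
    length = config.window_config.window_length
    center = config.window_config.center_index
    n_sites_total = config.n_proteins * config.sites_per_protein
    n_sno = int(config.sno_fraction * n_sites_total)
    if n_sites_total and config.sno_fraction > 0:
        n_sno = max(n_sno, 1)
    is_sno = np.zeros(n_sites_total, dtype=bool)
    is_sno[rng.choice(n_sites_total, size=n_sno, replace=False)] = True
    proteins: list[ProteinRecord] = []
    annotations: list[SiteAnnotation] = []
    site_idx = 0
    for p in range(config.n_proteins):
        blocks = []
        pid = f"SYN{p + 1:04d}"
        for s in range(config.sites_per_protein):
            positive = bool(is_sno[site_idx])
            block = _draw_windows(1, positive, config, rng)[0].residues
            # interior blocks have full flanks, so no pad symbols are needed
            blocks.append(block)
            position = s * length + center
            annotations.append(
                SiteAnnotation(pid, position, SNO if positive else NON_SNO)
            )
            site_idx += 1
        proteins.append(ProteinRecord(id=pid, sequence="".join(blocks)))
    return proteins, annotations
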