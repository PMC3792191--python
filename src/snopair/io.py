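"""Readers/writers: FASTA, peptide tables, annotations, model files.

Peptide tables are TSV with columns ``protein_id  position  label  window``
(1-based positions, 21-mer windows, labels SNO / non-SNO); a permissive
reader also accepts the four columns positionally without a header.  Models
persist as a single versioned JSON document carrying the window geometry,
both PSDP matrices at full double precision, both class norms and the
training metadata; the round trip is bit-exact.

Also home to the window redundancy filter: a greedy first-kept pass that
removes any window sharing at least the threshold fraction of identical
positions with an already-kept window.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
from Bio import SeqIO

from .classifier import ClassNorms, Prediction, TrainedModel
from .encoding import PSDPMatrix
from .errors import ConfigError, ModelFormatError, PeptideTableError
from .windows import (
    LABELS,
    N_PAIRS,
    PAD_SYMBOL,
    PeptideWindow,
    ProteinRecord,
    SiteAnnotation,
    WindowConfig,
)

MODEL_FORMAT_VERSION = 1

TABLE_COLUMNS = ("protein_id", "position", "label", "window")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, map_ambiguous: bool = False) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into validated protein records.

    The ID is the first whitespace-delimited header token.  Non-standard
    letters raise unless ``map_ambiguous`` maps them to the pad symbol.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord.from_raw(rec.id, str(rec.seq), map_ambiguous))
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Peptide tables and annotations

def _parse_table_row(
    row: list[str], path: str, lineno: int
) -> PeptideWindow:
    if len(row) != 4:
        raise PeptideTableError(
            f"{path}:{lineno}: expected 4 columns {TABLE_COLUMNS}, got {len(row)}"
        )
    protein_id, pos_str, label, window = (c.strip() for c in row)
    try:
        position = int(pos_str)
    except ValueError:
        raise PeptideTableError(
            f"{path}:{lineno}: position {pos_str!r} is not an integer"
        ) from None
    if position < 1:
        raise PeptideTableError(f"{path}:{lineno}: position must be >= 1, got {position}")
    if label not in LABELS:
        raise PeptideTableError(
            f"{path}:{lineno}: unknown label {label!r}: expected one of {LABELS}"
        )
    try:
        return PeptideWindow(
            residues=window.upper(),
            protein_id=protein_id,
            site_position=position,
            label=label,
        )
    except Exception as exc:
        raise PeptideTableError(f"{path}:{lineno}: invalid window: {exc}") from exc


def read_peptide_table(
    path: str | Path, expected_length: int | None = 21
) -> list[PeptideWindow]:
    """Read a labeled peptide table (TSV, header optional).

    Malformed rows raise :class:`PeptideTableError` naming file and line.
    ``expected_length`` (default 21) additionally enforces the window length;
    pass None to accept any odd length.
    """
    path = str(path)
    windows: list[PeptideWindow] = []
    seen: set[tuple[str, int]] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and [c.strip().lower() for c in row] == list(TABLE_COLUMNS):
                continue
            w = _parse_table_row(row, path, lineno)
            if expected_length is not None and len(w) != expected_length:
                raise PeptideTableError(
                    f"{path}:{lineno}: window length {len(w)} != expected {expected_length}"
                )
            key = (w.protein_id, w.site_position)
            if key in seen:
                raise PeptideTableError(
                    f"{path}:{lineno}: duplicate (protein_id, position) {key}"
                )
            seen.add(key)
            windows.append(w)
    return windows


def write_peptide_table(windows: Sequence[PeptideWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for i, w in enumerate(windows, start=1):
            # synthesize provenance for bare windows so the row stays readable
            pid = w.protein_id if w.protein_id is not None else f"W{i:06d}"
            pos = w.site_position if w.site_position is not None else w.center_index
            fh.write(f"{pid}\t{pos}\t{w.label or 'non-SNO'}\t{w.residues}\n")


def split_by_label(windows: Sequence[PeptideWindow]) -> tuple[list[PeptideWindow], list[PeptideWindow]]:
    """Partition a labeled table into (SNO, non-SNO) lists."""
    pos = [w for w in windows if w.label == "SNO"]
    neg = [w for w in windows if w.label == "non-SNO"]
    return pos, neg


def read_annotations(path: str | Path) -> list[SiteAnnotation]:
    """Read a site-annotation TSV: protein_id, position (1-based), label."""
    path = str(path)
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            cells = [c.strip() for c in row]
            if lineno == 1 and cells[:3] == ["protein_id", "position", "label"]:
                continue
            if len(cells) < 3:
                raise PeptideTableError(f"{path}:{lineno}: expected 3 columns")
            try:
                position = int(cells[1])
            except ValueError:
                raise PeptideTableError(
                    f"{path}:{lineno}: position {cells[1]!r} is not an integer"
                ) from None
            try:
                out.append(SiteAnnotation(cells[0], position, cells[2]))
            except Exception as exc:
                raise PeptideTableError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_annotations(annotations: Sequence[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for a in annotations:
            fh.write(f"{a.protein_id}\t{a.position}\t{a.label}\n")


# ---------------------------------------------------------------------------
# Redundancy filter

def window_identity(a: PeptideWindow, b: PeptideWindow, count_pad: bool = True) -> float:
    """Fraction of positions with identical residues between two equal-length windows.

    With ``count_pad=False``, positions where both windows carry the pad
    symbol are excluded from numerator and denominator.
    """
    if len(a) != len(b):
        raise ConfigError(f"windows must have equal length ({len(a)} vs {len(b)})")
    if count_pad:
        same = sum(x == y for x, y in zip(a.residues, b.residues))
        return same / len(a)
    pairs = [
        (x, y)
        for x, y in zip(a.residues, b.residues)
        if not (x == PAD_SYMBOL and y == PAD_SYMBOL)
    ]
    if not pairs:
        return 1.0
    return sum(x == y for x, y in pairs) / len(pairs)


def redundancy_filter(
    windows: Sequence[PeptideWindow],
    threshold: float = 0.40,
    count_pad: bool = True,
) -> tuple[list[PeptideWindow], list[PeptideWindow]]:
    """Greedy winnowing of windows sharing >= threshold positional identity.

    Windows are visited in input order; one is removed iff its identity to
    any already-kept window reaches the threshold.  Deterministic for a fixed
    input order.  Returns (kept, removed).
    """
    if not 0 < threshold <= 1:
        raise ConfigError(f"threshold must be in (0, 1], got {threshold}")
    kept: list[PeptideWindow] = []
    removed: list[PeptideWindow] = []
    for w in windows:
        if any(window_identity(w, k, count_pad) >= threshold for k in kept):
            removed.append(w)
        else:
            kept.append(w)
    return kept, removed


# ---------------------------------------------------------------------------
# Model persistence

def _matrix_to_json(m: PSDPMatrix) -> dict:
    return {"gap": m.gap, "values": [[float(v) for v in row] for row in m.values]}


def _matrix_from_json(d: dict) -> PSDPMatrix:
    values = np.asarray(d["values"], dtype=float)
    if values.shape[0] != N_PAIRS:
        raise ModelFormatError(
            f"PSDP matrix must have {N_PAIRS} rows, got {values.shape[0]}"
        )
    return PSDPMatrix(gap=int(d["gap"]), values=values)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a trained model as versioned JSON (lossless double precision)."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": {
            "xi": model.config.xi,
            "pad_symbol": model.config.pad_symbol,
            "min_protein_length_warning": model.config.min_protein_length_warning,
        },
        "rule": model.rule,
        "z0": _matrix_to_json(model.z0),
        "z1": _matrix_to_json(model.z1),
        "norms": {
            "norm_pos": [float(v) for v in model.norms.norm_pos],
            "norm_neg": [float(v) for v in model.norms.norm_neg],
            "n_pos": model.norms.n_pos,
            "n_neg": model.norms.n_neg,
        },
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)
        fh.write("\n")


def load_model(path: str | Path) -> TrainedModel:
    """Load a model file, verifying format version and structure."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"corrupted model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or "format_version" not in doc:
        raise ModelFormatError(f"corrupted model file {path}: missing format_version")
    version = doc["format_version"]
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model file {path} has format version {version}; "
            f"this build reads version {MODEL_FORMAT_VERSION}"
        )
    try:
        cfg = WindowConfig(**doc["config"])
        norms = ClassNorms(
            norm_pos=np.asarray(doc["norms"]["norm_pos"], dtype=float),
            norm_neg=np.asarray(doc["norms"]["norm_neg"], dtype=float),
            n_pos=int(doc["norms"]["n_pos"]),
            n_neg=int(doc["norms"]["n_neg"]),
        )
        model = TrainedModel(
            config=cfg,
            z0=_matrix_from_json(doc["z0"]),
            z1=_matrix_from_json(doc["z1"]),
            norms=norms,
            rule=doc.get("rule", "nearest"),
            metadata=doc.get("metadata", {}),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"corrupted model file {path}: {exc}") from exc
    if model.z0.n_subsites != cfg.window_length - 1 or model.z1.n_subsites != cfg.window_length - 2:
        raise ModelFormatError(f"model file {path}: matrix shapes inconsistent with xi={cfg.xi}")
    if norms.omega != cfg.omega:
        raise ModelFormatError(f"model file {path}: norm dimension inconsistent with xi={cfg.xi}")
    return model


# ---------------------------------------------------------------------------
# Prediction output

PREDICTION_COLUMNS = ("protein_id", "position", "window", "d_pos", "d_neg", "label", "tie")


def write_predictions(predictions: Sequence[Prediction], fh: TextIO) -> None:
    """Write per-site predictions as TSV (1-based positions)."""
    fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
    for p in predictions:
        w = p.window
        fh.write(
            f"{w.protein_id or '.'}\t{w.site_position or 0}\t{w.residues}\t"
            f"{p.d_pos!r}\t{p.d_neg!r}\t{p.label}\t{int(p.tie)}\n"
        )
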