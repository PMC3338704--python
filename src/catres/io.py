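"""Readers and writers for every external file format.

Formats handled here:

* FASTA sequences (via Biopython);
* catalytic-site annotations: headerless TSV ``chain<TAB>pos<TAB>residue``
  with 1-based positions;
* the ASCII profile dialect with two 20-column blocks per residue row
  (log-odds scores then weighted observed percentages) — only the second
  block is kept, with columns remapped to the canonical alphabet order;
* PSIPRED ``.ss2`` vertical format (per-residue coil/helix/strand scores,
  stored internally in (H, E, C) order);
* per-residue TSVs for solvent accessibility (binarized at a threshold)
  and conservation scores;
* the versioned JSON model file.

All positions in files are 1-based; readers convert at this boundary.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .classifier import L1LogregModel
from .encoding import WindowLayout
from .errors import FormatError, UnsupportedVersionError, ValidationError
from .tables import AA_ORDER
from .types import (
    AnnotationSet,
    ChainTracks,
    ConsurfTrack,
    SecondaryStructureTrack,
    SequenceRecord,
    SolventAccessTrack,
    WopProfile,
)

__all__ = [
    "read_fasta", "write_fasta",
    "read_annotations", "write_annotations",
    "read_wop_pssm", "write_wop_pssm",
    "read_ss2", "write_ss2",
    "read_asa", "write_asa",
    "read_consurf", "write_consurf",
    "save_model", "load_model",
    "load_dataset_dir",
]

MODEL_FORMAT = "catres-model"
MODEL_VERSION = 1

#: Default binarization cut for real-valued relative-accessibility inputs.
ASA_THRESHOLD = 5.0


# --------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[SequenceRecord]:
    """Read sequences; the chain id is the first header token."""
    path = Path(path)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for entry {entry.id!r}")
        records.append(SequenceRecord(chain_id=entry.id, sequence=seq))
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    bio = [_BioRecord(Seq(r.sequence), id=r.chain_id, description="")
           for r in records]
    SeqIO.write(bio, str(path), "fasta")


# --------------------------------------------------------------------------
# Annotations

def read_annotations(path) -> AnnotationSet:
    """Read ``chain<TAB>pos<TAB>residue`` rows (1-based positions)."""
    path = Path(path)
    annots = AnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got "
                    f"{len(parts)}"
                )
            chain_id, pos_s, residue = parts
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: position {pos_s!r} is not an integer"
                ) from exc
            if pos < 1:
                raise ValidationError(
                    f"{path}:{lineno}: position must be >= 1, got {pos}"
                )
            annots.add(chain_id, pos, residue)
    return annots


def write_annotations(records: list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            for pos in sorted(rec.catalytic_positions):
                fh.write(f"{rec.chain_id}\t{pos}\t{rec.sequence[pos - 1]}\n")


# --------------------------------------------------------------------------
# Profile (WOP) files

def _is_aa_header(tokens: list[str]) -> bool:
    return (len(tokens) == 40
            and all(len(t) == 1 and t in AA_ORDER for t in tokens))


def read_wop_pssm(path, chain_id: str | None = None,
                  expect_length: int | None = None) -> WopProfile:
    """Parse the two-block ASCII profile; keep the percentage block.

    The column-header line gives the residue order of both 20-column
    blocks; the percentage (second) block is remapped to canonical order.
    """
    path = Path(path)
    order: list[str] | None = None
    rows: list[np.ndarray] = []
    expected_idx = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens:
                continue
            if order is None:
                if _is_aa_header(tokens):
                    order = tokens[20:40]
                continue
            if not tokens[0].isdigit():
                continue  # trailing footer (K, Lambda, ...)
            if len(tokens) < 42:
                raise FormatError(
                    f"{path}:{lineno}: expected residue row with at least 42 "
                    f"fields, got {len(tokens)}"
                )
            expected_idx += 1
            if int(tokens[0]) != expected_idx:
                raise FormatError(
                    f"{path}:{lineno}: residue index {tokens[0]} out of "
                    f"order (expected {expected_idx})"
                )
            try:
                values = np.array([float(t) for t in tokens[22:42]])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: unparseable percentage value"
                ) from exc
            rows.append(values)
    if order is None:
        raise FormatError(f"{path}: no amino-acid column header found")
    if not rows:
        raise FormatError(f"{path}: no residue rows found")
    wop = np.vstack(rows)
    # remap file column order -> canonical order
    perm = [order.index(a) for a in AA_ORDER]
    wop = wop[:, perm]
    if expect_length is not None and wop.shape[0] != expect_length:
        raise FormatError(
            f"{path}: profile has {wop.shape[0]} rows, expected "
            f"{expect_length}"
        )
    return WopProfile(chain_id=chain_id or path.stem, wop=wop)


def write_wop_pssm(profile: WopProfile, sequence: str, path,
                   column_order: str = AA_ORDER) -> None:
    """Write the two-block ASCII profile dialect.

    The log-odds block is emitted as zeros (it is ignored on read); the
    percentage block is written in ``column_order`` with full precision.
    """
    if len(sequence) != len(profile):
        raise ValidationError("sequence length != profile length")
    perm = [AA_ORDER.index(a) for a in column_order]
    with open(path, "w") as fh:
        fh.write("Last position-specific scoring matrix computed, weighted "
                 "observed percentages rounded down, information per "
                 "position, and relative weight of gapless real matches to "
                 "pseudocounts\n")
        header = " ".join(column_order) + "  " + " ".join(column_order)
        fh.write("          " + header + "\n")
        for i, aa in enumerate(sequence):
            logodds = " ".join("0" for _ in range(20))
            wop = " ".join(repr(float(v)) for v in profile.wop[i, perm])
            fh.write(f"{i + 1:>5} {aa} {logodds}  {wop}  0.00 0.00\n")
        fh.write("\n                      K         Lambda\n")


# --------------------------------------------------------------------------
# Secondary structure (.ss2)

def read_ss2(path, chain_id: str | None = None,
             expect_length: int | None = None) -> SecondaryStructureTrack:
    """Parse PSIPRED vertical format; file columns are (C, H, E)."""
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 fields "
                    "(idx residue state C H E), got "
                    f"{len(parts)}"
                )
            try:
                c, h, e = (float(parts[3]), float(parts[4]), float(parts[5]))
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric probability"
                ) from exc
            rows.append([h, e, c])  # store (H, E, C)
    if not rows:
        raise FormatError(f"{path}: no residue rows found")
    probs = np.array(rows)
    if expect_length is not None and probs.shape[0] != expect_length:
        raise ValidationError(
            f"{path}: {probs.shape[0]} rows, expected {expect_length}"
        )
    return SecondaryStructureTrack(chain_id=chain_id or path.stem, probs=probs)


def write_ss2(track: SecondaryStructureTrack, sequence: str, path) -> None:
    if len(sequence) != len(track):
        raise ValidationError("sequence length != SS track length")
    states = "HEC"
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT (catres synthetic)\n\n")
        for i, aa in enumerate(sequence):
            h, e, c = (float(x) for x in track.probs[i])
            state = states[int(np.argmax(track.probs[i]))]
            fh.write(f"{i + 1:>4} {aa} {state}  {c!r}  {h!r}  {e!r}\n")


# --------------------------------------------------------------------------
# Per-residue TSV tracks (ASA, conservation scores)

def _read_residue_tsv(path, n_fields: int = 3) -> tuple[list[str], np.ndarray]:
    path = Path(path)
    residues: list[str] = []
    values: list[float] = []
    expected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != n_fields:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_fields} tab-separated "
                    f"fields, got {len(parts)}"
                )
            expected += 1
            try:
                if int(parts[0]) != expected:
                    raise FormatError(
                        f"{path}:{lineno}: positions must be consecutive "
                        "from 1"
                    )
                values.append(float(parts[-1]))
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric field"
                ) from exc
            residues.append(parts[1])
    if not values:
        raise FormatError(f"{path}: no rows found")
    return residues, np.array(values)


def read_asa(path, chain_id: str | None = None,
             threshold: float = ASA_THRESHOLD,
             expect_length: int | None = None) -> SolventAccessTrack:
    """Read per-residue accessibility values, binarized at ``threshold``.

    Inputs already in {0, 1} pass through unchanged.
    """
    path = Path(path)
    _, values = _read_residue_tsv(path)
    if expect_length is not None and values.shape[0] != expect_length:
        raise ValidationError(
            f"{path}: {values.shape[0]} rows, expected {expect_length}"
        )
    if np.all(np.isin(values, (0.0, 1.0))):
        exposed = values.astype(int)
    else:
        exposed = (values >= threshold).astype(int)
    return SolventAccessTrack(chain_id=chain_id or path.stem, exposed=exposed)


def write_asa(values: np.ndarray, sequence: str, path) -> None:
    """Write per-residue accessibility values (real or already binary)."""
    if len(sequence) != len(values):
        raise ValidationError("sequence length != ASA track length")
    with open(path, "w") as fh:
        for i, aa in enumerate(sequence):
            fh.write(f"{i + 1}\t{aa}\t{float(values[i])!r}\n")


def read_consurf(path, chain_id: str | None = None,
                 expect_length: int | None = None) -> ConsurfTrack:
    """Read per-residue conservation scores, losslessly (no rescaling)."""
    path = Path(path)
    _, values = _read_residue_tsv(path)
    if expect_length is not None and values.shape[0] != expect_length:
        raise ValidationError(
            f"{path}: {values.shape[0]} rows, expected {expect_length}"
        )
    return ConsurfTrack(chain_id=chain_id or path.stem, scores=values)


def write_consurf(track: ConsurfTrack, sequence: str, path) -> None:
    if len(sequence) != len(track):
        raise ValidationError("sequence length != conservation track length")
    with open(path, "w") as fh:
        for i, aa in enumerate(sequence):
            fh.write(f"{i + 1}\t{aa}\t{float(track.scores[i])!r}\n")


# --------------------------------------------------------------------------
# Model serialization

def save_model(model: L1LogregModel, path) -> None:
    """Write the model as versioned JSON with full-precision decimals."""
    if not (np.all(np.isfinite(model.w)) and math.isfinite(model.v)):
        raise ValidationError("cannot serialize a non-finite model")
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "window_size": model.layout.window_size,
        "channels": list(model.layout.channels),
        "layout_fingerprint": model.layout.fingerprint(),
        "lambda": model.lam,
        "intercept": model.v,
        "threshold": model.threshold,
        "weights": [float(x) for x in model.w],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path) -> L1LogregModel:
    path = Path(path)
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not a valid model file ({exc})") from exc
    if payload.get("format") != MODEL_FORMAT:
        raise FormatError(f"{path}: not a {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_VERSION:
        raise UnsupportedVersionError(
            f"{path}: model format version {payload.get('version')!r} is not "
            f"supported (this build reads version {MODEL_VERSION})"
        )
    layout = WindowLayout(window_size=payload["window_size"],
                          channels=tuple(payload["channels"]))
    if payload.get("layout_fingerprint") != layout.fingerprint():
        raise FormatError(f"{path}: layout fingerprint mismatch")
    weights = np.array(payload["weights"], dtype=float)
    if weights.shape[0] != layout.dim:
        raise FormatError(
            f"{path}: {weights.shape[0]} weights for layout dimension "
            f"{layout.dim}"
        )
    return L1LogregModel(w=weights, v=float(payload["intercept"]),
                         lam=float(payload["lambda"]), layout=layout,
                         threshold=float(payload["threshold"]))


# --------------------------------------------------------------------------
# Dataset directories

def load_dataset_dir(path) -> tuple[list[SequenceRecord],
                                    dict[str, ChainTracks]]:
    """Load a dataset directory written by the synthetic generator.

    Expects a ``manifest.json`` naming the FASTA, the annotation file and
    the per-chain track files.  Returns labelled records and a bundle of
    tracks per chain; every track is validated against its sequence length.
    """
    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"{root}: no manifest.json found")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    records = read_fasta(root / manifest["files"]["fasta"])
    annots = read_annotations(root / manifest["files"]["annotations"])
    annots.attach(records)
    tracks: dict[str, ChainTracks] = {}
    for rec in records:
        entry = manifest["files"]["chains"].get(rec.chain_id)
        if entry is None:
            raise FormatError(
                f"{root}: manifest has no track files for chain "
                f"{rec.chain_id!r}"
            )
        L = len(rec)
        tracks[rec.chain_id] = ChainTracks(
            record=rec,
            profile=read_wop_pssm(root / entry["pssm"], rec.chain_id,
                                  expect_length=L),
            ss=read_ss2(root / entry["ss2"], rec.chain_id, expect_length=L),
            asa=read_asa(root / entry["asa"], rec.chain_id, expect_length=L),
            consurf=read_consurf(root / entry["consurf"], rec.chain_id,
                                 expect_length=L),
        )
    return records, tracks
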