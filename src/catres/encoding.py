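"""Per-residue feature channels and sliding-window classifier vectors.

Eight channels describe each residue:

====== ===== ==========================================================
name   width description
====== ===== ==========================================================
RT     20    one-hot residue type, canonical alphabet order
OP     10    Taylor's overlapping property classes (multi-hot)
ACH    10    averaged cumulative hydrophobicity, window sizes 3,5,...,21
SS     3     secondary-structure scores (H, E, C)
ASA    1     binary solvent exposure
JSD    1     Jensen-Shannon conservation score
VJSD   1     combined class/residue conservation score
Consurf 1    phylogenetic conservation score (min-max normalized)
====== ===== ==========================================================

A classifier vector for a residue is built from a window of half-width
``w`` around it.  RT, OP and ACH apply to the central residue only; the
remaining five channels contribute one block per offset -w..+w.  Offsets
falling outside the chain contribute all-zero blocks, so the total
dimension is fixed at ``40 + 7 * (2w + 1)`` with all channels enabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .tables import AA_INDEX, AA_THREE, CLASS_NAMES, SWEET_EISENBERG, TAYLOR_CLASSES
from .types import (
    ChainTracks,
    ConsurfTrack,
    SecondaryStructureTrack,
    SequenceRecord,
    SolventAccessTrack,
    WopProfile,
)
from .conservation import BackgroundModel, ConservationScores, normalize_track, score_chain

__all__ = [
    "CENTRAL_CHANNELS",
    "WINDOWED_CHANNELS",
    "CHANNEL_NAMES",
    "ACH_WINDOW_SIZES",
    "encode_rt",
    "encode_op",
    "ach_profile",
    "ResidueFeatureTable",
    "build_feature_table",
    "WindowLayout",
    "assemble_window",
    "WindowedDataset",
    "build_dataset",
]

#: Channels applied to the central residue only, with their widths.
CENTRAL_CHANNELS = (("RT", 20), ("OP", 10), ("ACH", 10))
#: Channels repeated at every window offset, with their per-offset widths.
WINDOWED_CHANNELS = (("SS", 3), ("ASA", 1), ("JSD", 1), ("VJSD", 1),
                     ("Consurf", 1))
CHANNEL_NAMES = tuple(n for n, _ in CENTRAL_CHANNELS + WINDOWED_CHANNELS)

#: The ten ACH window sizes.
ACH_WINDOW_SIZES = tuple(range(3, 22, 2))

_RT = {aa: np.eye(20)[i] for aa, i in AA_INDEX.items()}
_OP = {
    aa: np.array([1.0 if aa in members else 0.0
                  for _, members in TAYLOR_CLASSES])
    for aa in AA_INDEX
}
_ZERO20 = np.zeros(20)
_ZERO10 = np.zeros(10)


def encode_rt(residue: str) -> np.ndarray:
    """20-bit one-hot residue-type vector; all-zero for non-canonical letters."""
    return _RT.get(residue.upper(), _ZERO20).copy()


def encode_op(residue: str) -> np.ndarray:
    """10-bit overlapping-property vector; all-zero for non-canonical letters."""
    return _OP.get(residue.upper(), _ZERO10).copy()


def ach_profile(sequence: str) -> np.ndarray:
    """Averaged cumulative hydrophobicity, all ten window sizes, per residue.

    Column ``k`` holds the mean Sweet-Eisenberg index over the centered
    window of size ``2k + 3``; positions beyond the termini contribute 0
    to the sum while the divisor stays the full window size.
    """
    if not sequence:
        raise ValidationError("cannot compute hydrophobicity of empty sequence")
    h = np.array([SWEET_EISENBERG.get(c, 0.0) for c in sequence.upper()])
    L = h.shape[0]
    out = np.empty((L, 10))
    maxw = ACH_WINDOW_SIZES[-1]
    pad = np.concatenate([np.zeros(maxw), h, np.zeros(maxw)])
    csum = np.concatenate([[0.0], np.cumsum(pad)])
    idx = np.arange(L) + maxw  # position i in padded coordinates
    for k, w in enumerate(ACH_WINDOW_SIZES):
        half = (w - 1) // 2
        out[:, k] = (csum[idx + half + 1] - csum[idx - half]) / w
    return out


@dataclass
class ResidueFeatureTable:
    """All eight channels evaluated for every residue of one chain."""

    chain_id: str
    sequence: str
    rt: np.ndarray       # L x 20
    op: np.ndarray       # L x 10
    ach: np.ndarray      # L x 10
    ss: np.ndarray       # L x 3
    asa: np.ndarray      # L
    jsd: np.ndarray      # L
    vjsd: np.ndarray     # L
    consurf: np.ndarray  # L

    def __len__(self) -> int:
        return len(self.sequence)

    def channel(self, name: str) -> np.ndarray:
        """Return a channel as an L x width matrix."""
        arr = getattr(self, name.lower())
        return arr if arr.ndim == 2 else arr[:, None]


def build_feature_table(record: SequenceRecord,
                        profile: WopProfile,
                        ss: SecondaryStructureTrack,
                        asa: SolventAccessTrack,
                        consurf: ConsurfTrack,
                        cons_scores: ConservationScores | None = None,
                        background: BackgroundModel | None = None,
                        normalize_consurf: bool = True) -> ResidueFeatureTable:
    """Assemble the eight-channel feature table for one chain.

    ``cons_scores`` may be precomputed; otherwise they are derived from the
    profile.  The conservation-score channel from the external predictor is
    min-max normalized per chain by default so that its scale is comparable
    across chains.
    """
    L = len(record)
    for name, track in (("WOP", profile), ("SS", ss), ("ASA", asa),
                        ("Consurf", consurf)):
        if len(track) != L:
            raise ValidationError(
                f"chain {record.chain_id!r}: {name} track length {len(track)} "
                f"!= sequence length {L}"
            )
    if cons_scores is None:
        cons_scores = score_chain(profile, background)
    if cons_scores.jsd.shape[0] != L:
        raise ValidationError(
            f"chain {record.chain_id!r}: conservation scores length mismatch"
        )
    cons_channel = consurf.scores.astype(float)
    if normalize_consurf:
        cons_channel = normalize_track(cons_channel)
    return ResidueFeatureTable(
        chain_id=record.chain_id,
        sequence=record.sequence,
        rt=np.vstack([encode_rt(c) for c in record.sequence]),
        op=np.vstack([encode_op(c) for c in record.sequence]),
        ach=ach_profile(record.sequence),
        ss=ss.probs.astype(float),
        asa=asa.exposed.astype(float),
        jsd=cons_scores.jsd,
        vjsd=cons_scores.vjsd,
        consurf=cons_channel,
    )


def build_table_from_tracks(tracks: ChainTracks, **kwargs) -> ResidueFeatureTable:
    """Convenience: feature table straight from a ``ChainTracks`` bundle."""
    return build_feature_table(tracks.record, tracks.profile, tracks.ss,
                               tracks.asa, tracks.consurf, **kwargs)


@dataclass(frozen=True)
class WindowLayout:
    """Feature-vector layout for a given window half-width and channel set.

    With all eight channels the dimension is ``40 + 7 * (2w + 1)``.
    Dropping a channel removes its slots: 20 (RT), 10 (OP), 10 (ACH), or
    ``width * (2w + 1)`` for a windowed channel.
    """

    window_size: int
    channels: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        if self.window_size < 0:
            raise ValidationError("window_size must be >= 0")
        unknown = set(self.channels) - set(CHANNEL_NAMES)
        if unknown:
            raise ValidationError(f"unknown channels: {sorted(unknown)}")
        object.__setattr__(self, "channels", tuple(self.channels))

    @property
    def n_offsets(self) -> int:
        return 2 * self.window_size + 1

    @property
    def dim(self) -> int:
        d = sum(w for n, w in CENTRAL_CHANNELS if n in self.channels)
        d += self.n_offsets * sum(
            w for n, w in WINDOWED_CHANNELS if n in self.channels)
        return d

    def slot_names(self) -> list[str]:
        """Human-readable name per feature slot (e.g. SS-4-E, VJSD+0)."""
        names: list[str] = []
        if "RT" in self.channels:
            names += [f"RT-{t}" for t in AA_THREE]
        if "OP" in self.channels:
            names += [f"OP-{c}" for c in CLASS_NAMES]
        if "ACH" in self.channels:
            names += [f"ACH-Win{w}" for w in ACH_WINDOW_SIZES]
        w = self.window_size
        for delta in range(-w, w + 1):
            off = f"{delta:+d}"
            if "SS" in self.channels:
                names += [f"SS{off}-{s}" for s in "HEC"]
            if "ASA" in self.channels:
                names.append(f"ASA{off}")
            if "JSD" in self.channels:
                names.append(f"JSD{off}")
            if "VJSD" in self.channels:
                names.append(f"VJSD{off}")
            if "Consurf" in self.channels:
                names.append(f"Consurf{off}")
        return names

    def fingerprint(self) -> str:
        return f"w={self.window_size};channels={','.join(self.channels)}"


def assemble_window(table: ResidueFeatureTable, position: int,
                    layout: WindowLayout) -> np.ndarray:
    """Build the classifier vector for one residue (0-based position).

    Central channels come from the residue itself; windowed channels from
    offsets -w..+w with all-zero blocks where the window overhangs a
    terminus.
    """
    L = len(table)
    if not 0 <= position < L:
        raise ValidationError(f"position {position} outside 0..{L - 1}")
    parts: list[np.ndarray] = []
    if "RT" in layout.channels:
        parts.append(table.rt[position])
    if "OP" in layout.channels:
        parts.append(table.op[position])
    if "ACH" in layout.channels:
        parts.append(table.ach[position])
    w = layout.window_size
    windowed = [(n, wd, table.channel(n)) for n, wd in WINDOWED_CHANNELS
                if n in layout.channels]
    for delta in range(-w, w + 1):
        j = position + delta
        inside = 0 <= j < L
        for _, width, chan in windowed:
            parts.append(chan[j] if inside else np.zeros(width))
    return np.concatenate(parts) if parts else np.zeros(0)


@dataclass
class WindowedDataset:
    """Assembled training/evaluation matrix with chain grouping.

    ``y`` uses +1 for catalytic and -1 for background residues; ``groups``
    carries the chain id of each row for chain-aware cross-validation.
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    positions: np.ndarray  # 0-based residue index per row
    layout: WindowLayout

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValidationError("X and y row counts differ")
        if self.X.size and self.X.shape[1] != self.layout.dim:
            raise ValidationError(
                f"X has {self.X.shape[1]} columns, layout dimension is "
                f"{self.layout.dim}"
            )
        if self.y.size and not np.all(np.isin(self.y, (-1, 1))):
            raise ValidationError("labels must be +1 or -1")
        seen = set()
        for g, p in zip(self.groups, self.positions):
            if (g, p) in seen:
                raise ValidationError(f"duplicate row for chain {g!r} pos {p}")
            seen.add((g, p))

    def __len__(self) -> int:
        return self.X.shape[0]


def build_dataset(tables: dict[str, ResidueFeatureTable],
                  selected: list[tuple[str, int, int]],
                  layout: WindowLayout) -> WindowedDataset:
    """Assemble rows for ``selected`` = [(chain_id, 0-based pos, label)].

    Rows keep the given selection order; labels are +1/-1.
    """
    n = len(selected)
    X = np.empty((n, layout.dim))
    y = np.empty(n, dtype=int)
    groups = np.empty(n, dtype=object)
    positions = np.empty(n, dtype=int)
    for i, (chain_id, pos, label) in enumerate(selected):
        table = tables.get(chain_id)
        if table is None:
            raise ValidationError(f"unknown chain {chain_id!r} in selection")
        X[i] = assemble_window(table, pos, layout)
        y[i] = label
        groups[i] = chain_id
        positions[i] = pos
    return WindowedDataset(X=X, y=y, groups=groups, positions=positions,
                           layout=layout)


def export_sparse(dataset: WindowedDataset, matrix_path, layout_path) -> None:
    """Write the encoded matrix as (row, col, value) text plus a layout JSON."""
    import json

    with open(matrix_path, "w") as fh:
        fh.write("row\tcol\tvalue\n")
        rows, cols = np.nonzero(dataset.X)
        for r, c in zip(rows, cols):
            fh.write(f"{r}\t{c}\t{float(dataset.X[r, c])!r}\n")
    with open(layout_path, "w") as fh:
        json.dump(
            {
                "window_size": dataset.layout.window_size,
                "channels": list(dataset.layout.channels),
                "dim": dataset.layout.dim,
                "slot_names": dataset.layout.slot_names(),
                "labels": dataset.y.tolist(),
                "groups": [str(g) for g in dataset.groups],
                "positions": dataset.positions.tolist(),
            },
            fh, indent=1,
        )
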