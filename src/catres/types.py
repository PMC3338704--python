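"""In-memory domain types.

All file parsing lives in :mod:`catres.io`; downstream modules consume only
the types defined here.  Positions are 1-based in files and in
``SequenceRecord.catalytic_positions`` (mirroring catalytic-site annotation
conventions); everything else internal is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .tables import AA_ORDER

_CANONICAL = set(AA_ORDER)


@dataclass
class SequenceRecord:
    """One enzyme chain: sequence plus 1-based catalytic-site positions.

    Non-canonical letters (B, Z, X, U, O, ...) are kept in the sequence;
    encoders map them to all-zero bit vectors and hydrophobicity 0.
    """

    chain_id: str
    sequence: str
    catalytic_positions: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"chain {self.chain_id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        L = len(self.sequence)
        for p in self.catalytic_positions:
            if not 1 <= p <= L:
                raise ValidationError(
                    f"chain {self.chain_id!r}: catalytic position {p} outside "
                    f"1..{L}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def labels(self) -> np.ndarray:
        """Per-residue labels, +1 catalytic / -1 background (0-based index)."""
        y = -np.ones(len(self.sequence), dtype=int)
        for p in self.catalytic_positions:
            y[p - 1] = 1
        return y


def _check_track_length(chain_id: str, name: str, got: int,
                        expect: int | None) -> None:
    if expect is not None and got != expect:
        raise ValidationError(
            f"chain {chain_id!r}: {name} track has {got} rows, sequence has "
            f"{expect} residues"
        )


@dataclass
class WopProfile:
    """L x 20 weighted-observed-percentage matrix from a sequence profile.

    Columns follow the canonical alphabet order; rows follow the sequence.
    Values are on the 0-100 percentage scale as read; normalization to
    per-column distributions is the conservation module's job.
    """

    chain_id: str
    wop: np.ndarray

    def __post_init__(self) -> None:
        self.wop = np.asarray(self.wop, dtype=float)
        if self.wop.ndim != 2 or self.wop.shape[1] != 20:
            raise ValidationError(
                f"chain {self.chain_id!r}: WOP matrix must be L x 20, got "
                f"shape {self.wop.shape}"
            )
        if np.any(self.wop < 0) or not np.all(np.isfinite(self.wop)):
            raise ValidationError(
                f"chain {self.chain_id!r}: WOP entries must be finite and "
                "non-negative"
            )

    def __len__(self) -> int:
        return self.wop.shape[0]


@dataclass
class SecondaryStructureTrack:
    """Per-residue secondary-structure scores, columns (H, E, C)."""

    chain_id: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise ValidationError(
                f"chain {self.chain_id!r}: SS track must be L x 3"
            )
        if np.any(self.probs < 0) or not np.all(np.isfinite(self.probs)):
            raise ValidationError(
                f"chain {self.chain_id!r}: SS scores must be finite and >= 0"
            )

    def __len__(self) -> int:
        return self.probs.shape[0]


@dataclass
class SolventAccessTrack:
    """Per-residue binary solvent exposure (1 = exposed)."""

    chain_id: str
    exposed: np.ndarray

    def __post_init__(self) -> None:
        self.exposed = np.asarray(self.exposed)
        if self.exposed.ndim != 1:
            raise ValidationError(
                f"chain {self.chain_id!r}: ASA track must be 1-D"
            )
        if not np.all(np.isin(self.exposed, (0, 1))):
            raise ValidationError(
                f"chain {self.chain_id!r}: ASA values must be 0 or 1"
            )
        self.exposed = self.exposed.astype(int)

    def __len__(self) -> int:
        return self.exposed.shape[0]


@dataclass
class ConsurfTrack:
    """Per-residue evolutionary conservation scores (arbitrary real scale)."""

    chain_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValidationError(
                f"chain {self.chain_id!r}: conservation track must be 1-D"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError(
                f"chain {self.chain_id!r}: conservation scores must be finite"
            )

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class ChainTracks:
    """All per-chain input tracks bundled together."""

    record: SequenceRecord
    profile: WopProfile
    ss: SecondaryStructureTrack
    asa: SolventAccessTrack
    consurf: ConsurfTrack

    def __post_init__(self) -> None:
        L = len(self.record)
        cid = self.record.chain_id
        _check_track_length(cid, "WOP", len(self.profile), L)
        _check_track_length(cid, "SS", len(self.ss), L)
        _check_track_length(cid, "ASA", len(self.asa), L)
        _check_track_length(cid, "Consurf", len(self.consurf), L)


class AnnotationSet:
    """Catalytic-site labels: chain id -> {1-based position: residue letter}."""

    def __init__(self) -> None:
        self._by_chain: dict[str, dict[int, str]] = {}

    def add(self, chain_id: str, position: int, residue: str) -> None:
        sites = self._by_chain.setdefault(chain_id, {})
        if position in sites:
            raise ValidationError(
                f"duplicate annotation for chain {chain_id!r} position "
                f"{position}"
            )
        sites[position] = residue.upper()

    def chains(self) -> list[str]:
        return sorted(self._by_chain)

    def positions(self, chain_id: str) -> dict[int, str]:
        return dict(self._by_chain.get(chain_id, {}))

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chain.values())

    def attach(self, records: list[SequenceRecord]) -> list[str]:
        """Attach labels to records in place.

        Returns a list of human-readable mismatch reports for annotations
        whose stated residue letter disagrees with the sequence.  Positions
        outside the chain raise :class:`ValidationError`.
        """
        mismatches: list[str] = []
        by_id = {r.chain_id: r for r in records}
        for chain_id, sites in self._by_chain.items():
            rec = by_id.get(chain_id)
            if rec is None:
                continue
            for pos, letter in sites.items():
                if not 1 <= pos <= len(rec):
                    raise ValidationError(
                        f"annotation for chain {chain_id!r} position {pos} "
                        f"outside 1..{len(rec)}"
                    )
                actual = rec.sequence[pos - 1]
                if letter != actual:
                    mismatches.append(
                        f"chain {chain_id!r} position {pos}: annotation says "
                        f"{letter}, sequence has {actual}"
                    )
                rec.catalytic_positions.add(pos)
        return mismatches
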