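"""Synthetic enzyme-chain datasets with a planted catalytic signal.

The generator emulates the inputs the predictor consumes in production —
sequences, catalytic-site annotations, alignment-profile percentage
matrices, secondary-structure scores, solvent accessibility and an
external conservation track — with a tunable signal strength sigma in
[0, 1] controlling how strongly catalytic sites differ from background:

* background residues are drawn from the BLOSUM62 background
  distribution; catalytic residues come from the polar/charged pool with
  probability 1/2 + sigma/2;
* background profile columns get mild Dirichlet noise around the
  background (concentration 50); catalytic columns are drawn around
  ``(1 - sigma) * background + sigma * one_hot(residue)`` and are exactly
  one-hot at sigma = 1;
* catalytic sites have their coil probability mixed up by sigma, are
  exposed with probability 1/2 + sigma/2, and get a conservation score
  shifted by two standard deviations times sigma.

Per-channel toggles select which channels carry signal, and
``signal_offsets`` moves the track-channel signal to flanking positions —
useful for constructing fixtures where only a window of a given width can
see the signal.  Everything is driven by one mandatory seed; identical
seeds give byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io import (
    ASA_THRESHOLD,
    write_annotations,
    write_asa,
    write_consurf,
    write_fasta,
    write_ss2,
    write_wop_pssm,
)
from .tables import AA_INDEX, AA_ORDER, BLOSUM62_BACKGROUND, POLAR_OR_CHARGED
from .types import (
    ChainTracks,
    ConsurfTrack,
    SecondaryStructureTrack,
    SequenceRecord,
    SolventAccessTrack,
    WopProfile,
)

__all__ = ["SyntheticSpec", "SyntheticChain", "generate_chain",
           "generate_dataset", "write_dataset"]

#: Channels that can carry planted signal.
SIGNAL_CHANNELS = ("residue", "wop", "ss", "asa", "consurf")

# baseline secondary-structure propensities (H, E, C): mostly coil,
# helix next — roughly the composition of globular proteins
_SS_ALPHA = np.array([3.5, 2.0, 4.5])
_WOP_CONCENTRATION = 50.0
_BACKGROUND_EXPOSED = 0.45


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one generated dataset.

    Defaults give 50 chains of 60-120 residues with two catalytic sites
    each and signal strength 0.8 in every channel.
    """

    seed: int
    n_chains: int = 50
    length_range: tuple[int, int] = (60, 120)
    catalytic_per_chain: int = 2
    signal_strength: float = 0.8
    signal_channels: tuple[str, ...] = SIGNAL_CHANNELS
    signal_offsets: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if self.length_range[0] < 30:
            raise ValidationError("chain lengths must be >= 30")
        if self.length_range[0] > self.length_range[1]:
            raise ValidationError("length_range must be (min, max)")
        if self.catalytic_per_chain < 1:
            raise ValidationError("need at least one catalytic site per chain")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValidationError("signal_strength must lie in [0, 1]")
        unknown = set(self.signal_channels) - set(SIGNAL_CHANNELS)
        if unknown:
            raise ValidationError(f"unknown signal channels: {sorted(unknown)}")

    def as_dict(self) -> dict:
        return {
            "seed": self.seed, "n_chains": self.n_chains,
            "length_range": list(self.length_range),
            "catalytic_per_chain": self.catalytic_per_chain,
            "signal_strength": self.signal_strength,
            "signal_channels": list(self.signal_channels),
            "signal_offsets": list(self.signal_offsets),
        }


@dataclass
class SyntheticChain:
    """Generated tracks plus the raw (real-valued) accessibility values."""

    tracks: ChainTracks
    asa_raw: np.ndarray


def _signal_positions(catalytic0: set[int], offsets, L: int) -> set[int]:
    out = set()
    for p in catalytic0:
        for d in offsets:
            if 0 <= p + d < L:
                out.add(p + d)
    return out


def generate_chain(spec: SyntheticSpec, rng: np.random.Generator,
                   chain_id: str) -> SyntheticChain:
    """Generate one chain with all of its input tracks."""
    q = BLOSUM62_BACKGROUND
    sigma = spec.signal_strength
    on = set(spec.signal_channels)
    L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    if spec.catalytic_per_chain > L:
        raise ValidationError(
            f"cannot place {spec.catalytic_per_chain} catalytic sites on a "
            f"length-{L} chain"
        )
    catalytic0 = set(
        int(i) for i in
        rng.choice(L, size=spec.catalytic_per_chain, replace=False)
    )
    track_sites = _signal_positions(catalytic0, spec.signal_offsets, L)

    # sequence
    pc_mass = np.array([q[AA_INDEX[a]] for a in POLAR_OR_CHARGED])
    pc_mass = pc_mass / pc_mass.sum()
    letters = []
    for i in range(L):
        if (i in catalytic0 and "residue" in on
                and rng.random() < 0.5 + sigma / 2.0):
            letters.append(str(rng.choice(POLAR_OR_CHARGED, p=pc_mass)))
        else:
            letters.append(AA_ORDER[int(rng.choice(20, p=q))])
    sequence = "".join(letters)
    record = SequenceRecord(
        chain_id=chain_id, sequence=sequence,
        catalytic_positions={p + 1 for p in catalytic0},
    )

    # profile columns (percent scale)
    wop = np.empty((L, 20))
    for i in range(L):
        if i in catalytic0 and "wop" in on:
            one_hot = np.zeros(20)
            one_hot[AA_INDEX.get(sequence[i], 0)] = 1.0
            mean = (1.0 - sigma) * q + sigma * one_hot
            if sigma >= 1.0:
                wop[i] = 100.0 * one_hot
            else:
                wop[i] = 100.0 * rng.dirichlet(_WOP_CONCENTRATION * mean)
        else:
            wop[i] = 100.0 * rng.dirichlet(_WOP_CONCENTRATION * q)
    profile = WopProfile(chain_id=chain_id, wop=wop)

    # secondary structure (H, E, C)
    ss = rng.dirichlet(_SS_ALPHA, size=L)
    if "ss" in on:
        coil = np.array([0.0, 0.0, 1.0])
        for i in track_sites:
            ss[i] = (1.0 - sigma) * ss[i] + sigma * coil
    ss_track = SecondaryStructureTrack(chain_id=chain_id, probs=ss)

    # solvent accessibility: raw relative values, binarized at the default cut
    exposed = rng.random(L) < _BACKGROUND_EXPOSED
    if "asa" in on:
        for i in track_sites:
            exposed[i] = rng.random() < 0.5 + sigma / 2.0
    asa_raw = np.where(
        exposed,
        rng.uniform(ASA_THRESHOLD, 60.0, size=L),
        rng.uniform(0.0, ASA_THRESHOLD * 0.98, size=L),
    )
    asa_track = SolventAccessTrack(chain_id=chain_id,
                                   exposed=exposed.astype(int))

    # external conservation score: unit-normal background, shifted at sites
    cons = rng.normal(0.0, 1.0, size=L)
    if "consurf" in on:
        for i in track_sites:
            cons[i] += 2.0 * sigma
    cons_track = ConsurfTrack(chain_id=chain_id, scores=cons)

    return SyntheticChain(
        tracks=ChainTracks(record=record, profile=profile, ss=ss_track,
                           asa=asa_track, consurf=cons_track),
        asa_raw=asa_raw,
    )


def generate_dataset(spec: SyntheticSpec,
                     ) -> tuple[list[SequenceRecord], dict[str, ChainTracks]]:
    """Generate all chains in memory; chain ids are syn0001, syn0002, ..."""
    rng = np.random.default_rng(spec.seed)
    records = []
    tracks: dict[str, ChainTracks] = {}
    for i in range(spec.n_chains):
        chain = generate_chain(spec, rng, f"syn{i + 1:04d}")
        records.append(chain.tracks.record)
        tracks[chain.tracks.record.chain_id] = chain.tracks
    return records, tracks


def write_dataset(spec: SyntheticSpec, out_dir) -> dict:
    """Write a complete file-backed dataset; returns the manifest.

    Emits one FASTA, one annotation TSV, per-chain profile / ss2 / asa /
    conservation files and a ``manifest.json`` recording the spec and all
    paths.  Every file parses back through :mod:`catres.io`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    records = []
    chain_files: dict[str, dict[str, str]] = {}
    for i in range(spec.n_chains):
        chain = generate_chain(spec, rng, f"syn{i + 1:04d}")
        rec = chain.tracks.record
        records.append(rec)
        cid = rec.chain_id
        files = {
            "pssm": f"{cid}.pssm",
            "ss2": f"{cid}.ss2",
            "asa": f"{cid}.asa.tsv",
            "consurf": f"{cid}.consurf.tsv",
        }
        write_wop_pssm(chain.tracks.profile, rec.sequence, out / files["pssm"])
        write_ss2(chain.tracks.ss, rec.sequence, out / files["ss2"])
        write_asa(chain.asa_raw, rec.sequence, out / files["asa"])
        write_consurf(chain.tracks.consurf, rec.sequence,
                      out / files["consurf"])
        chain_files[cid] = files
    write_fasta(records, out / "chains.fasta")
    write_annotations(records, out / "annotations.tsv")
    manifest = {
        "format": "catres-dataset",
        "spec": spec.as_dict(),
        "files": {
            "fasta": "chains.fasta",
            "annotations": "annotations.tsv",
            "chains": chain_files,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def dataset_checksum(path) -> str:
    """SHA-256 over the manifest-listed files of a dataset directory.

    Covers the dataset artifact itself (manifest, FASTA, annotations and
    every per-chain track file); unrelated files such as run logs are
    ignored.
    """
    root = Path(path)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    names = ["manifest.json", manifest["files"]["fasta"],
             manifest["files"]["annotations"]]
    for entry in manifest["files"]["chains"].values():
        names.extend(entry.values())
    digest = hashlib.sha256()
    for name in sorted(names):
        digest.update(name.encode())
        digest.update((root / name).read_bytes())
    return digest.hexdigest()
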