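"""Profile-based conservation scores.

Three per-residue scores are computed from a chain's weighted-observed-
percentage (WOP) profile:

* **JSD** — Jensen-Shannon divergence between the profile column's
  amino-acid distribution ``p`` and the BLOSUM62 background ``q``,

  .. math::

     \\mathrm{JSD}(p, q) = \\lambda\\, D(p \\| r) + (1-\\lambda)\\, D(q \\| r),
     \\qquad r = \\lambda p + (1-\\lambda) q,

  with Kullback-Leibler divergence :math:`D` in bits (log base 2) and
  mixture weight :math:`\\lambda = 1/2`, which bounds the score in [0, 1].

* **RVD** — relative entropy over Taylor's ten overlapping property
  classes: :math:`\\sum_c P_c \\log_2 (P_c / Q_c)` where ``P_c`` is the
  column mass of class ``c`` and ``Q_c`` the background mass.  Because the
  classes overlap this is a sum of per-class relative-entropy terms, not a
  KL divergence over a partition, and it can exceed 1.

* **VJSD** — the arithmetic mean of the per-chain min-max-normalized RVD
  and JSD tracks, combining class-level and residue-level conservation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .tables import AA_INDEX, BLOSUM62_BACKGROUND, TAYLOR_CLASSES
from .types import WopProfile

__all__ = [
    "BackgroundModel",
    "ConservationScores",
    "default_background",
    "column_distribution",
    "jsd_score",
    "rvd_score",
    "normalize_track",
    "vjsd_score",
    "score_chain",
    "write_conservation_tsv",
]


@dataclass(frozen=True)
class BackgroundModel:
    """Amino-acid background distribution plus class-level background mass.

    ``q`` is a length-20 probability vector in canonical alphabet order;
    ``classes`` is the fixed ordered list of the ten overlapping property
    classes; ``class_mass`` holds :math:`Q_c = \\sum_{a \\in c} q_a`.
    """

    q: np.ndarray
    classes: tuple[tuple[str, frozenset], ...]
    class_mass: np.ndarray
    class_matrix: np.ndarray  # 10 x 20 binary membership, for vectorization

    def __post_init__(self) -> None:
        if abs(float(self.q.sum()) - 1.0) > 1e-12:
            raise ValidationError("background distribution must sum to 1")
        if np.any(self.q <= 0):
            raise ValidationError("background frequencies must be positive")
        if len(self.classes) != 10:
            raise ValidationError("expected exactly 10 property classes")


def default_background() -> BackgroundModel:
    """The BLOSUM62 background with Taylor's overlapping classes."""
    q = BLOSUM62_BACKGROUND.copy()
    member = np.zeros((10, 20))
    for ci, (_, members) in enumerate(TAYLOR_CLASSES):
        for aa in members:
            member[ci, AA_INDEX[aa]] = 1.0
    return BackgroundModel(
        q=q,
        classes=TAYLOR_CLASSES,
        class_mass=member @ q,
        class_matrix=member,
    )


def column_distribution(wop_row: np.ndarray,
                        background: BackgroundModel) -> np.ndarray:
    """Normalize one WOP row to a probability vector.

    An all-zero row carries no conservation evidence and falls back to the
    background distribution (its scores will be exactly 0).
    """
    row = np.asarray(wop_row, dtype=float)
    if row.shape != (20,):
        raise ValidationError(f"WOP row must have 20 entries, got {row.shape}")
    if np.any(row < 0):
        raise ValidationError("WOP row entries must be non-negative")
    total = row.sum()
    if total <= 0:
        return background.q.copy()
    return row / total


def _check_distribution(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (20,):
        raise ValidationError(f"{name} must have 20 entries")
    if np.any(p < 0):
        raise ValidationError(f"{name} has negative entries")
    if abs(float(p.sum()) - 1.0) > 1e-9:
        raise ValidationError(f"{name} does not sum to 1 (sum={p.sum()!r})")
    return p


def _kl_bits(a: np.ndarray, b: np.ndarray) -> float:
    # 0 * log 0 := 0; b > 0 wherever a > 0 holds for mixtures by construction
    mask = a > 0
    return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))


def jsd_score(p: np.ndarray, q: np.ndarray, lambda_mix: float = 0.5) -> float:
    """Jensen-Shannon divergence in bits between distributions p and q.

    For ``lambda_mix = 0.5`` and log base 2 the score lies in [0, 1], is
    symmetric, and is 0 iff ``p == q``.
    """
    p = _check_distribution(p, "p")
    q = _check_distribution(q, "q")
    if not 0.0 < lambda_mix < 1.0:
        raise ValidationError("lambda_mix must lie strictly in (0, 1)")
    r = lambda_mix * p + (1.0 - lambda_mix) * q
    return lambda_mix * _kl_bits(p, r) + (1.0 - lambda_mix) * _kl_bits(q, r)


def rvd_score(p: np.ndarray, background: BackgroundModel) -> float:
    """Class-level relative entropy of p against the background.

    Sums :math:`P_c \\log_2(P_c/Q_c)` over the ten overlapping property
    classes, with the convention :math:`0 \\log(0/Q) = 0`.
    """
    p = _check_distribution(p, "p")
    P = background.class_matrix @ p
    Q = background.class_mass
    mask = P > 0
    return float(np.sum(P[mask] * np.log2(P[mask] / Q[mask])))


def normalize_track(values: np.ndarray) -> np.ndarray:
    """Per-chain min-max normalization to [0, 1]; constant tracks map to 0."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot normalize an empty track")
    if not np.all(np.isfinite(x)):
        raise ValidationError("track contains non-finite values")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def vjsd_score(rvd_norm: float, jsd_norm: float) -> float:
    """Combine normalized class- and residue-level conservation (mean)."""
    for name, v in (("rvd_norm", rvd_norm), ("jsd_norm", jsd_norm)):
        if not -1e-9 <= v <= 1.0 + 1e-9:
            raise ValidationError(f"{name}={v!r} outside [0, 1]")
    return (rvd_norm + jsd_norm) / 2.0


@dataclass
class ConservationScores:
    """Per-residue conservation tracks for one chain."""

    chain_id: str
    jsd: np.ndarray
    rvd: np.ndarray
    jsd_norm: np.ndarray
    rvd_norm: np.ndarray
    vjsd: np.ndarray


def score_chain(profile: WopProfile,
                background: BackgroundModel | None = None,
                lambda_mix: float = 0.5) -> ConservationScores:
    """Compute JSD, RVD and VJSD for every residue of a chain."""
    bg = background if background is not None else default_background()
    L = len(profile)
    jsd = np.empty(L)
    rvd = np.empty(L)
    for i in range(L):
        p = column_distribution(profile.wop[i], bg)
        jsd[i] = jsd_score(p, bg.q, lambda_mix)
        rvd[i] = rvd_score(p, bg)
    jsd_norm = normalize_track(jsd)
    rvd_norm = normalize_track(rvd)
    vjsd = (rvd_norm + jsd_norm) / 2.0
    return ConservationScores(
        chain_id=profile.chain_id, jsd=jsd, rvd=rvd,
        jsd_norm=jsd_norm, rvd_norm=rvd_norm, vjsd=vjsd,
    )


def write_conservation_tsv(scores: ConservationScores, path) -> None:
    """Export per-position score tracks: chain, pos (1-based), jsd, rvd, vjsd."""
    with open(path, "w") as fh:
        fh.write("chain\tpos\tjsd\trvd\tvjsd\n")
        for i in range(scores.jsd.shape[0]):
            fh.write(
                f"{scores.chain_id}\t{i + 1}\t{float(scores.jsd[i])!r}\t"
                f"{float(scores.rvd[i])!r}\t{float(scores.vjsd[i])!r}\n"
            )
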