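"""Positional sequence entropy and per-extein conservation ranks.

Intein insertion sites tend to fall at conserved positions of their host
protein.  Conservation is scored from a position-specific scoring matrix
(PSSM): the Shannon entropy of the per-position amino-acid distribution,

    S_i = -sum_j p_ij ln p_ij,

is low where a single residue dominates (conserved) and reaches ln 20 for
the uniform distribution.  Each candidate C/S/T site is then ranked against
all other C/S/T candidates of the same extein: rank 1 is the most conserved
(lowest entropy) candidate, rank 0 the least conserved.  The natural
logarithm is used throughout; the base only rescales entropies and cannot
change any rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS
from .errors import InteinSiteError, UndefinedRankError

__all__ = [
    "PSSMatrix",
    "EntropyProfile",
    "site_entropy",
    "entropy_profile",
    "conservation_rank",
    "conservation_ranks",
]

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PSSMatrix:
    """Per-position amino-acid probabilities for one sequence.

    Parameters
    ----------
    probabilities
        Array of shape ``(n_positions, 20)``; row ``k`` is the probability
        distribution over :data:`~inteinsite.alphabet.AMINO_ACIDS` at
        sequence position ``positions[k]``.
    positions
        Matching 1-based sequence positions (defaults to ``1..n``).
    sequence
        Optional query-sequence residues, one per row.
    """

    probabilities: np.ndarray
    positions: tuple[int, ...] = ()
    sequence: str | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != len(AMINO_ACIDS):
            raise InteinSiteError(
                f"PSSM probability array must be (n, 20), got {probs.shape}"
            )
        object.__setattr__(self, "probabilities", probs)
        if not self.positions:
            object.__setattr__(
                self, "positions", tuple(range(1, probs.shape[0] + 1))
            )
        if len(self.positions) != probs.shape[0]:
            raise InteinSiteError("positions length must match row count")
        if np.any(probs < 0):
            raise InteinSiteError("PSSM probabilities must be non-negative")
        sums = probs.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > _ROW_SUM_TOL)
        if bad.size:
            raise InteinSiteError(
                f"PSSM row for position {self.positions[bad[0]]} sums to "
                f"{sums[bad[0]]:.12g}, not 1"
            )
        object.__setattr__(
            self,
            "_row_of",
            {pos: k for k, pos in enumerate(self.positions)},
        )

    _row_of: dict = field(default_factory=dict, repr=False, compare=False)

    def __len__(self) -> int:
        return self.probabilities.shape[0]

    def row(self, position: int) -> np.ndarray:
        """Probability vector at a 1-based sequence position."""
        try:
            return self.probabilities[self._row_of[position]]
        except KeyError:
            raise InteinSiteError(
                f"PSSM has no row for position {position}"
            ) from None


@dataclass(frozen=True)
class EntropyProfile:
    """Per-position sequence entropies ``S_i`` in nats."""

    S: np.ndarray
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        if S.shape != (len(self.positions),):
            raise InteinSiteError("entropy/position length mismatch")
        if np.any(S < -1e-12) or np.any(S > np.log(20.0) + 1e-9):
            raise InteinSiteError("entropies must lie in [0, ln 20]")
        object.__setattr__(
            self, "_row_of", {pos: k for k, pos in enumerate(self.positions)}
        )

    _row_of: dict = field(default_factory=dict, repr=False, compare=False)

    def at(self, position: int) -> float:
        try:
            return float(self.S[self._row_of[position]])
        except KeyError:
            raise InteinSiteError(
                f"no entropy for position {position}"
            ) from None


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0.0]
    return float(-(nz * np.log(nz)).sum())


def site_entropy(pssm: PSSMatrix, position: int) -> float:
    """Shannon entropy (nats) of the PSSM row at ``position``.

    ``0 * ln 0`` is taken as 0, so a one-hot row has entropy 0 and the
    uniform row entropy ``ln 20``.  The row must already be normalized;
    :class:`PSSMatrix` enforces this at construction, so no silent
    renormalization happens here.
    """
    return _entropy(pssm.row(position))


def entropy_profile(pssm: PSSMatrix) -> EntropyProfile:
    """Entropy of every PSSM row, as an :class:`EntropyProfile`."""
    p = pssm.probabilities
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0.0, p * np.log(np.where(p > 0.0, p, 1.0)), 0.0)
    return EntropyProfile(S=-terms.sum(axis=1), positions=pssm.positions)


def conservation_rank(
    entropies: EntropyProfile,
    candidates: Sequence,
    target: int,
) -> float:
    """Conservation rank in [0, 1] of ``target`` among candidate sites.

    The rank is the fraction of the other candidate C/S/T sites with
    strictly higher entropy, ties counted half::

        rank = (#higher + 0.5 * #tied) / (n_candidates - 1)

    so the unique lowest-entropy (most conserved) candidate gets 1 and the
    unique highest-entropy candidate gets 0.

    ``candidates`` may be :class:`~inteinsite.core_io.CandidateSite`
    objects or bare integer positions; ``target`` must be among them.
    """
    positions = [getattr(c, "position", c) for c in candidates]
    if positions.count(target) != 1:
        raise InteinSiteError(
            f"target position {target} must occur exactly once among candidates"
        )
    if len(positions) < 2:
        raise UndefinedRankError(
            "conservation rank is undefined with a single candidate site"
        )
    s_target = entropies.at(target)
    others = [entropies.at(p) for p in positions if p != target]
    higher = sum(1 for s in others if s > s_target)
    tied = sum(1 for s in others if s == s_target)
    return (higher + 0.5 * tied) / (len(positions) - 1)


def conservation_ranks(
    entropies: EntropyProfile, candidates: Sequence
) -> dict[int, float]:
    """Conservation rank of every candidate site, keyed by position."""
    positions = [getattr(c, "position", c) for c in candidates]
    return {
        p: conservation_rank(entropies, positions, p) for p in positions
    }


def write_conservation_tsv(
    path, entropies: EntropyProfile, ranks: dict[int, float] | None = None
) -> None:
    """Write a ``position<TAB>entropy<TAB>rank`` table (rank blank if n/a)."""
    ranks = ranks or {}
    with open(path, "w") as fh:
        fh.write("position\tentropy_nats\tconservation_rank\n")
        for pos in entropies.positions:
            r = ranks.get(pos)
            fh.write(
                f"{pos}\t{entropies.at(pos):.6f}\t"
                f"{'' if r is None else f'{r:.4f}'}\n"
            )
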