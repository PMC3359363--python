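"""Structure-derived features of candidate insertion sites.

Four structural quantities are computed per C/S/T site: the six-way
secondary-structure context (near a helix/loop or sheet/loop junction, in
the middle of a helix/sheet/loop, or other), the burial proxy of C-beta
contact density (neighbouring C-beta atoms within 8 A), the minimum
C-alpha distance to annotated functional residues (active site and/or
dimer interface), and the per-residue positional RMSD over trajectory
snapshots after rigid-body superposition onto the first snapshot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .core_io import SnapshotSet, StructureContext
from .errors import (
    AnnotationError,
    DegenerateGeometryError,
    InteinSiteError,
)

__all__ = [
    "SSContext",
    "FlexibilityResult",
    "group_ss_codes",
    "classify_site_ss",
    "cbeta_density",
    "distance_to_functional_site",
    "kabsch_superpose",
    "site_flexibility",
]

#: Stride/DSSP code -> coarse group.  H: helix; E: sheet; turns, bends and
#: coil (T, S, C) are loops; 3-10/pi helices and bridges (G, I, B, b) are
#: "other", as is any unrecognised code.
_SS_GROUP: dict[str, str] = {
    "H": "helix",
    "E": "sheet",
    "T": "loop",
    "S": "loop",
    "C": "loop",
    "G": "other",
    "I": "other",
    "B": "other",
    "b": "other",
}

#: Six-way secondary-structure bins.
SS_BINS = (
    "AH/L-junction",
    "BS/L-junction",
    "mid-AH",
    "mid-BS",
    "mid-L",
    "other",
)


@dataclass(frozen=True)
class SSContext:
    """Secondary-structure bin and junction distance of one site.

    ``junction_distance`` is the sequence separation (in residues) to the
    nearest residue of a different helix/sheet/loop group, or ``inf`` when
    no junction is reachable; it is reported as ">2" above 2.
    """

    bin: str
    junction_distance: float

    def __post_init__(self) -> None:
        if self.bin not in SS_BINS:
            raise InteinSiteError(f"unknown SS bin {self.bin!r}")
        if self.junction_distance < 1:
            raise InteinSiteError("junction distance must be >= 1")

    @property
    def printed_distance(self) -> str:
        d = self.junction_distance
        return str(int(d)) if d <= 2 else ">2"


@dataclass(frozen=True)
class FlexibilityResult:
    """Time-averaged C-alpha deviation (A) of one site over snapshots."""

    rmsd: float

    def __post_init__(self) -> None:
        if self.rmsd < 0 or not math.isfinite(self.rmsd):
            raise InteinSiteError("rmsd must be finite and non-negative")


def group_ss_codes(codes: Mapping[int, str] | Sequence[str]) -> dict[int, str]:
    """Coarse-group one-letter SS codes: helix, sheet, loop or other.

    Accepts a position->code mapping (as from
    :func:`~inteinsite.core_io.read_ss_assignment`) or a plain sequence of
    codes taken to start at position 1.  Grouping is idempotent: group
    names map to themselves.
    """
    if not isinstance(codes, Mapping):
        codes = {i + 1: c for i, c in enumerate(codes)}
    out = {}
    for pos, code in codes.items():
        if code in ("helix", "sheet", "loop", "other"):
            out[pos] = code
        else:
            out[pos] = _SS_GROUP.get(code, "other")
    return out


def classify_site_ss(
    groups: Mapping[int, str], position: int, junction_window: int = 2
) -> SSContext:
    """Six-way secondary-structure classification of one site.

    In each sequence direction the nearest residue whose group differs
    from the site's is sought; an ``other`` (or unassigned) residue
    terminates the run in that direction without defining a junction.  A
    helix<->loop contact within ``junction_window`` residues puts the site
    in ``AH/L-junction``, a sheet<->loop contact in ``BS/L-junction`` (when
    both are equally reachable the nearer wins; an exact tie goes to the
    sheet junction, the structure class enriched at native sites).
    Otherwise the site is mid-helix / mid-sheet / mid-loop by its own
    group; sites whose own group is ``other`` get bin ``other``.
    """
    groups = group_ss_codes(groups)
    own = groups.get(position)
    if own is None or own == "other":
        return SSContext(bin="other", junction_distance=math.inf)

    def scan(step: int) -> tuple[float, str | None]:
        d = 1
        pos = position + step
        while pos in groups:
            g = groups[pos]
            if g == "other":
                return math.inf, None
            if g != own:
                return d, g
            d += 1
            pos += step
        return math.inf, None

    nearest: dict[str, float] = {}
    for dist, g in (scan(-1), scan(+1)):
        if g is not None:
            nearest[g] = min(nearest.get(g, math.inf), dist)
    junction_distance = min(nearest.values()) if nearest else math.inf

    # distance to the relevant loop junction for each junction bin
    if own == "loop":
        d_helix = nearest.get("helix", math.inf)
        d_sheet = nearest.get("sheet", math.inf)
    elif own == "helix":
        d_helix = nearest.get("loop", math.inf)
        d_sheet = math.inf
    else:  # sheet
        d_helix = math.inf
        d_sheet = nearest.get("loop", math.inf)

    if min(d_helix, d_sheet) <= junction_window:
        bin_ = "BS/L-junction" if d_sheet <= d_helix else "AH/L-junction"
    else:
        bin_ = {"helix": "mid-AH", "sheet": "mid-BS", "loop": "mid-L"}[own]
    return SSContext(bin=bin_, junction_distance=junction_distance)


def cbeta_density(
    structure: StructureContext, position: int, cutoff: float = 8.0
) -> int:
    """Number of other residues' C-beta atoms within ``cutoff`` A (closed).

    The burial proxy: high counts indicate a core position, low counts an
    exposed one.  Glycine uses its C-alpha as C-beta.  The site's own
    C-beta is excluded.
    """
    if position not in structure.cb_coords:
        raise InteinSiteError(
            f"no C-beta (or substituted C-alpha) at position {position}"
        )
    origin = structure.cb_coords[position]
    count = 0
    for pos, xyz in structure.cb_coords.items():
        if pos == position:
            continue
        if np.linalg.norm(xyz - origin) <= cutoff:
            count += 1
    return count


def distance_to_functional_site(
    structure: StructureContext,
    position: int,
    which: Literal["active", "dimer", "either"] = "either",
) -> float:
    """Minimum C-alpha distance (A) to annotated functional residues.

    ``which`` selects the active-site set, the dimer-interface set, or
    their union (the combined "distance to the active site or dimer
    interface" feature).  An empty selected annotation set raises
    :class:`~inteinsite.errors.AnnotationError`: the feature is *missing*,
    never zero.
    """
    if which == "active":
        annotated = set(structure.active_site_positions)
    elif which == "dimer":
        annotated = set(structure.dimer_interface_positions)
    elif which == "either":
        annotated = set(structure.active_site_positions) | set(
            structure.dimer_interface_positions
        )
    else:
        raise InteinSiteError(f"unknown annotation selector {which!r}")
    if not annotated:
        raise AnnotationError(
            f"no {which!r} functional-residue annotations available"
        )
    if position not in structure.ca_coords:
        raise InteinSiteError(f"no C-alpha coordinate at position {position}")
    ca = structure.ca_coords[position]
    return float(
        min(np.linalg.norm(ca - structure.ca_coords[a]) for a in annotated)
    )


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Least-squares rigid-body superposition of ``mobile`` onto ``reference``.

    Returns the transformed mobile coordinates minimising the summed
    squared C-alpha deviation (rotation + translation only, no scaling or
    reflection).  Requires at least 3 non-collinear reference atoms.
    """
    from scipy.spatial.transform import Rotation

    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DegenerateGeometryError(
            f"coordinate sets must both be (N, 3); got {mobile.shape} "
            f"and {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 atoms to superpose")
    ref_c = reference - reference.mean(axis=0)
    mob_c = mobile - mobile.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise DegenerateGeometryError("reference coordinates are collinear")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    return rot.apply(mob_c) + reference.mean(axis=0)


def site_flexibility(
    snapshots: SnapshotSet,
    position: int,
    superpose: bool = True,
    ddof: int = 0,
) -> FlexibilityResult:
    """Per-site positional RMSD over snapshots, vs the first snapshot.

    Each snapshot is (optionally) superposed onto snapshot 1 over all
    residues; the site's flexibility is then::

        rmsd_i = sqrt( (1/(S - ddof)) * sum_s ||x_{i,s} - x_{i,1}||^2 )

    with the sum over all S snapshots (the reference term is 0).  The
    default ``ddof=0`` divides by S; ``ddof=1`` selects the S-1
    convention.
    """
    traj = snapshots.ca_trajectory
    S = snapshots.n_snapshots
    if ddof not in (0, 1):
        raise InteinSiteError("ddof must be 0 or 1")
    idx = snapshots.residue_index(position)
    ref = traj[0]
    sq = 0.0
    for s in range(S):
        frame = kabsch_superpose(traj[s], ref) if superpose else traj[s]
        sq += float(np.sum((frame[idx] - ref[idx]) ** 2))
    return FlexibilityResult(rmsd=math.sqrt(sq / (S - ddof)))
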