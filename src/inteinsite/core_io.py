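"""Domain types, candidate-site enumeration, file readers and synthetic data.

An intein inserts immediately before a cysteine, serine or threonine (the
"+1" residue of the C-extein); the seven residues -3..+4 around the
insertion point form the insertion-site cassette.  Everything downstream
(conservation ranks, cassette SVM, structural context) operates on the
candidate C/S/T sites enumerated here.

Positions are 1-based throughout, matching residue naming such as C64 or
S158; the insertion occurs between the -1 and +1 residues.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, NUCLEOPHILES, UNKNOWN, canonical_residue
from .conservation import PSSMatrix, entropy_profile, conservation_rank
from .errors import (
    AnnotationError,
    CassetteRangeError,
    InteinSiteError,
    InteinSiteWarning,
    PSSMParseError,
    StrideParseError,
    StructureMappingError,
    SyntheticParameterError,
)

__all__ = [
    "ExteinRecord",
    "CandidateSite",
    "Cassette",
    "StructureContext",
    "SnapshotSet",
    "SiteFeatureRow",
    "JUNCTION_FAR",
    "enumerate_candidate_sites",
    "extract_cassette",
    "read_pssm",
    "read_structure",
    "read_ss_assignment",
    "read_extein_fasta",
    "load_xynb_table",
    "SyntheticCaseParams",
    "SyntheticCase",
    "generate_synthetic_case",
    "generate_extein_set",
    "shuffle_native_labels",
]

#: Sentinel for a junction distance reported only as "more than 2".
JUNCTION_FAR: float = math.inf


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExteinRecord:
    """A host (extein) sequence with its known intein insertion sites.

    ``native_sites`` holds the 1-based positions of the +1 residue of each
    annotated insertion site; each must be a C, S or T of the sequence.
    """

    id: str
    sequence: str
    native_sites: tuple[int, ...] = ()
    source_note: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "native_sites", tuple(self.native_sites))
        bad = {c for c in seq if c not in AA_INDEX and c != UNKNOWN}
        if bad:
            raise InteinSiteError(
                f"extein {self.id!r}: non-standard residues {sorted(bad)} "
                "(use X for unknown)"
            )
        for p in self.native_sites:
            if not 1 <= p <= len(seq):
                raise InteinSiteError(
                    f"extein {self.id!r}: native site {p} outside 1..{len(seq)}"
                )
            if seq[p - 1] not in NUCLEOPHILES:
                raise InteinSiteError(
                    f"extein {self.id!r}: native site {p} is "
                    f"{seq[p - 1]!r}, not C/S/T"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        return self.sequence[position - 1]


@dataclass(frozen=True)
class CandidateSite:
    """A C/S/T position whose full -3..+4 window lies inside the sequence."""

    extein_id: str
    position: int
    plus_one_residue: str
    is_native: bool = False

    def __post_init__(self) -> None:
        if self.plus_one_residue not in NUCLEOPHILES:
            raise InteinSiteError(
                f"+1 residue must be C/S/T, got {self.plus_one_residue!r}"
            )


@dataclass(frozen=True)
class Cassette:
    """The seven-residue -3..+4 insertion-site window.

    ``residues_minus`` are positions -3,-2,-1; ``plus_one`` is the C/S/T
    nucleophile; ``residues_plus`` are +2,+3,+4.  Only the six flanking
    residues are used by the SVM encoding; the +1 identity is not.
    """

    residues_minus: str
    plus_one: str
    residues_plus: str

    def __post_init__(self) -> None:
        if len(self.residues_minus) != 3 or len(self.residues_plus) != 3:
            raise InteinSiteError("cassette needs 3 residues on each flank")
        if self.plus_one not in NUCLEOPHILES:
            raise InteinSiteError(
                f"cassette +1 residue must be C/S/T, got {self.plus_one!r}"
            )

    @property
    def seven(self) -> str:
        """All seven residues as a string, -3..+4."""
        return self.residues_minus + self.plus_one + self.residues_plus

    @property
    def encoded_key(self) -> str:
        """The six encoded flank residues (identity used for dedup)."""
        return self.residues_minus + self.residues_plus


@dataclass
class StructureContext:
    """Structural context of one extein, keyed by extein sequence position.

    Coordinates are in Angstrom.  ``cb_coords`` substitutes the C-alpha
    for glycine (and, with a warning, for any residue lacking a C-beta).
    """

    residue_index_map: dict[int, int]          # structure resnum -> extein pos
    ca_coords: dict[int, np.ndarray]           # extein pos -> (3,)
    cb_coords: dict[int, np.ndarray]           # extein pos -> (3,)
    ss_codes: dict[int, str] = field(default_factory=dict)
    active_site_positions: frozenset[int] = frozenset()
    dimer_interface_positions: frozenset[int] = frozenset()
    unmapped_annotations: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        for pos, xyz in list(self.ca_coords.items()):
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise StructureMappingError(
                    f"non-finite or malformed C-alpha at position {pos}"
                )
            self.ca_coords[pos] = arr
        for pos, xyz in list(self.cb_coords.items()):
            self.cb_coords[pos] = np.asarray(xyz, dtype=float)
        annotated = set(self.active_site_positions) | set(
            self.dimer_interface_positions
        )
        missing = annotated - set(self.ca_coords)
        if missing:
            raise StructureMappingError(
                f"annotated positions without C-alpha coordinates: "
                f"{sorted(missing)}"
            )


@dataclass(frozen=True)
class SnapshotSet:
    """Aligned C-alpha coordinates over trajectory snapshots.

    ``ca_trajectory`` has shape (S, N, 3); ``positions`` maps trajectory
    residue index to extein sequence position (defaults to 1..N).
    """

    ca_trajectory: np.ndarray
    positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        traj = np.asarray(self.ca_trajectory, dtype=float)
        if traj.ndim != 3 or traj.shape[2] != 3:
            raise InteinSiteError(
                f"trajectory must be (S, N, 3), got {traj.shape}"
            )
        if traj.shape[0] < 2:
            raise InteinSiteError("at least 2 snapshots required")
        object.__setattr__(self, "ca_trajectory", traj)
        if not self.positions:
            object.__setattr__(
                self, "positions", tuple(range(1, traj.shape[1] + 1))
            )
        if len(self.positions) != traj.shape[1]:
            raise InteinSiteError("positions length must equal residue count")

    @property
    def n_snapshots(self) -> int:
        return self.ca_trajectory.shape[0]

    def residue_index(self, position: int) -> int:
        try:
            return self.positions.index(position)
        except ValueError:
            raise InteinSiteError(
                f"no trajectory residue for position {position}"
            ) from None


@dataclass
class SiteFeatureRow:
    """Per-site feature values, as in the XynB case-study table.

    ``junction_distance`` is 1, 2 or :data:`JUNCTION_FAR` (printed ">2");
    optional features are ``None`` when their inputs were unavailable.
    """

    site: CandidateSite
    distance_to_functional_site: float | None = None
    svm_score: float | None = None
    junction_distance: float | None = None
    conservation_rank: float | None = None
    cbeta_density: int | None = None
    flexibility_rmsd: float | None = None
    splicing_label: bool | None = None

    def __post_init__(self) -> None:
        if self.conservation_rank is not None and not (
            -1e-12 <= self.conservation_rank <= 1 + 1e-12
        ):
            raise InteinSiteError("conservation rank must lie in [0, 1]")
        for name in ("distance_to_functional_site", "junction_distance"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InteinSiteError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# Candidate enumeration and cassette extraction
# ---------------------------------------------------------------------------

def enumerate_candidate_sites(extein: ExteinRecord) -> list[CandidateSite]:
    """All C/S/T positions of ``extein`` with a complete -3..+4 window.

    Sites whose window would be clipped by a terminus are excluded: the
    cassette (and hence the SVM vector) is undefined without all six
    flanking residues.  Returned in ascending position order.
    """
    if len(extein) < 7:
        warnings.warn(
            f"extein {extein.id!r} shorter than 7 residues: no candidate "
            "site can carry a full cassette",
            InteinSiteWarning,
            stacklevel=2,
        )
        return []
    native = set(extein.native_sites)
    sites = []
    # 1-based: cassette occupies pos-3..pos+3 (offsets -3..-1, +1, +2..+4)
    for pos in range(4, len(extein) - 2):
        aa = extein.residue(pos)
        if aa in NUCLEOPHILES:
            sites.append(
                CandidateSite(
                    extein_id=extein.id,
                    position=pos,
                    plus_one_residue=aa,
                    is_native=pos in native,
                )
            )
    return sites


def extract_cassette(extein: ExteinRecord, position: int) -> Cassette:
    """The -3..+4 cassette around ``position`` (the +1 residue).

    Non-standard residues in the window are recorded as ``X``.
    """
    if position - 3 < 1 or position + 3 > len(extein):
        raise CassetteRangeError(
            f"cassette -3..+4 around position {position} (sequence positions "
            f"{position - 3}..{position + 3}) exceeds sequence 1.."
            f"{len(extein)} of extein {extein.id!r}"
        )
    window = extein.sequence[position - 4 : position + 3]
    window = "".join(canonical_residue(c) for c in window)
    plus_one = extein.residue(position)
    if plus_one not in NUCLEOPHILES:
        raise InteinSiteError(
            f"position {position} of extein {extein.id!r} is "
            f"{plus_one!r}, not C/S/T"
        )
    return Cassette(
        residues_minus=window[:3], plus_one=plus_one, residues_plus=window[4:]
    )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_pssm(text: str) -> PSSMatrix:
    """Parse a PSI-BLAST (blastpgp ``-Q``) ASCII PSSM into probabilities.

    The probability of amino acid *j* at position *i* is taken from the
    weighted-observed-percentage block (the second 20 columns), divided by
    100 and renormalized to sum 1.  An all-zero percentage row (positions
    with no aligned information) becomes the uniform distribution -- the
    maximum-entropy, least-conserved fallback.
    """
    lines = text.splitlines()
    alphabet: list[str] = []
    header_line = None
    for k, line in enumerate(lines):
        toks = line.split()
        if len(toks) == 40 and all(len(t) == 1 and t.isalpha() for t in toks):
            alphabet = toks[:20]
            header_line = k
            break
    if header_line is None:
        raise PSSMParseError(
            "no PSSM column header (40 single-letter columns) found"
        )
    if sorted(alphabet) != sorted(AMINO_ACIDS):
        raise PSSMParseError(
            f"header line {header_line + 1}: unexpected amino-acid alphabet "
            f"{''.join(alphabet)!r}"
        )
    order = [alphabet.index(aa) for aa in AMINO_ACIDS]

    rows: list[np.ndarray] = []
    positions: list[int] = []
    seq_chars: list[str] = []
    for k in range(header_line + 1, len(lines)):
        toks = lines[k].split()
        if not toks:
            continue
        if not toks[0].lstrip("-").isdigit():
            break  # footer (K, Lambda, ...) terminates the matrix block
        if len(toks) < 42:
            raise PSSMParseError(
                f"line {k + 1}: expected >= 42 fields "
                f"(position, residue, 20 log-odds, 20 percentages), "
                f"got {len(toks)}"
            )
        try:
            pos = int(toks[0])
            pct = np.array([float(t) for t in toks[22:42]], dtype=float)
        except ValueError as exc:
            raise PSSMParseError(f"line {k + 1}: {exc}") from None
        if np.any(pct < 0):
            raise PSSMParseError(
                f"line {k + 1}: negative observed percentage"
            )
        pct = pct[order]
        total = pct.sum()
        if total == 0.0:
            row = np.full(20, 1.0 / 20.0)
        else:
            row = pct / total
        rows.append(row)
        positions.append(pos)
        seq_chars.append(canonical_residue(toks[1]))
    if not rows:
        raise PSSMParseError("PSSM contains no data rows")
    return PSSMatrix(
        probabilities=np.vstack(rows),
        positions=tuple(positions),
        sequence="".join(seq_chars),
    )


def read_structure(
    pdb_text: str,
    chain: str,
    annotations: Mapping[str, Iterable[int]] | None = None,
    offset: int = 0,
    residue_map: Mapping[int, int] | None = None,
) -> StructureContext:
    """Build a :class:`StructureContext` from PDB-format ATOM records.

    Structure residue numbers are mapped onto extein numbering either via
    ``residue_map`` (explicit structure-resnum -> extein-position map) or
    ``extein_pos = resnum + offset``; the mapping is always an explicit
    input, never inferred.  ``annotations`` maps ``"active_site"`` and/or
    ``"dimer_interface"`` to extein positions.  Glycine (and any residue
    missing a C-beta, with a warning) has its C-alpha used as C-beta.
    Annotated positions absent from the structure are reported in
    ``unmapped_annotations`` with a warning; an annotated residue present
    but lacking a C-alpha is an error.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", io.StringIO(pdb_text))
    try:
        chain_obj = structure[0][chain]
    except KeyError:
        raise StructureMappingError(f"chain {chain!r} not found") from None

    annotations = annotations or {}
    active = frozenset(int(p) for p in annotations.get("active_site", ()))
    dimer = frozenset(int(p) for p in annotations.get("dimer_interface", ()))
    annotated = active | dimer

    index_map: dict[int, int] = {}
    ca: dict[int, np.ndarray] = {}
    cb: dict[int, np.ndarray] = {}
    for res in chain_obj:
        if res.id[0] != " ":
            continue  # skip heteroatoms / waters
        resnum = res.id[1]
        if residue_map is not None:
            if resnum not in residue_map:
                continue
            pos = int(residue_map[resnum])
        else:
            pos = resnum + offset
        index_map[resnum] = pos
        if "CA" not in res:
            if pos in annotated:
                raise StructureMappingError(
                    f"annotated position {pos} has no C-alpha atom"
                )
            warnings.warn(
                f"residue {resnum} ({res.resname}) has no C-alpha; skipped",
                InteinSiteWarning,
                stacklevel=2,
            )
            continue
        ca[pos] = res["CA"].coord.astype(float)
        if "CB" in res:
            cb[pos] = res["CB"].coord.astype(float)
        else:
            if res.resname.strip() != "GLY":
                warnings.warn(
                    f"residue {resnum} ({res.resname}) lacks C-beta; "
                    "using C-alpha",
                    InteinSiteWarning,
                    stacklevel=2,
                )
            cb[pos] = ca[pos]
    if not ca:
        raise StructureMappingError(
            f"chain {chain!r} contains no mappable residues"
        )
    unmapped = annotated - set(ca)
    if unmapped:
        warnings.warn(
            f"annotated positions not present in structure: {sorted(unmapped)}",
            InteinSiteWarning,
            stacklevel=2,
        )
    return StructureContext(
        residue_index_map=index_map,
        ca_coords=ca,
        cb_coords=cb,
        active_site_positions=active - unmapped,
        dimer_interface_positions=dimer - unmapped,
        unmapped_annotations=frozenset(unmapped),
    )


_SS_CODES = set("HGIEBbTCS")


def read_ss_assignment(text: str, offset: int = 0) -> dict[int, str]:
    """Per-residue secondary-structure codes from Stride output.

    Accepts either Stride ``ASG`` records (code in the sixth column) or a
    plain two-column ``position<TAB>code`` table; either way returns a
    mapping from extein position (``position + offset``) to one-letter
    code.  Positions absent from the mapping are treated as unknown by the
    junction classifier.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise StrideParseError("empty secondary-structure input")
    asg = [ln for ln in lines if ln.startswith("ASG")]
    codes: dict[int, str] = {}
    if asg:
        for ln in asg:
            toks = ln.split()
            if len(toks) < 6:
                raise StrideParseError(f"malformed ASG record: {ln!r}")
            try:
                pos = int(toks[3]) + offset
            except ValueError:
                raise StrideParseError(
                    f"non-integer residue number in ASG record: {ln!r}"
                ) from None
            code = toks[5]
            if len(code) != 1:
                raise StrideParseError(
                    f"secondary-structure code {code!r} is not one letter"
                )
            if pos in codes:
                raise StrideParseError(f"duplicate position {pos}")
            codes[pos] = code
    else:
        for ln in lines:
            if ln.lstrip().startswith("#"):
                continue
            toks = ln.split()
            if len(toks) < 2:
                raise StrideParseError(f"expected 'position code', got {ln!r}")
            if toks[0].lower() in {"position", "pos"}:
                continue
            try:
                pos = int(toks[0]) + offset
            except ValueError:
                raise StrideParseError(
                    f"non-integer position in line {ln!r}"
                ) from None
            code = toks[1]
            if len(code) != 1:
                raise StrideParseError(
                    f"secondary-structure code {code!r} is not one letter"
                )
            if pos in codes:
                raise StrideParseError(f"duplicate position {pos}")
            codes[pos] = code
    if not codes:
        raise StrideParseError("no secondary-structure records found")
    return codes


def read_extein_fasta(
    handle_or_text,
    native_sites: Mapping[str, Iterable[int]] | None = None,
) -> list[ExteinRecord]:
    """Read extein sequences from FASTA.

    ``native_sites`` optionally maps record ids to known +1 positions.
    """
    from Bio import SeqIO

    if isinstance(handle_or_text, str):
        handle = io.StringIO(handle_or_text)
    else:
        handle = handle_or_text
    native_sites = native_sites or {}
    records = []
    for rec in SeqIO.parse(handle, "fasta"):
        records.append(
            ExteinRecord(
                id=rec.id,
                sequence=str(rec.seq),
                native_sites=tuple(native_sites.get(rec.id, ())),
                source_note=rec.description,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Packaged XynB case-study table
# ---------------------------------------------------------------------------

def load_xynb_table() -> list[SiteFeatureRow]:
    """The packaged 20-site XynB xylanase feature table.

    Twenty C/S/T sites of the *D. thermophilum* XynB catalytic domain with
    their distance to the nearest active-site residue, cassette SVM score,
    junction distance (1, 2 or ``JUNCTION_FAR`` for ">2") and conservation
    rank, plus the experimentally determined splicing outcome (11 sites
    spliced).  Internal consistency of the packaged values is re-checked at
    every load; a discrepancy raises rather than being silently corrected.
    """
    text = (
        resources.files("inteinsite.data")
        .joinpath("xynb_table1.tsv")
        .read_text()
    )
    rows: list[SiteFeatureRow] = []
    lines = text.strip().splitlines()
    for ln in lines[1:]:
        toks = ln.split("\t")
        if len(toks) < 5:
            raise InteinSiteError(f"malformed packaged table row: {ln!r}")
        name, dist, svm, junc, cons = toks[:5]
        splicing = len(toks) > 5 and toks[5].strip() == "X"
        site = CandidateSite(
            extein_id="XynB",
            position=int(name[1:]),
            plus_one_residue=name[0],
            is_native=splicing,
        )
        rows.append(
            SiteFeatureRow(
                site=site,
                distance_to_functional_site=float(dist),
                svm_score=float(svm),
                junction_distance=JUNCTION_FAR if junc == ">2" else float(junc),
                conservation_rank=float(cons),
                splicing_label=splicing,
            )
        )
    _validate_xynb_table(rows)
    return rows


def _validate_xynb_table(rows: list[SiteFeatureRow]) -> None:
    """Cross-check the packaged table against its documented tallies."""
    if len(rows) != 20:
        raise InteinSiteError(f"packaged XynB table has {len(rows)} rows, not 20")
    n_splice = sum(1 for r in rows if r.splicing_label)
    checks = {
        "splice sites": (n_splice, 11),
        "splice sites within 2 of a junction": (
            sum(
                1
                for r in rows
                if r.splicing_label and r.junction_distance <= 2
            ),
            7,
        ),
        "splice sites above conservation 0.61": (
            sum(
                1
                for r in rows
                if r.splicing_label and r.conservation_rank > 0.61
            ),
            7,
        ),
        "splice sites with positive SVM score": (
            sum(1 for r in rows if r.splicing_label and r.svm_score > 0),
            5,
        ),
        "splice sites closer than 14.1 A": (
            sum(
                1
                for r in rows
                if r.splicing_label and r.distance_to_functional_site < 14.1
            ),
            7,
        ),
    }
    for what, (got, expected) in checks.items():
        if got != expected:
            raise InteinSiteError(
                f"packaged XynB table inconsistent: {got} {what}, "
                f"expected {expected}"
            )


# ---------------------------------------------------------------------------
# Synthetic data generation
# ---------------------------------------------------------------------------

_BACKGROUND_AAS = "".join(a for a in AMINO_ACIDS if a not in NUCLEOPHILES)


@dataclass(frozen=True)
class SyntheticCaseParams:
    """Parameters of a synthetic single-extein test case.

    The generated extein carries one *planted* insertion site plus
    ``n_decoy_sites`` decoy C/S/T sites on an otherwise C/S/T-free
    background, so the candidate set is exactly the planted + decoy sites.
    The planted site's feature profile is controlled by the ``planted_*``
    flags and verified on the generated bundle before it is returned.
    """

    length: int = 200
    n_decoy_sites: int = 14
    planted_conserved: bool = True     # low-entropy PSSM row at the site
    planted_near_functional: bool = True   # active-site residues nearby
    planted_near_junction: bool = True     # within 2 of an SS/loop boundary
    planted_motif: str | None = None   # optional 7-residue cassette override
    min_site_spacing: int = 8          # keeps cassettes free of other C/S/T
    pssm_max_weight: float = 0.5       # background one-hot mixture weight cap
    n_snapshots: int = 50
    snapshot_jitter: float = 0.5       # per-coordinate Gaussian sigma, A

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise SyntheticParameterError("sequence length must be positive")
        if self.n_decoy_sites < 0:
            raise SyntheticParameterError("n_decoy_sites must be >= 0")
        if self.planted_motif is not None and len(self.planted_motif) != 7:
            raise SyntheticParameterError("planted_motif must have 7 residues")
        if self.n_snapshots < 2:
            raise SyntheticParameterError("need at least 2 snapshots")
        if not 0.0 <= self.pssm_max_weight < 0.9:
            raise SyntheticParameterError(
                "pssm_max_weight must lie in [0, 0.9) to keep decoy rows "
                "distinguishably noisier than the planted row"
            )


@dataclass(frozen=True)
class SyntheticCase:
    """The bundle produced by :func:`generate_synthetic_case`."""

    extein: ExteinRecord
    pssm: PSSMatrix
    structure: StructureContext
    snapshots: SnapshotSet
    planted_site: CandidateSite
    params: SyntheticCaseParams
    seed: int


def _site_positions(
    rng: np.random.Generator, params: SyntheticCaseParams
) -> list[int]:
    lo, hi = 4, params.length - 3  # full window fits
    if hi < lo:
        raise SyntheticParameterError(
            f"length {params.length} too short for any full cassette"
        )
    n_sites = params.n_decoy_sites + 1
    pool = np.arange(lo, hi + 1)
    for _ in range(200):
        picks = rng.permutation(pool)
        chosen: list[int] = []
        for p in picks:
            if all(abs(p - q) >= params.min_site_spacing for q in chosen):
                chosen.append(int(p))
                if len(chosen) == n_sites:
                    return sorted(chosen)
    raise SyntheticParameterError(
        f"cannot place {n_sites} sites with spacing "
        f"{params.min_site_spacing} in a length-{params.length} sequence"
    )


def _self_avoiding_trace(
    rng: np.random.Generator, n: int, step: float = 3.8, clash: float = 4.0
) -> np.ndarray:
    """A self-avoiding C-alpha random walk with fixed bond length."""
    for _ in range(50):  # restart attempts
        coords = np.zeros((n, 3))
        prev_dir = np.array([1.0, 0.0, 0.0])
        ok = True
        for i in range(1, n):
            placed = False
            for _ in range(300):
                d = rng.normal(size=3)
                d = 0.9 * prev_dir + 0.8 * d / np.linalg.norm(d)
                d /= np.linalg.norm(d)
                cand = coords[i - 1] + step * d
                if i >= 2:
                    dists = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                    if dists.min() < clash:
                        continue
                coords[i] = cand
                prev_dir = d
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return coords
    raise SyntheticParameterError(
        f"failed to build a self-avoiding trace of length {n}"
    )


def _cbeta_offsets(ca: np.ndarray, sequence: str) -> np.ndarray:
    """Pseudo C-beta positions 1.53 A off the local chain axis."""
    n = ca.shape[0]
    cb = ca.copy()
    for i in range(n):
        if sequence[i] == "G":
            continue
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        v = ca[i] - 0.5 * (ca[lo] + ca[hi])
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            v = np.array([0.0, 0.0, 1.0])
            norm = 1.0
        cb[i] = ca[i] + 1.53 * v / norm
    return cb


def generate_synthetic_case(
    params: SyntheticCaseParams | None = None, seed: int = 0
) -> SyntheticCase:
    """Deterministically generate an extein + PSSM + structure + snapshots.

    The planted site is guaranteed (and verified before returning) to
    satisfy the requested profile: with ``planted_conserved`` its PSSM row
    is near one-hot while every other position's row mixes at most
    ``pssm_max_weight`` of one-hot mass into the uniform background, so the
    planted site is strictly the lowest-entropy candidate; with
    ``planted_near_functional`` active-site residues are placed two
    positions up- and downstream (well inside 14.1 A along the chain);
    with ``planted_near_junction`` the local secondary structure is forced
    to a sheet/loop boundary one residue away.
    """
    params = params or SyntheticCaseParams()
    rng = np.random.default_rng(seed)

    sites = _site_positions(rng, params)
    planted_pos = int(sites[rng.integers(len(sites))])

    seq = list(rng.choice(list(_BACKGROUND_AAS), size=params.length))
    for p in sites:
        seq[p - 1] = str(rng.choice(list("CST")))
    if params.planted_motif is not None:
        motif = params.planted_motif.upper()
        if motif[3] not in NUCLEOPHILES:
            raise SyntheticParameterError(
                "planted_motif position 4 (the +1 residue) must be C/S/T"
            )
        for k, aa in enumerate(motif):
            seq[planted_pos - 4 + k] = aa
    sequence = "".join(seq)

    # PSSM: background rows mix a capped one-hot component into uniform;
    # the planted row (if conserved) is nearly one-hot, hence lowest entropy.
    probs = np.empty((params.length, 20))
    for i in range(params.length):
        w = rng.uniform(0.2, params.pssm_max_weight)
        row = np.full(20, (1.0 - w) / 20.0)
        row[AA_INDEX[sequence[i]]] += w
        probs[i] = row
    if params.planted_conserved:
        row = np.full(20, 0.03 / 20.0)
        row[AA_INDEX[sequence[planted_pos - 1]]] += 0.97
        probs[planted_pos - 1] = row
    pssm = PSSMatrix(probabilities=probs, sequence=sequence)

    ca = _self_avoiding_trace(rng, params.length)
    cb = _cbeta_offsets(ca, sequence)

    # Secondary structure: random H/E/C runs, then force a sheet/loop
    # boundary right after the planted site when requested.
    codes = []
    while len(codes) < params.length:
        kind = rng.choice(["H", "E", "C"], p=[0.35, 0.3, 0.35])
        run = int(rng.integers(3, 9))
        codes.extend([kind] * run)
    codes = codes[: params.length]
    if params.planted_near_junction:
        for p in range(max(1, planted_pos - 3), planted_pos + 1):
            codes[p - 1] = "E"
        for p in range(planted_pos + 1, min(params.length, planted_pos + 3) + 1):
            codes[p - 1] = "C"
    ss_codes = {i + 1: codes[i] for i in range(params.length)}

    active: frozenset[int] = frozenset()
    dimer: frozenset[int] = frozenset()
    if params.planted_near_functional:
        active = frozenset(
            p for p in (planted_pos - 2, planted_pos + 2) if 1 <= p <= params.length
        )
        far = [p for p in range(1, params.length + 1) if abs(p - planted_pos) > 30]
        if far:
            dimer = frozenset(int(x) for x in rng.choice(far, size=min(2, len(far)), replace=False))

    structure = StructureContext(
        residue_index_map={i + 1: i + 1 for i in range(params.length)},
        ca_coords={i + 1: ca[i] for i in range(params.length)},
        cb_coords={i + 1: cb[i] for i in range(params.length)},
        ss_codes=ss_codes,
        active_site_positions=active,
        dimer_interface_positions=dimer,
    )

    traj = np.empty((params.n_snapshots, params.length, 3))
    traj[0] = ca
    for s in range(1, params.n_snapshots):
        jitter = rng.normal(scale=params.snapshot_jitter, size=(params.length, 3))
        # random rigid-body motion, removable by superposition
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(rng=rng)
        shift = rng.normal(scale=5.0, size=3)
        traj[s] = rot.apply(ca + jitter) + shift
    snapshots = SnapshotSet(ca_trajectory=traj)

    extein = ExteinRecord(
        id=f"synthetic-{seed}",
        sequence=sequence,
        native_sites=(planted_pos,),
        source_note="synthetic test case",
    )
    planted = CandidateSite(
        extein_id=extein.id,
        position=planted_pos,
        plus_one_residue=sequence[planted_pos - 1],
        is_native=True,
    )
    case = SyntheticCase(
        extein=extein,
        pssm=pssm,
        structure=structure,
        snapshots=snapshots,
        planted_site=planted,
        params=params,
        seed=seed,
    )
    _verify_planted_profile(case)
    return case


def _verify_planted_profile(case: SyntheticCase) -> None:
    params = case.params
    candidates = enumerate_candidate_sites(case.extein)
    if params.planted_conserved and len(candidates) >= 2:
        prof = entropy_profile(case.pssm)
        rank = conservation_rank(
            prof, candidates, case.planted_site.position
        )
        if rank < 0.9:
            raise SyntheticParameterError(
                f"planted site conservation rank {rank:.3f} < 0.9; "
                "profile verification failed"
            )
    if params.planted_near_functional:
        p = case.planted_site.position
        ca = case.structure.ca_coords
        dmin = min(
            np.linalg.norm(ca[p] - ca[a])
            for a in case.structure.active_site_positions
        )
        if dmin >= 14.1:
            raise SyntheticParameterError(
                f"planted site {dmin:.1f} A from nearest active-site residue"
            )


def generate_extein_set(
    n_exteins: int = 15,
    n_candidates: int = 12,
    length: int = 150,
    motif: Mapping[int, str] | None = None,
    seed: int = 0,
) -> list[ExteinRecord]:
    """A synthetic extein family whose native cassettes share a motif.

    Each extein carries ``n_candidates`` C/S/T candidate sites, one of
    which is marked native; the native cassette carries ``motif``, a map
    from cassette offset (-3..-1, +2..+4) to residue (default: G at -1 and
    P at +2).  Decoy cassettes are background sequence, so a linear SVM
    trained on other exteins can recognise the native cassettes.  Used by
    the planted-motif LOOCV benchmark.
    """
    if n_candidates < 2:
        raise SyntheticParameterError("need at least 2 candidate sites")
    motif = dict(motif) if motif is not None else {-1: "G", +2: "P"}
    for off in motif:
        if off == 0 or off == 1 or not -3 <= off <= 4:
            raise SyntheticParameterError(
                f"motif offset {off} outside the encoded cassette positions"
            )
    rng = np.random.default_rng(seed)
    params = SyntheticCaseParams(
        length=length, n_decoy_sites=n_candidates - 1, min_site_spacing=8
    )
    exteins = []
    for k in range(n_exteins):
        sites = _site_positions(rng, params)
        native_pos = int(sites[rng.integers(len(sites))])
        seq = list(rng.choice(list(_BACKGROUND_AAS), size=length))
        for p in sites:
            seq[p - 1] = str(rng.choice(list("CST")))
        for off, aa in motif.items():
            # cassette offset +1 is the site itself at index native_pos-1
            idx = native_pos - 1 + (off if off < 0 else off - 1)
            seq[idx] = aa
        exteins.append(
            ExteinRecord(
                id=f"ext{k:03d}",
                sequence="".join(seq),
                native_sites=(native_pos,),
                source_note="synthetic planted-motif extein",
            )
        )
    return exteins


def shuffle_native_labels(
    dataset: Sequence[ExteinRecord], seed: int = 0
) -> list[ExteinRecord]:
    """Move each extein's native label to a random other candidate site.

    The planted motif stays where it was; only the labels move.  Used as
    the null control of the planted-motif benchmark: a model trained on
    shuffled labels should rank the (mislabelled) "native" sites no better
    than chance.
    """
    rng = np.random.default_rng(seed)
    shuffled = []
    for ext in dataset:
        candidates = [
            c.position
            for c in enumerate_candidate_sites(ext)
            if not c.is_native
        ]
        if not candidates:
            raise SyntheticParameterError(
                f"extein {ext.id!r} has no non-native candidate to relabel"
            )
        new_pos = int(rng.choice(candidates))
        shuffled.append(replace(ext, native_sites=(new_pos,)))
    return shuffled
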