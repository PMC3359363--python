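"""One-hot cassette encoding, decoy sampling and the cassette SVM.

Native insertion-site cassettes resemble each other more than random
C/S/T-centred windows do.  A linear support vector machine is trained to
separate native cassettes (+1) from randomly drawn decoy cassettes (-1),
with positive errors weighted 3x (the cost-factor), compensating for the
1:3 class imbalance of one native to three decoys per extein.

Each cassette is a 120-component binary vector: six 20-component one-hot
blocks for positions -3, -2, -1, +2, +3, +4 (the +1 nucleophile is not
encoded, it is C/S/T by construction).  An unknown residue (X) gives an
all-zero block.  The leave-one-extein-out protocol ranks each extein's
native site against its decoy sites under a model trained on all other
exteins, re-sampling the decoy training cassettes each repeat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS
from .core_io import (
    Cassette,
    CandidateSite,
    ExteinRecord,
    enumerate_candidate_sites,
    extract_cassette,
)
from .errors import InteinSiteError, InteinSiteWarning, UndefinedRankError

__all__ = [
    "BLOCK_OFFSETS",
    "EncodedCassette",
    "LinearSVMModel",
    "encode_cassette",
    "sample_decoys",
    "train_svm",
    "score_cassette",
    "loocv_rank",
    "dedupe_cassettes",
    "planted_motif_benchmark",
    "read_cassette_table",
    "write_cassette_table",
    "save_model",
    "load_model",
]

#: Cassette offsets encoded, in block order.
BLOCK_OFFSETS: tuple[int, ...] = (-3, -2, -1, +2, +3, +4)

N_FEATURES = len(BLOCK_OFFSETS) * 20


@dataclass(frozen=True)
class EncodedCassette:
    """The 120-component one-hot vector of a cassette's six flank residues."""

    v: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        if v.shape != (N_FEATURES,):
            raise InteinSiteError(f"encoded cassette must be ({N_FEATURES},)")
        object.__setattr__(self, "v", v)


def encode_cassette(cassette: Cassette) -> EncodedCassette:
    """One-hot encode the six flanking residues of a cassette.

    Blocks are ordered -3, -2, -1, +2, +3, +4; within each block the 20
    components follow the alphabetical one-letter order of
    :data:`~inteinsite.alphabet.AMINO_ACIDS`.  An X residue leaves its
    block all-zero.  The +1 residue is never encoded.
    """
    v = np.zeros(N_FEATURES)
    residues = cassette.residues_minus + cassette.residues_plus
    for block, aa in enumerate(residues):
        idx = AA_INDEX.get(aa)
        if idx is not None:
            v[block * 20 + idx] = 1.0
    return EncodedCassette(v=v)


def _encode_many(cassettes: Iterable[Cassette]) -> np.ndarray:
    return np.array([encode_cassette(c).v for c in cassettes])


def sample_decoys(
    extein: ExteinRecord, n: int = 3, seed: int | np.random.Generator = 0
) -> list[Cassette]:
    """Draw ``n`` distinct decoy cassettes from an extein's non-native sites.

    Decoys are sampled uniformly without replacement from the candidate
    C/S/T sites that are not annotated native; they are presumed (not
    proven) negatives.  If fewer than ``n`` non-native candidates exist,
    all of them are returned with a warning.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    non_native = [
        c for c in enumerate_candidate_sites(extein) if not c.is_native
    ]
    if len(non_native) < n:
        warnings.warn(
            f"extein {extein.id!r} has only {len(non_native)} non-native "
            f"candidate sites; returning all of them instead of {n}",
            InteinSiteWarning,
            stacklevel=2,
        )
        chosen = non_native
    else:
        idx = rng.choice(len(non_native), size=n, replace=False)
        chosen = [non_native[int(i)] for i in idx]
    return [extract_cassette(extein, c.position) for c in chosen]


@dataclass(frozen=True)
class LinearSVMModel:
    """A trained linear cassette classifier: score(v) = w . v + b."""

    weights: np.ndarray
    bias: float
    cost_factor: float = 3.0
    C: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_FEATURES,):
            raise InteinSiteError(f"weights must be ({N_FEATURES},)")
        if not np.all(np.isfinite(w)) or not np.isfinite(self.bias):
            raise InteinSiteError("model weights must be finite")
        object.__setattr__(self, "weights", w)


def train_svm(
    positives: Sequence[Cassette | EncodedCassette | np.ndarray],
    negatives: Sequence[Cassette | EncodedCassette | np.ndarray],
    cost_factor: float = 3.0,
    C: float | None = None,
) -> LinearSVMModel:
    """Train the class-weighted linear SVM on encoded cassettes.

    Positive-class hinge errors are weighted ``cost_factor`` (default 3)
    times negative-class errors.  When ``C`` is None it defaults to
    ``1 / mean(||v||^2)`` over the training set -- for complete cassettes
    ``||v||^2 = 6`` so ``C = 1/6``.  Training is deterministic for a given
    training set and invariant to example order.
    """
    from sklearn.svm import SVC

    if len(positives) == 0 or len(negatives) == 0:
        raise InteinSiteError(
            "training requires at least one example of each class"
        )

    def as_matrix(items) -> np.ndarray:
        rows = []
        for it in items:
            if isinstance(it, Cassette):
                rows.append(encode_cassette(it).v)
            elif isinstance(it, EncodedCassette):
                rows.append(it.v)
            else:
                arr = np.asarray(it, dtype=float)
                if arr.shape != (N_FEATURES,):
                    raise InteinSiteError(
                        f"training vectors must be ({N_FEATURES},)"
                    )
                rows.append(arr)
        return np.array(rows)

    X = np.vstack([as_matrix(positives), as_matrix(negatives)])
    y = np.concatenate(
        [np.ones(len(positives)), -np.ones(len(negatives))]
    )
    if C is None:
        mean_sq = float(np.mean(np.sum(X * X, axis=1)))
        C = 1.0 / mean_sq if mean_sq > 0 else 1.0
    clf = SVC(
        kernel="linear",
        C=C,
        class_weight={1: float(cost_factor), -1: 1.0},
        tol=1e-6,
    )
    clf.fit(X, y)
    w = clf.coef_.ravel().astype(float)
    # libsvm's decision_function sign follows its internal label order;
    # anchor the convention "positive = native-like" explicitly.
    if clf.classes_[1] != 1:
        w, b = -w, -float(clf.intercept_[0])
    else:
        b = float(clf.intercept_[0])
    return LinearSVMModel(weights=w, bias=b, cost_factor=cost_factor, C=C)


def score_cassette(
    model: LinearSVMModel, cassette: Cassette | EncodedCassette
) -> float:
    """Decision value ``w . encode(cassette) + b``; > 0 means native-like."""
    if isinstance(cassette, Cassette):
        v = encode_cassette(cassette).v
    else:
        v = cassette.v
    return float(model.weights @ v + model.bias)


def dedupe_cassettes(dataset: Sequence[ExteinRecord]) -> list[ExteinRecord]:
    """Drop native sites whose encoded cassette duplicates another's.

    Two native cassettes are duplicates when their six encoded positions
    (-3..-1, +2..+4) are identical; of a duplicate group the site on the
    longest extein survives (ties broken by extein id, then position, for
    determinism).  Exteins left without native sites are dropped.
    """
    entries: list[tuple[str, int, str, ExteinRecord]] = []
    for ext in dataset:
        for pos in ext.native_sites:
            key = extract_cassette(ext, pos).encoded_key
            entries.append((key, pos, ext.id, ext))
    keep: dict[str, tuple[int, str, int]] = {}  # key -> (len, id, pos)
    for key, pos, ext_id, ext in entries:
        cand = (-len(ext), ext_id, pos)
        if key not in keep or cand < keep[key]:
            keep[key] = cand
    kept_sites: dict[str, set[int]] = {}
    for key, (neglen, ext_id, pos) in keep.items():
        kept_sites.setdefault(ext_id, set()).add(pos)
    out = []
    for ext in dataset:
        sites = tuple(sorted(kept_sites.get(ext.id, ())))
        if not sites:
            continue
        if sites == ext.native_sites:
            out.append(ext)
        else:
            from dataclasses import replace

            out.append(replace(ext, native_sites=sites))
    return out


def _native_cassettes(ext: ExteinRecord) -> list[Cassette]:
    return [extract_cassette(ext, p) for p in ext.native_sites]


def loocv_rank(
    dataset: Sequence[ExteinRecord],
    target_extein: str,
    repeats: int = 25,
    seed: int = 0,
    cost_factor: float = 3.0,
    C: float | None = None,
    n_decoys: int = 3,
) -> float:
    """Mean leave-one-extein-out rank of the target's native site.

    Per repeat: train on every *other* extein's native cassettes (+1) plus
    ``n_decoys`` freshly sampled decoy cassettes per extein (-1); score all
    candidate sites of the target extein; the native site's rank is the
    fraction of the target's decoy (non-native candidate) cassettes scoring
    strictly below it, ties counted half.  Returns the mean rank over
    ``repeats`` -- re-sampling the training decoys is the only random
    element, so repeats differ only through it.
    """
    by_id = {ext.id: ext for ext in dataset}
    if target_extein not in by_id:
        raise InteinSiteError(f"target extein {target_extein!r} not in dataset")
    target = by_id[target_extein]
    if not target.native_sites:
        raise InteinSiteError(
            f"target extein {target_extein!r} has no native site"
        )
    if len(dataset) < 2:
        raise InteinSiteError("leave-one-out requires at least 2 exteins")

    target_native = target.native_sites[0]
    candidates = enumerate_candidate_sites(target)
    decoy_pos = [c.position for c in candidates if c.position != target_native]
    if target_native not in {c.position for c in candidates}:
        raise InteinSiteError(
            f"native site {target_native} of {target_extein!r} has no "
            "complete cassette"
        )
    if not decoy_pos:
        raise UndefinedRankError(
            f"extein {target_extein!r} has a single candidate site; "
            "rank undefined"
        )

    others = [ext for ext in dataset if ext.id != target_extein]
    positives = [c for ext in others for c in _native_cassettes(ext)]
    target_vec = encode_cassette(extract_cassette(target, target_native)).v
    decoy_vecs = _encode_many(
        [extract_cassette(target, p) for p in decoy_pos]
    )

    rng = np.random.default_rng(seed)
    ranks = []
    for _ in range(repeats):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", InteinSiteWarning)
            negatives = [
                c
                for ext in others
                for c in sample_decoys(ext, n=n_decoys, seed=rng)
            ]
        model = train_svm(positives, negatives, cost_factor=cost_factor, C=C)
        s_native = float(model.weights @ target_vec + model.bias)
        s_decoys = decoy_vecs @ model.weights + model.bias
        below = np.sum(s_decoys < s_native) + 0.5 * np.sum(
            s_decoys == s_native
        )
        ranks.append(below / len(decoy_pos))
    return float(np.mean(ranks))


def planted_motif_benchmark(
    n_exteins: int = 15,
    n_candidates: int = 12,
    repeats: int = 5,
    seed: int = 0,
    shuffled: bool = False,
) -> float:
    """Mean LOOCV native rank on a synthetic planted-motif extein family.

    Generates ``n_exteins`` exteins whose native cassettes share a
    two-residue motif, optionally moves the native labels to random decoy
    sites (``shuffled``, the chance-level control), and returns the mean
    leave-one-extein-out native rank across all exteins.
    """
    from .core_io import generate_extein_set, shuffle_native_labels

    dataset = generate_extein_set(
        n_exteins=n_exteins, n_candidates=n_candidates, seed=seed
    )
    if shuffled:
        dataset = shuffle_native_labels(dataset, seed=seed + 1)
    ranks = [
        loocv_rank(dataset, ext.id, repeats=repeats, seed=seed + 2 + k)
        for k, ext in enumerate(dataset)
    ]
    return float(np.mean(ranks))


# ---------------------------------------------------------------------------
# Plain-text interchange
# ---------------------------------------------------------------------------

def read_cassette_table(path_or_text) -> list[dict]:
    """Read a cassette TSV: extein_id, position, cassette (7 letters), label.

    Returns one dict per row with keys ``extein_id``, ``position``,
    ``cassette`` (:class:`~inteinsite.core_io.Cassette`) and ``label``
    (bool).  This is the interchange format for external cassette sets
    such as curated intein-database extracts.
    """
    import os

    if isinstance(path_or_text, (str, os.PathLike)) and "\n" not in str(
        path_or_text
    ):
        with open(path_or_text) as fh:
            text = fh.read()
    else:
        text = str(path_or_text)
    rows = []
    for k, ln in enumerate(text.strip().splitlines()):
        if not ln.strip() or ln.startswith("#"):
            continue
        toks = ln.split("\t")
        if toks[0] == "extein_id":
            continue
        if len(toks) < 4:
            raise InteinSiteError(
                f"cassette table line {k + 1}: expected 4 tab-separated "
                f"fields, got {len(toks)}"
            )
        seven = toks[2].strip().upper()
        if len(seven) != 7:
            raise InteinSiteError(
                f"cassette table line {k + 1}: cassette {seven!r} is not "
                "7 residues"
            )
        rows.append(
            {
                "extein_id": toks[0],
                "position": int(toks[1]),
                "cassette": Cassette(
                    residues_minus=seven[:3],
                    plus_one=seven[3],
                    residues_plus=seven[4:],
                ),
                "label": toks[3].strip().lower() in {"1", "true", "x", "pos"},
            }
        )
    return rows


def write_cassette_table(path, rows: Iterable[Mapping]) -> None:
    """Inverse of :func:`read_cassette_table`."""
    with open(path, "w") as fh:
        fh.write("extein_id\tposition\tcassette\tlabel\n")
        for r in rows:
            fh.write(
                f"{r['extein_id']}\t{r['position']}\t"
                f"{r['cassette'].seven}\t{int(bool(r['label']))}\n"
            )


def save_model(path, model: LinearSVMModel) -> None:
    """Persist a model as plain text: one weight per line, then the bias."""
    with open(path, "w") as fh:
        fh.write(f"# inteinsite linear cassette SVM; cost_factor="
                 f"{model.cost_factor} C={model.C}\n")
        for w in model.weights:
            fh.write(f"{float(w)!r}\n")
        fh.write(f"bias {float(model.bias)!r}\n")


def load_model(path) -> LinearSVMModel:
    """Read a model written by :func:`save_model`."""
    weights = []
    bias = None
    cost_factor, C = 3.0, None
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                for tok in ln.split():
                    if tok.startswith("cost_factor="):
                        cost_factor = float(tok.split("=", 1)[1])
                    elif tok.startswith("C=") and tok != "C=None":
                        C = float(tok.split("=", 1)[1])
                continue
            if ln.startswith("bias"):
                bias = float(ln.split()[1])
            else:
                weights.append(float(ln))
    if bias is None or len(weights) != N_FEATURES:
        raise InteinSiteError(f"malformed model file {path}")
    return LinearSVMModel(
        weights=np.array(weights), bias=bias, cost_factor=cost_factor, C=C
    )
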