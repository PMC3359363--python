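"""Combined insertion-site prediction from the four features.

Each feature is turned into a boolean call at its optimal cutoff from the
native-intein ROC analysis: distance to the active site / dimer interface
< 14.1 A, cassette SVM score > 0, secondary-structure junction distance
<= 2 residues, conservation rank > 0.61.  The combined rule requires a
configurable subset of calls jointly; the default conjunction
{conservation, svm, distance} is the one that isolates S112, S158 and
T164 -- all experimentally splice-competent -- among the 20 XynB sites.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cassette_svm import LinearSVMModel, score_cassette
from .core_io import extract_cassette
from .conservation import PSSMatrix, conservation_ranks, entropy_profile
from .core_io import (
    CandidateSite,
    ExteinRecord,
    SiteFeatureRow,
    SnapshotSet,
    StructureContext,
    enumerate_candidate_sites,
)
from .errors import (
    AnnotationError,
    InteinSiteError,
    InteinSiteWarning,
    MissingFeatureError,
    UndefinedRankError,
)
from .evaluation import ROCCurve, confusion_rates, roc_sweep
from .structure_features import classify_site_ss, distance_to_functional_site

__all__ = [
    "PREDICTORS",
    "PredictorConfig",
    "SiteVerdict",
    "call_site",
    "run_case_study",
    "CaseStudyReport",
    "predict_extein",
]

#: The four per-feature predictors, in reporting order.
PREDICTORS = ("distance", "svm", "junction", "conservation")


@dataclass(frozen=True)
class PredictorConfig:
    """Cutoffs and combination rule for the per-feature predictors.

    Boundary semantics are fixed: distance strictly below its cutoff, SVM
    score and conservation rank strictly above theirs, junction distance
    at-or-below its cutoff.
    """

    distance_cutoff: float = 14.1       # Angstrom
    svm_cutoff: float = 0.0
    junction_cutoff: float = 2.0        # residues
    conservation_cutoff: float = 0.61   # rank in [0, 1]
    combined_rule: frozenset[str] = frozenset(
        {"conservation", "svm", "distance"}
    )

    def __post_init__(self) -> None:
        for name in (
            "distance_cutoff",
            "svm_cutoff",
            "junction_cutoff",
            "conservation_cutoff",
        ):
            if not math.isfinite(getattr(self, name)):
                raise InteinSiteError(f"{name} must be finite")
        rule = frozenset(self.combined_rule)
        object.__setattr__(self, "combined_rule", rule)
        if not rule:
            raise InteinSiteError("combined_rule must name >= 1 predictor")
        unknown = rule - set(PREDICTORS)
        if unknown:
            raise InteinSiteError(f"unknown predictors in rule: {sorted(unknown)}")


@dataclass(frozen=True)
class SiteVerdict:
    """Per-predictor boolean calls and the combined verdict for one site.

    A call is ``None`` when its feature was unavailable; under the
    conservative missing-feature policy a ``None`` call fails the
    combined rule.
    """

    features: SiteFeatureRow
    calls: Mapping[str, bool | None]
    combined: bool
    missing: frozenset[str] = frozenset()

    @property
    def n_satisfied(self) -> int:
        return sum(1 for v in self.calls.values() if v)


def _feature_value(features: SiteFeatureRow, predictor: str):
    return {
        "distance": features.distance_to_functional_site,
        "svm": features.svm_score,
        "junction": features.junction_distance,
        "conservation": features.conservation_rank,
    }[predictor]


def call_site(
    features: SiteFeatureRow,
    config: PredictorConfig | None = None,
    allow_missing: bool = False,
) -> SiteVerdict:
    """Apply the four cutoff predictors and the combined rule to one site.

    A feature that is absent yields call ``None``; if it is required by
    ``config.combined_rule`` this raises
    :class:`~inteinsite.errors.MissingFeatureError` unless
    ``allow_missing`` is set, in which case the missing call conservatively
    fails the combined rule and the feature is reported in ``missing``.
    """
    config = config or PredictorConfig()
    values = {p: _feature_value(features, p) for p in PREDICTORS}
    missing = {p for p, v in values.items() if v is None}
    required_missing = missing & config.combined_rule
    if required_missing and not allow_missing:
        raise MissingFeatureError(
            f"feature(s) {sorted(required_missing)} required by the "
            "combined rule are missing"
        )
    calls: dict[str, bool | None] = {}
    for p, v in values.items():
        if v is None:
            calls[p] = None
        elif p == "distance":
            calls[p] = v < config.distance_cutoff
        elif p == "svm":
            calls[p] = v > config.svm_cutoff
        elif p == "junction":
            calls[p] = v <= config.junction_cutoff
        else:
            calls[p] = v > config.conservation_cutoff
    combined = all(bool(calls[p]) for p in config.combined_rule)
    return SiteVerdict(
        features=features,
        calls=calls,
        combined=combined,
        missing=frozenset(missing),
    )


def _site_name(row: SiteFeatureRow) -> str:
    return f"{row.site.plus_one_residue}{row.site.position}"


@dataclass(frozen=True)
class CaseStudyReport:
    """Output of :func:`run_case_study`."""

    verdicts: tuple[SiteVerdict, ...]
    per_predictor: Mapping[str, dict]       # confusion counts + rates
    combined_sites: tuple[str, ...]         # e.g. ("S112", "S158", "T164")
    combined_confusion: dict
    roc: Mapping[str, ROCCurve]


#: Cutoff grids for the per-feature ROC sweeps: (start, stop, step).
_ROC_GRIDS = {
    "distance": (0.0, 30.0, 0.1),
    "svm": (-10.0, 10.0, 0.01),
    "junction": (0.0, 5.0, 1.0),
    "conservation": (0.0, 1.0, 0.01),
}
_ORIENTATIONS = {
    "distance": "less",
    "svm": "greater",
    "junction": "leq",
    "conservation": "greater",
}


def run_case_study(
    table: Sequence[SiteFeatureRow],
    config: PredictorConfig | None = None,
) -> CaseStudyReport:
    """Apply the predictors to a labelled feature table (the XynB design).

    Rows without a splicing label are excluded with a warning.  Returns
    per-predictor confusion rates against the splicing labels, the
    combined-rule site list, and a per-feature ROC sweep over the stated
    cutoff ranges.
    """
    config = config or PredictorConfig()
    if not table:
        raise InteinSiteError("empty feature table")
    labelled = [r for r in table if r.splicing_label is not None]
    dropped = len(table) - len(labelled)
    if dropped:
        warnings.warn(
            f"{dropped} unlabelled row(s) excluded from the case study",
            InteinSiteWarning,
            stacklevel=2,
        )
    if not labelled:
        raise InteinSiteError("no labelled rows in feature table")

    verdicts = tuple(
        call_site(r, config, allow_missing=True) for r in labelled
    )
    labels = [bool(r.splicing_label) for r in labelled]

    per_predictor = {}
    roc: dict[str, ROCCurve] = {}
    for p in PREDICTORS:
        preds = [bool(v.calls[p]) for v in verdicts]
        per_predictor[p] = confusion_rates(labels, preds)
        values = [_feature_value(r, p) for r in labelled]
        if any(v is None for v in values):
            continue
        lo, hi, step = _ROC_GRIDS[p]
        grid = np.arange(lo, hi + step / 2, step)
        roc[p] = roc_sweep(values, labels, grid, _ORIENTATIONS[p])

    combined = [v for v in verdicts if v.combined]
    combined_names = tuple(_site_name(v.features) for v in combined)
    combined_confusion = confusion_rates(
        labels, [v.combined for v in verdicts]
    )
    return CaseStudyReport(
        verdicts=verdicts,
        per_predictor=per_predictor,
        combined_sites=combined_names,
        combined_confusion=combined_confusion,
        roc=roc,
    )


def predict_extein(
    extein: ExteinRecord,
    pssm: PSSMatrix | None = None,
    structure: StructureContext | None = None,
    ss_codes: Mapping[int, str] | None = None,
    model: LinearSVMModel | None = None,
    snapshots: SnapshotSet | None = None,
    config: PredictorConfig | None = None,
) -> list[SiteVerdict]:
    """End-to-end site nomination for one extein.

    Enumerates candidate C/S/T sites, computes every feature whose inputs
    were supplied (conservation rank needs the PSSM, SVM score a trained
    model, distance/junction/burial the structure, flexibility the
    snapshots), applies the cutoff calls with the conservative
    missing-feature policy, and returns verdicts sorted by number of
    satisfied predictors, then conservation rank (descending), then
    position.  An extein with no candidates returns an empty list with a
    warning.
    """
    config = config or PredictorConfig()
    candidates = enumerate_candidate_sites(extein)
    if not candidates:
        warnings.warn(
            f"extein {extein.id!r} has no candidate C/S/T site",
            InteinSiteWarning,
            stacklevel=2,
        )
        return []

    if structure is not None:
        mapped = set(structure.ca_coords)
        out_of_range = {p for p in mapped if not 1 <= p <= len(extein)}
        if out_of_range:
            raise InteinSiteError(
                f"structure maps to positions outside the extein "
                f"sequence: {sorted(out_of_range)[:5]} ... -- numbering "
                "mismatch between structure map and sequence"
            )

    ranks: dict[int, float] = {}
    if pssm is not None and len(candidates) >= 2:
        ranks = conservation_ranks(entropy_profile(pssm), candidates)

    codes = ss_codes
    if codes is None and structure is not None and structure.ss_codes:
        codes = structure.ss_codes

    verdicts = []
    for cand in candidates:
        row = SiteFeatureRow(site=cand)
        row.conservation_rank = ranks.get(cand.position)
        if model is not None:
            row.svm_score = score_cassette(
                model, extract_cassette(extein, cand.position)
            )
        if structure is not None:
            try:
                row.distance_to_functional_site = distance_to_functional_site(
                    structure, cand.position, which="either"
                )
            except (AnnotationError, InteinSiteError):
                pass
            from .structure_features import cbeta_density

            if cand.position in structure.cb_coords:
                row.cbeta_density = cbeta_density(structure, cand.position)
        if codes is not None:
            ctx = classify_site_ss(codes, cand.position)
            if ctx.bin == "other" and not math.isfinite(ctx.junction_distance):
                row.junction_distance = None  # unknown-code gap: undefined
            else:
                # may be inf ("more than 2"), which simply fails the call
                row.junction_distance = ctx.junction_distance
        if snapshots is not None:
            from .structure_features import site_flexibility

            try:
                row.flexibility_rmsd = site_flexibility(
                    snapshots, cand.position
                ).rmsd
            except InteinSiteError:
                pass
        verdicts.append(call_site(row, config, allow_missing=True))

    verdicts.sort(
        key=lambda v: (
            -v.n_satisfied,
            -(v.features.conservation_rank or 0.0),
            v.features.site.position,
        )
    )
    return verdicts
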