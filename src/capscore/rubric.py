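"""The five-category ordinal capillary rubric.

Each skeletal-muscle capillary cross-section receives a score of 0, 1 or 2
in five categories:

====================  =========================  =========================  ==========================
category              0                          1                          2
====================  =========================  =========================  ==========================
BM thickening         50–100 nm                  100–200 nm                 200+ nm
BM reduplication      single lamina              2–3 layers                 4+ layers
endothelial           none                       mild (increased area       marked
activation                                       and/or organelles)
ensheathment          0–4 processes              5–6 processes (not only    7+ processes (also
                                                 focal and small)           depending on size)
TRI                   none                       2 small- or 1 medium-      2+ medium- or 1+
                                                 sized inclusion            large-sized inclusion
====================  =========================  =========================  ==========================

The first four categories sum to a per-capillary score in 0..8 (the TRI
category is reported but never summed); averaging that sum over a biopsy's
capillaries yields the case-level AS statistic computed in
:mod:`capscore.cohort`.

Thickness and count bands are half-open on the right ("200+" includes
exactly 200 nm).  Basement membranes thinner than the 50 nm floor of the
normal band are scored 0: thinner-than-normal is not pathological
thickening.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import ActivationConfig, RubricConfig, ScoringThresholds, TriSizeClasses
from .errors import InvalidInputError

__all__ = [
    "SizeClass",
    "ActivationGrade",
    "OrganelleProminence",
    "ProcessProminence",
    "TriObservation",
    "CapillaryFeatures",
    "CapillaryScore",
    "AS_CATEGORIES",
    "CATEGORIES",
    "score_bm_thickening",
    "score_bm_reduplication",
    "score_endothelial_activation",
    "score_ensheathment",
    "score_tri",
    "score_capillary",
    "score_features_frame",
]

logger = logging.getLogger(__name__)

#: The four categories whose per-capillary scores are summed (TRI excluded).
AS_CATEGORIES: tuple[str, ...] = (
    "bm_thickening",
    "bm_reduplication",
    "endothelial_activation",
    "ensheathment",
)
#: All five scored categories.
CATEGORIES: tuple[str, ...] = AS_CATEGORIES + ("tri",)


class SizeClass(str, Enum):
    """Size class of a tubuloreticular inclusion."""

    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"


class ActivationGrade(str, Enum):
    """Visually assigned endothelial-activation grade."""

    NONE = "none"
    MILD = "mild"
    MARKED = "marked"


class OrganelleProminence(str, Enum):
    """Prominence of endothelial membrane organelles."""

    NONE = "none"
    INCREASED = "increased"
    MARKED = "marked"


class ProcessProminence(str, Enum):
    """Visual qualifier of the ensheathing pericyte/endothelial processes."""

    FOCAL_SMALL = "focal_small"
    PROMINENT = "prominent"
    VERY_PROMINENT = "very_prominent"


@dataclass(frozen=True)
class TriObservation:
    """One or more tubuloreticular inclusions of a single size class."""

    size_class: SizeClass
    count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "size_class", SizeClass(self.size_class))
        if not isinstance(self.count, (int, np.integer)) or self.count < 1:
            raise InvalidInputError(f"TRI count must be an integer >= 1, got {self.count!r}")


@dataclass
class CapillaryFeatures:
    """Raw measurable observations for one capillary cross-section.

    Any of the category-defining fields may be ``None`` when the structure
    could not be assessed (a degraded capillary, an annotation that failed a
    measurement); the scorer records such categories as missing.  Endothelial
    activation is supplied either as an explicit ``activation_grade`` or as
    the raw pair (``endothelial_area_um2``, ``organelle_prominence``).
    """

    bm_thickness_nm: float | None = None
    bm_layer_count: int | None = None
    activation_grade: ActivationGrade | str | None = None
    endothelial_area_um2: float | None = None
    organelle_prominence: OrganelleProminence | str | None = None
    process_count: int | None = None
    process_prominence: ProcessProminence | str = ProcessProminence.PROMINENT
    tri: Sequence[TriObservation] | None = ()
    degraded: bool = False

    def __post_init__(self) -> None:
        if self.activation_grade is not None:
            self.activation_grade = ActivationGrade(self.activation_grade)
        if self.organelle_prominence is not None:
            self.organelle_prominence = OrganelleProminence(self.organelle_prominence)
        self.process_prominence = ProcessProminence(self.process_prominence)
        if self.tri is not None:
            self.tri = tuple(self.tri)


@dataclass(frozen=True)
class CapillaryScore:
    """Five ordinal category scores plus the four-category sum.

    Categories that could not be assessed are listed in ``missing`` and
    contribute 0 to ``four_category_sum``; a capillary with all four summed
    categories missing is flagged ``fully_missing`` and should be excluded
    from the capillary count N of its case.
    """

    bm_thickening: int
    bm_reduplication: int
    endothelial_activation: int
    ensheathment: int
    tri: int
    missing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in CATEGORIES:
            value = getattr(self, name)
            if value not in (0, 1, 2):
                raise InvalidInputError(f"{name} score must be 0, 1 or 2, got {value!r}")
        unknown = set(self.missing) - set(CATEGORIES)
        if unknown:
            raise InvalidInputError(f"unknown missing categories: {sorted(unknown)}")

    @property
    def four_category_sum(self) -> int:
        return (
            self.bm_thickening
            + self.bm_reduplication
            + self.endothelial_activation
            + self.ensheathment
        )

    @property
    def fully_missing(self) -> bool:
        return all(c in self.missing for c in AS_CATEGORIES)


def _check_finite_positive(value: float, what: str) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError) as exc:
        raise InvalidInputError(f"{what} must be a number, got {value!r}") from exc
    if not math.isfinite(value) or value <= 0:
        raise InvalidInputError(f"{what} must be positive and finite, got {value}")
    return value


def score_bm_thickening(
    thickness_nm: float, thresholds: ScoringThresholds | None = None
) -> int:
    """Score basement-membrane thickening: 0 below 100 nm, 1 in [100, 200) nm,
    2 at 200 nm and above (default cuts)."""
    thresholds = thresholds or ScoringThresholds()
    thickness_nm = _check_finite_positive(thickness_nm, "BM thickness")
    if thickness_nm < thresholds.bm_cut_1_nm:
        return 0
    if thickness_nm < thresholds.bm_cut_2_nm:
        return 1
    return 2


def score_bm_reduplication(
    layer_count: int, thresholds: ScoringThresholds | None = None
) -> int:
    """Score reduplication by layer count: single lamina 0, 2–3 layers 1,
    4 or more layers 2 (default cuts)."""
    thresholds = thresholds or ScoringThresholds()
    if not isinstance(layer_count, (int, np.integer)) or isinstance(layer_count, bool):
        raise InvalidInputError(f"layer count must be an integer, got {layer_count!r}")
    if layer_count < 1:
        raise InvalidInputError(f"layer count must be >= 1, got {layer_count}")
    if layer_count < thresholds.layers_cut_1:
        return 0
    if layer_count < thresholds.layers_cut_2:
        return 1
    return 2


_GRADE_SCORE = {ActivationGrade.NONE: 0, ActivationGrade.MILD: 1, ActivationGrade.MARKED: 2}
_ORGANELLE_SCORE = {
    OrganelleProminence.NONE: 0,
    OrganelleProminence.INCREASED: 1,
    OrganelleProminence.MARKED: 2,
}


def score_endothelial_activation(
    features: CapillaryFeatures, config: ActivationConfig | None = None
) -> int:
    """Score endothelial activation.

    An explicit visual grade (none/mild/marked) maps directly to 0/1/2.
    Otherwise the raw endothelial cross-sectional area is banded relative to
    the configured reference area and combined with the organelle-prominence
    level by a max rule, so either an enlarged endothelium or prominent
    organelles alone suffices for the corresponding grade.
    """
    config = config or ActivationConfig()
    if features.activation_grade is not None:
        return _GRADE_SCORE[ActivationGrade(features.activation_grade)]
    if features.endothelial_area_um2 is None:
        raise InvalidInputError(
            "endothelial activation needs either activation_grade or "
            "endothelial_area_um2 (with optional organelle_prominence)"
        )
    area = _check_finite_positive(features.endothelial_area_um2, "endothelial area")
    ratio = area / config.reference_area_um2
    if ratio >= config.marked_ratio:
        area_score = 2
    elif ratio >= config.mild_ratio:
        area_score = 1
    else:
        area_score = 0
    organelle = features.organelle_prominence or OrganelleProminence.NONE
    return max(area_score, _ORGANELLE_SCORE[OrganelleProminence(organelle)])


def score_ensheathment(
    process_count: int,
    prominence: ProcessProminence | str = ProcessProminence.PROMINENT,
    thresholds: ScoringThresholds | None = None,
) -> int:
    """Score capillary ensheathment by pericyte/endothelial process count.

    0–4 processes score 0, 5–6 score 1, 7+ score 2 (default cuts).  The
    rubric's size caveats ("not only focal and small", "also depending on
    size") are encoded as a prominence qualifier: processes that are only
    focal and small demote the count-derived score by one level.
    """
    thresholds = thresholds or ScoringThresholds()
    if not isinstance(process_count, (int, np.integer)) or isinstance(process_count, bool):
        raise InvalidInputError(f"process count must be an integer, got {process_count!r}")
    if process_count < 0:
        raise InvalidInputError(f"process count must be >= 0, got {process_count}")
    prominence = ProcessProminence(prominence)
    if process_count >= thresholds.proc_cut_2:
        base = 2
    elif process_count >= thresholds.proc_cut_1:
        base = 1
    else:
        base = 0
    if prominence is ProcessProminence.FOCAL_SMALL:
        base = max(base - 1, 0)
    return base


def score_tri(tri: Iterable[TriObservation] | None) -> int:
    """Score tubuloreticular inclusions.

    No inclusions (or a single small one) score 0; two small or one medium
    inclusion score 1; two or more medium, or any large inclusion, score 2.
    Mixed observation lists take the maximum applicable score.
    """
    counts = {SizeClass.SMALL: 0, SizeClass.MEDIUM: 0, SizeClass.LARGE: 0}
    for obs in tri or ():
        if not isinstance(obs, TriObservation):
            obs = TriObservation(*obs) if isinstance(obs, tuple) else TriObservation(obs)
        counts[SizeClass(obs.size_class)] += obs.count
    if counts[SizeClass.LARGE] >= 1 or counts[SizeClass.MEDIUM] >= 2:
        return 2
    if counts[SizeClass.MEDIUM] == 1 or counts[SizeClass.SMALL] >= 2:
        return 1
    return 0


def score_capillary(
    features: CapillaryFeatures,
    thresholds: ScoringThresholds | None = None,
    config: RubricConfig | ActivationConfig | None = None,
) -> CapillaryScore:
    """Score one capillary in all five categories.

    Categories whose defining features are absent (``None``) are recorded as
    missing and scored 0; this keeps the four-category sum defined for
    degraded capillaries that remain partially measurable.  A capillary with
    no measurable summed category at all is flagged fully missing.  Errors
    raised by a category scorer are re-raised with the category named.
    """
    thresholds = thresholds or ScoringThresholds()
    if isinstance(config, RubricConfig):
        activation_cfg: ActivationConfig | None = config.activation
    else:
        activation_cfg = config

    missing: list[str] = []
    scores: dict[str, int] = {}

    def _apply(name: str, available: bool, fn) -> None:
        if not available:
            missing.append(name)
            scores[name] = 0
            return
        try:
            scores[name] = fn()
        except InvalidInputError as exc:
            raise InvalidInputError(f"category {name!r}: {exc}") from exc

    _apply(
        "bm_thickening",
        features.bm_thickness_nm is not None,
        lambda: score_bm_thickening(features.bm_thickness_nm, thresholds),
    )
    _apply(
        "bm_reduplication",
        features.bm_layer_count is not None,
        lambda: score_bm_reduplication(features.bm_layer_count, thresholds),
    )
    _apply(
        "endothelial_activation",
        features.activation_grade is not None or features.endothelial_area_um2 is not None,
        lambda: score_endothelial_activation(features, activation_cfg),
    )
    _apply(
        "ensheathment",
        features.process_count is not None,
        lambda: score_ensheathment(features.process_count, features.process_prominence, thresholds),
    )
    _apply("tri", features.tri is not None, lambda: score_tri(features.tri))

    if missing:
        as_missing = [m for m in missing if m in AS_CATEGORIES]
        if len(as_missing) == len(AS_CATEGORIES):
            logger.warning("capillary has no measurable summed category; flagged fully missing")
        elif as_missing:
            logger.warning(
                "capillary categories %s unmeasurable; treated as 0 in the four-category sum",
                as_missing,
            )
    return CapillaryScore(missing=tuple(missing), **scores)


# ---------------------------------------------------------------------------
# Vectorised batch scoring
# ---------------------------------------------------------------------------

_PROMINENCE_CODES = {p.value: i for i, p in enumerate(ProcessProminence)}
_ORGANELLE_CODES = {p.value: i for i, p in enumerate(OrganelleProminence)}
_GRADE_CODES = {g.value: i for i, g in enumerate(ActivationGrade)}


def score_features_frame(
    frame: pd.DataFrame,
    thresholds: ScoringThresholds | None = None,
    config: RubricConfig | ActivationConfig | None = None,
) -> pd.DataFrame:
    """Score a whole feature table at once with numpy banding.

    ``frame`` uses the canonical feature-table columns (see
    :mod:`capscore.io`): ``bm_thickness_nm``, ``bm_layer_count``,
    ``activation_grade`` or (``endothelial_area_um2``,
    ``organelle_prominence``), ``process_count``, ``process_prominence`` and
    TRI counts ``tri_small``/``tri_medium``/``tri_large``.  Missing values
    (NaN/empty) mark the category missing, mirroring the scalar scorer.
    Returns a DataFrame with one 0/1/2 column per category, the
    ``four_category_sum`` and a ``fully_missing`` flag, preserving the input
    index.
    """
    thresholds = thresholds or ScoringThresholds()
    if isinstance(config, RubricConfig):
        activation_cfg = config.activation
    else:
        activation_cfg = config or ActivationConfig()

    n = len(frame)
    out = pd.DataFrame(index=frame.index)

    def _col(name: str) -> pd.Series:
        if name in frame.columns:
            return frame[name]
        return pd.Series([np.nan] * n, index=frame.index)

    # BM thickening
    thick = pd.to_numeric(_col("bm_thickness_nm"), errors="coerce").to_numpy(float)
    with np.errstate(invalid="ignore"):
        bad = np.isfinite(thick) & (thick <= 0)
    if bad.any():
        raise InvalidInputError(
            f"non-positive BM thickness in rows {list(frame.index[bad])[:5]}"
        )
    thick_missing = ~np.isfinite(thick)
    thick_score = np.where(
        thick >= thresholds.bm_cut_2_nm, 2, np.where(thick >= thresholds.bm_cut_1_nm, 1, 0)
    )
    thick_score[thick_missing] = 0

    # BM reduplication
    layers = pd.to_numeric(_col("bm_layer_count"), errors="coerce").to_numpy(float)
    layers_missing = ~np.isfinite(layers)
    if ((layers < 1) & ~layers_missing).any():
        raise InvalidInputError("bm_layer_count must be >= 1")
    layer_score = np.where(
        layers >= thresholds.layers_cut_2, 2, np.where(layers >= thresholds.layers_cut_1, 1, 0)
    )
    layer_score[layers_missing] = 0

    # Endothelial activation: explicit grade wins, raw (area, organelles) else
    grade_raw = _col("activation_grade").astype("object")
    grade_codes = grade_raw.map(lambda g: _GRADE_CODES.get(g, np.nan) if isinstance(g, str) and g else np.nan)
    grade_codes = grade_codes.to_numpy(float)
    area = pd.to_numeric(_col("endothelial_area_um2"), errors="coerce").to_numpy(float)
    ratio = area / activation_cfg.reference_area_um2
    area_score = np.where(
        ratio >= activation_cfg.marked_ratio,
        2,
        np.where(ratio >= activation_cfg.mild_ratio, 1, 0),
    )
    org_raw = _col("organelle_prominence").astype("object")
    org_codes = org_raw.map(
        lambda g: _ORGANELLE_CODES.get(g, 0) if isinstance(g, str) and g else 0
    ).to_numpy(int)
    raw_score = np.maximum(area_score, org_codes)
    have_grade = np.isfinite(grade_codes)
    have_area = np.isfinite(area)
    act_score = np.where(have_grade, np.nan_to_num(grade_codes), np.where(have_area, raw_score, 0))
    act_missing = ~(have_grade | have_area)
    act_score = act_score.astype(int)

    # Ensheathment
    procs = pd.to_numeric(_col("process_count"), errors="coerce").to_numpy(float)
    procs_missing = ~np.isfinite(procs)
    if ((procs < 0) & ~procs_missing).any():
        raise InvalidInputError("process_count must be >= 0")
    proc_base = np.where(
        procs >= thresholds.proc_cut_2, 2, np.where(procs >= thresholds.proc_cut_1, 1, 0)
    )
    prom_raw = _col("process_prominence").astype("object")
    prom = prom_raw.map(
        lambda p: p if isinstance(p, str) and p else ProcessProminence.PROMINENT.value
    )
    unknown_prom = set(prom) - set(_PROMINENCE_CODES)
    if unknown_prom:
        raise InvalidInputError(f"unknown process prominence values: {sorted(unknown_prom)}")
    focal = (prom == ProcessProminence.FOCAL_SMALL.value).to_numpy()
    proc_score = np.where(focal, np.maximum(proc_base - 1, 0), proc_base)
    proc_score[procs_missing] = 0

    # TRI from per-size counts; all three counts NaN => missing
    tri_s = pd.to_numeric(_col("tri_small"), errors="coerce").to_numpy(float)
    tri_m = pd.to_numeric(_col("tri_medium"), errors="coerce").to_numpy(float)
    tri_l = pd.to_numeric(_col("tri_large"), errors="coerce").to_numpy(float)
    tri_missing = ~np.isfinite(tri_s) & ~np.isfinite(tri_m) & ~np.isfinite(tri_l)
    tri_s, tri_m, tri_l = (np.nan_to_num(v) for v in (tri_s, tri_m, tri_l))
    tri_score = np.where(
        (tri_l >= 1) | (tri_m >= 2), 2, np.where((tri_m == 1) | (tri_s >= 2), 1, 0)
    )
    tri_score[tri_missing] = 0

    out["bm_thickening"] = thick_score.astype(int)
    out["bm_reduplication"] = layer_score.astype(int)
    out["endothelial_activation"] = act_score
    out["ensheathment"] = proc_score.astype(int)
    out["tri"] = tri_score.astype(int)
    out["four_category_sum"] = (
        out["bm_thickening"]
        + out["bm_reduplication"]
        + out["endothelial_activation"]
        + out["ensheathment"]
    )
    out["fully_missing"] = thick_missing & layers_missing & act_missing & procs_missing
    return out
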