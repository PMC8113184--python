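"""Synthetic cohort and phantom generation.

No per-capillary human scores underlying the published group statistics are
deposited anywhere, so everything downstream of the rubric is exercised on
synthetic cohorts whose *marginal* structure matches what is printed: per
study group (MMCP, non-MMCP, dermatomyositis, anti-synthetase syndrome,
non-diseased control) a :class:`GroupProfile` specifies per-category score
probabilities whose implied expected AS equals the published group mean,
plus distributions for VAS, findings flags and clinical covariates.

Case-to-case severity heterogeneity is modelled with a proportional-odds
case effect: each case draws a latent shift ``delta ~ N(0, sigma)`` applied
to the cumulative logits of every category.  The baseline cut-points are
re-calibrated numerically (Gauss–Hermite quadrature) so that the
delta-marginal category probabilities equal the profile's stated
probabilities exactly — the case effect widens the per-case AS spread
without moving the group mean.

Each drawn ordinal score is then *inverted* into a raw feature value sampled
uniformly inside the corresponding rubric band (a thickening score of 1
becomes a thickness in [100, 200) nm, and so on), so re-scoring the feature
table through :mod:`capscore.rubric` reproduces the drawn scores exactly.
:func:`synthesize_geometry` goes one step further and builds a polygonal
phantom from a feature record for exercising :mod:`capscore.morphometry`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from shapely.geometry import Polygon

from .config import ActivationConfig, RubricConfig
from .cohort import (
    CaseRecord,
    ClinicalRecord,
    FindingsFlags,
    GROUP_LABELS,
    LightMicroscopyScore,
    case_table,
)
from .errors import ConfigError
from .morphometry import CapillaryGeometry, ProcessAnnotation, TriMark
from .rubric import (
    AS_CATEGORIES,
    CATEGORIES,
    CapillaryFeatures,
    CapillaryScore,
    ProcessProminence,
    SizeClass,
    TriObservation,
)

__all__ = [
    "GroupProfile",
    "CohortConfig",
    "CohortResult",
    "default_cohort_config",
    "expected_as",
    "simulate_case",
    "simulate_cohort",
    "synthesize_geometry",
]

_PROB_TOL = 1e-9


def _validate_probs(p: Sequence[float], what: str) -> tuple[float, float, float]:
    p = tuple(float(v) for v in p)
    if len(p) != 3 or any(v < 0 or v > 1 for v in p) or abs(sum(p) - 1.0) > _PROB_TOL:
        raise ConfigError(f"{what}: probabilities must be a 3-vector summing to 1, got {p}")
    return p


@dataclass(frozen=True)
class GroupProfile:
    """Generative description of one study group.

    ``score_probs`` maps each of the five rubric categories to the marginal
    probabilities (p0, p1, p2) of scoring 0/1/2.  ``case_severity_sd`` is
    the SD of the proportional-odds case effect (0 disables it).  TRI is
    modelled case-level: a case harbours TRI-bearing capillaries with
    probability ``tri_case_probability``, in which case its capillaries use
    ``score_probs['tri']``; otherwise every capillary is TRI-free.
    """

    label: str
    n_cases: int
    score_probs: Mapping[str, tuple[float, float, float]]
    case_severity_sd: float = 0.0
    tri_case_probability: float = 0.0
    capillaries_per_case: int = 100
    vas_mean: float = 5.0
    vas_sd: float = 2.0
    myophagocytosis_p: float = 0.0
    nuclear_inclusions_p: float = 0.0
    htype_labels: tuple[str, ...] = ()
    age_mean: float = 54.0
    age_sd: float = 13.0
    ck_mean: float | None = None
    ck_sd: float | None = None
    lcssc_p: float | None = None
    ild_p: float | None = None
    cardiac_p: float | None = None
    digital_ulcers_p: float | None = None

    def __post_init__(self) -> None:
        if self.label not in GROUP_LABELS:
            raise ConfigError(f"unknown group label {self.label!r}")
        if self.n_cases < 1:
            raise ConfigError("n_cases must be >= 1")
        if not (1 <= self.capillaries_per_case <= 100):
            raise ConfigError("capillaries_per_case must be in 1..100")
        if self.case_severity_sd < 0:
            raise ConfigError("case_severity_sd must be >= 0")
        probs = dict(self.score_probs)
        missing = set(CATEGORIES) - set(probs)
        if missing:
            raise ConfigError(f"score_probs missing categories: {sorted(missing)}")
        for cat in CATEGORIES:
            probs[cat] = _validate_probs(probs[cat], f"{self.label}/{cat}")
        object.__setattr__(self, "score_probs", probs)
        for name in ("tri_case_probability", "myophagocytosis_p", "nuclear_inclusions_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class CohortConfig:
    """A list of group profiles plus the master seed and the sub-100-sample
    rule: ``n_short_samples`` randomly chosen cases are given a capillary
    count drawn uniformly from [short_low, short_high] instead of their
    profile's nominal 100."""

    profiles: tuple[GroupProfile, ...]
    master_seed: int = 0
    n_short_samples: int = 8
    short_low: int = 40
    short_high: int = 99

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ConfigError("at least one group profile required")
        total = sum(p.n_cases for p in self.profiles)
        if self.n_short_samples > total:
            raise ConfigError("n_short_samples exceeds total number of cases")
        if not (1 <= self.short_low <= self.short_high <= 100):
            raise ConfigError("require 1 <= short_low <= short_high <= 100")


@dataclass
class CohortResult:
    """In-memory result of a cohort simulation."""

    cases: list[CaseRecord]
    features: pd.DataFrame
    case_frame: pd.DataFrame
    config: CohortConfig


def expected_as(profile: GroupProfile) -> float:
    """Analytic expected per-capillary four-category sum (= expected AS)
    implied by the profile's marginal score probabilities."""
    return float(
        sum(
            profile.score_probs[cat][1] + 2.0 * profile.score_probs[cat][2]
            for cat in AS_CATEGORIES
        )
    )


# ---------------------------------------------------------------------------
# Proportional-odds calibration
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(41)


def _marginal_cumulative(theta: float, sigma: float) -> float:
    """E_{delta ~ N(0, sigma)}[expit(theta - delta)] by Gauss–Hermite."""
    deltas = math.sqrt(2.0) * sigma * _GH_NODES
    return float(np.sum(_GH_WEIGHTS * expit(theta - deltas)) / math.sqrt(math.pi))


def _calibrate_cut(target: float, sigma: float) -> float:
    """Cumulative-logit cut-point whose delta-marginal probability is
    ``target``; infinities handle degenerate categories."""
    if target <= _PROB_TOL:
        return -math.inf
    if target >= 1.0 - _PROB_TOL:
        return math.inf
    return brentq(lambda t: _marginal_cumulative(t, sigma) - target, -60.0, 60.0, xtol=1e-12)


_CUT_CACHE: dict[tuple, dict[str, tuple[float, float]]] = {}


def _calibrated_cuts(
    probs: Mapping[str, tuple[float, float, float]], sigma: float
) -> dict[str, tuple[float, float]]:
    key = (tuple(sorted((k, tuple(v)) for k, v in probs.items())), sigma)
    cached = _CUT_CACHE.get(key)
    if cached is not None:
        return cached
    cuts = {}
    for cat, (p0, p1, p2) in probs.items():
        cuts[cat] = (_calibrate_cut(p0, sigma), _calibrate_cut(p0 + p1, sigma))
    _CUT_CACHE[key] = cuts
    return cuts


def _shifted_probs(cuts: tuple[float, float], delta: float) -> np.ndarray:
    f0 = expit(cuts[0] - delta) if math.isfinite(cuts[0]) else (0.0 if cuts[0] < 0 else 1.0)
    f1 = expit(cuts[1] - delta) if math.isfinite(cuts[1]) else (0.0 if cuts[1] < 0 else 1.0)
    f1 = max(f1, f0)
    return np.array([f0, f1 - f0, 1.0 - f1])


# ---------------------------------------------------------------------------
# Score -> raw feature inversion (banded, exact on re-scoring)
# ---------------------------------------------------------------------------

_GRADE_BY_SCORE = ("none", "mild", "marked")


def _invert_scores(scores: Mapping[str, np.ndarray], rng: np.random.Generator) -> pd.DataFrame:
    """Sample raw feature values uniformly inside the rubric band of each
    drawn score, so re-scoring recovers the scores exactly."""
    n = len(scores["bm_thickening"])
    cols: dict[str, np.ndarray | list] = {}

    s = scores["bm_thickening"]
    lo = np.select([s == 0, s == 1, s == 2], [50.0, 100.0, 200.0])
    hi = np.select([s == 0, s == 1, s == 2], [100.0, 200.0, 400.0])
    # full precision: rounding could push a value across a band edge
    cols["bm_thickness_nm"] = rng.uniform(lo, hi)

    s = scores["bm_reduplication"]
    layers = np.ones(n, dtype=int)
    layers[s == 1] = rng.integers(2, 4, size=int((s == 1).sum()))
    layers[s == 2] = rng.integers(4, 7, size=int((s == 2).sum()))
    cols["bm_layer_count"] = layers

    cols["activation_grade"] = [_GRADE_BY_SCORE[v] for v in scores["endothelial_activation"]]

    s = scores["ensheathment"]
    procs = np.empty(n, dtype=int)
    procs[s == 0] = rng.integers(0, 5, size=int((s == 0).sum()))
    procs[s == 1] = rng.integers(5, 7, size=int((s == 1).sum()))
    procs[s == 2] = rng.integers(7, 11, size=int((s == 2).sum()))
    cols["process_count"] = procs
    prom = np.where(
        s == 2,
        np.where(rng.random(n) < 0.5, "very_prominent", "prominent"),
        "prominent",
    )
    cols["process_prominence"] = prom

    s = scores["tri"]
    tri_small = np.zeros(n, dtype=int)
    tri_medium = np.zeros(n, dtype=int)
    tri_large = np.zeros(n, dtype=int)
    pick = rng.random(n) < 0.5
    tri_small[(s == 1) & pick] = 2
    tri_medium[(s == 1) & ~pick] = 1
    tri_medium[(s == 2) & pick] = 2
    tri_large[(s == 2) & ~pick] = 1
    cols["tri_small"] = tri_small
    cols["tri_medium"] = tri_medium
    cols["tri_large"] = tri_large
    cols["degraded"] = np.zeros(n, dtype=bool)
    return pd.DataFrame(cols)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a log-normal with the given mean/SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    """Rejection-sampled truncated normal (cheap at these mild truncations)."""
    if sd <= 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))


def simulate_case(
    profile: GroupProfile,
    seed: int | np.random.Generator,
    case_id: str = "case-1",
    case_index: int = 0,
    n_capillaries: int | None = None,
    with_features: bool = True,
) -> tuple[CaseRecord, pd.DataFrame | None]:
    """Draw one synthetic case from a group profile.

    Returns the :class:`~capscore.cohort.CaseRecord` and, when
    ``with_features``, the per-capillary raw-feature table whose re-scoring
    reproduces the drawn category scores exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(n_capillaries if n_capillaries is not None else profile.capillaries_per_case)
    if not (1 <= n <= 100):
        raise ConfigError(f"capillary count must be in 1..100, got {n}")

    sigma = profile.case_severity_sd
    cuts = _calibrated_cuts(profile.score_probs, sigma)
    delta = rng.normal(0.0, sigma) if sigma > 0 else 0.0

    tri_case = rng.random() < profile.tri_case_probability

    scores: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        if cat == "tri" and not tri_case:
            scores[cat] = np.zeros(n, dtype=int)
            continue
        p = _shifted_probs(cuts[cat], delta) if sigma > 0 else np.asarray(
            profile.score_probs[cat]
        )
        p = np.clip(p, 0.0, None)
        p = p / p.sum()
        scores[cat] = rng.choice(3, size=n, p=p)

    capillary_scores = [
        CapillaryScore(
            bm_thickening=int(scores["bm_thickening"][i]),
            bm_reduplication=int(scores["bm_reduplication"][i]),
            endothelial_activation=int(scores["endothelial_activation"][i]),
            ensheathment=int(scores["ensheathment"][i]),
            tri=int(scores["tri"][i]),
        )
        for i in range(n)
    ]

    vas = round(_truncnorm(rng, profile.vas_mean, profile.vas_sd, 0.0, 10.0), 1)
    lm = LightMicroscopyScore(
        vas=vas,
        capillaries=int(rng.binomial(3, vas / 10.0)),
        muscle_fibers=int(rng.binomial(3, vas / 10.0)),
        endo_perimysium=int(rng.binomial(3, vas / 10.0)),
    )
    findings = FindingsFlags(
        tri_present=bool((scores["tri"] >= 1).any()),
        myophagocytosis=bool(rng.random() < profile.myophagocytosis_p),
        nuclear_inclusions=bool(rng.random() < profile.nuclear_inclusions_p),
    )
    if profile.ck_mean is not None and profile.ck_sd is not None:
        mu, s = _lognormal_params(profile.ck_mean, profile.ck_sd)
        ck = round(float(rng.lognormal(mu, s)), 0)
    else:
        ck = None
    clinical = ClinicalRecord(
        age=round(_truncnorm(rng, profile.age_mean, profile.age_sd, 18.0, 90.0), 0),
        max_ck_u_l=ck,
        cutaneous_subtype=(
            ("lcSSc" if rng.random() < profile.lcssc_p else "dcSSc")
            if profile.lcssc_p is not None
            else None
        ),
        ild=bool(rng.random() < profile.ild_p) if profile.ild_p is not None else None,
        cardiac=bool(rng.random() < profile.cardiac_p) if profile.cardiac_p is not None else None,
        digital_ulcers=(
            bool(rng.random() < profile.digital_ulcers_p)
            if profile.digital_ulcers_p is not None
            else None
        ),
    )
    htype = (
        profile.htype_labels[case_index % len(profile.htype_labels)]
        if profile.htype_labels
        else profile.label
    )
    case = CaseRecord(
        case_id=case_id,
        group_label=profile.label,
        htype_label=htype,
        lm=lm,
        capillary_scores=capillary_scores,
        findings=findings,
        clinical=clinical,
    )

    features: pd.DataFrame | None = None
    if with_features:
        features = _invert_scores(scores, rng)
        features.insert(0, "capillary_id", [f"{case_id}-cap{i + 1:03d}" for i in range(n)])
        features.insert(0, "case_id", case_id)
    return case, features


def simulate_cohort(config: CohortConfig, with_features: bool = True) -> CohortResult:
    """Simulate a whole cohort deterministically from the master seed.

    Cases are drawn group by group in profile order; ``n_short_samples``
    cases (chosen uniformly across the cohort) receive a sub-100 capillary
    count from the configured range, emulating sections that contain fewer
    than 100 capillaries.
    """
    ss = np.random.SeedSequence(config.master_seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    total = sum(p.n_cases for p in config.profiles)
    short_idx = set(
        cohort_rng.choice(total, size=config.n_short_samples, replace=False).tolist()
    )
    short_counts = {
        i: int(cohort_rng.integers(config.short_low, config.short_high + 1)) for i in sorted(short_idx)
    }

    case_seeds = ss.spawn(total)
    cases: list[CaseRecord] = []
    feature_frames: list[pd.DataFrame] = []
    global_i = 0
    for profile in config.profiles:
        for k in range(profile.n_cases):
            case_id = f"{profile.label}-{k + 1:02d}"
            n = short_counts.get(global_i, profile.capillaries_per_case)
            case, feats = simulate_case(
                profile,
                np.random.default_rng(case_seeds[global_i]),
                case_id=case_id,
                case_index=k,
                n_capillaries=n,
                with_features=with_features,
            )
            cases.append(case)
            if feats is not None:
                feature_frames.append(feats)
            global_i += 1

    features = (
        pd.concat(feature_frames, ignore_index=True) if feature_frames else pd.DataFrame()
    )
    return CohortResult(
        cases=cases, features=features, case_frame=case_table(cases), config=config
    )


def default_cohort_config(master_seed: int = 0) -> CohortConfig:
    """The study-sized default cohort: 12 MMCP + 6 non-MMCP SSc biopsies,
    8 dermatomyositis + 2 anti-synthetase disease controls and 1 non-diseased
    control (29 sections in total), with eight sections containing fewer
    than 100 capillaries.

    The per-category score probabilities are moment-matched so each group's
    expected AS equals its published mean (MMCP 2.35, non-MMCP 4.2, DM 1.45,
    anti-synthetase 3.555, control 0.08); ``case_severity_sd`` is set so the
    per-case AS spread is of the order of the published group SDs.
    """
    mmcp = GroupProfile(
        label="MMCP",
        n_cases=12,
        score_probs={
            "bm_thickening": (0.30, 0.55, 0.15),
            "bm_reduplication": (0.55, 0.35, 0.10),
            "endothelial_activation": (0.60, 0.30, 0.10),
            "ensheathment": (0.60, 0.35, 0.05),
            "tri": (0.90, 0.07, 0.03),
        },
        case_severity_sd=0.7,
        tri_case_probability=1.0 / 12.0,
        vas_mean=3.0,
        vas_sd=1.5,
        myophagocytosis_p=2.0 / 12.0,
        htype_labels=("MMCP",),
        ck_mean=1325.0,
        ck_sd=1791.0,
        lcssc_p=0.9,
        ild_p=0.2,
        cardiac_p=0.2,
        digital_ulcers_p=0.4,
    )
    nonmmcp = GroupProfile(
        label="nonMMCP",
        n_cases=6,
        score_probs={
            "bm_thickening": (0.10, 0.45, 0.45),
            "bm_reduplication": (0.25, 0.45, 0.30),
            "endothelial_activation": (0.30, 0.50, 0.20),
            "ensheathment": (0.35, 0.40, 0.25),
            "tri": (0.85, 0.10, 0.05),
        },
        case_severity_sd=0.8,
        tri_case_probability=0.5,
        vas_mean=7.0,
        vas_sd=1.5,
        myophagocytosis_p=5.0 / 6.0,
        nuclear_inclusions_p=0.5,
        htype_labels=("TASS", "SNMCPF", "IVPP", "IVPP", "IMNM+", "IMNM+"),
        ck_mean=2536.0,
        ck_sd=2068.0,
        lcssc_p=0.5,
        ild_p=0.67,
        cardiac_p=0.5,
        digital_ulcers_p=0.4,
    )
    dm = GroupProfile(
        label="DM",
        n_cases=8,
        score_probs={
            "bm_thickening": (0.50, 0.40, 0.10),
            "bm_reduplication": (0.75, 0.20, 0.05),
            "endothelial_activation": (0.70, 0.25, 0.05),
            "ensheathment": (0.82, 0.16, 0.02),
            "tri": (0.80, 0.13, 0.07),
        },
        case_severity_sd=0.5,
        tri_case_probability=0.75,
        vas_mean=5.0,
        vas_sd=2.0,
        myophagocytosis_p=0.5,
        htype_labels=("DM",),
        age_mean=50.0,
        age_sd=15.0,
        ck_mean=1500.0,
        ck_sd=1500.0,
    )
    asys = GroupProfile(
        label="ASyS",
        n_cases=2,
        score_probs={
            "bm_thickening": (0.20, 0.50, 0.30),
            "bm_reduplication": (0.40, 0.40, 0.20),
            "endothelial_activation": (0.40, 0.45, 0.15),
            "ensheathment": (0.30, 0.50, 0.20),
            "tri": (0.85, 0.10, 0.05),
        },
        case_severity_sd=0.8,
        tri_case_probability=0.5,
        vas_mean=6.0,
        vas_sd=2.0,
        myophagocytosis_p=0.5,
        htype_labels=("TASS",),
        ck_mean=2000.0,
        ck_sd=1800.0,
    )
    control = GroupProfile(
        label="control",
        n_cases=1,
        score_probs={
            "bm_thickening": (0.98, 0.02, 0.0),
            "bm_reduplication": (0.98, 0.02, 0.0),
            "endothelial_activation": (0.98, 0.02, 0.0),
            "ensheathment": (0.98, 0.02, 0.0),
            "tri": (1.0, 0.0, 0.0),
        },
        case_severity_sd=0.0,
        vas_mean=0.2,
        vas_sd=0.2,
        htype_labels=("control",),
        age_mean=45.0,
        age_sd=12.0,
    )
    return CohortConfig(
        profiles=(mmcp, nonmmcp, dm, asys, control),
        master_seed=master_seed,
        n_short_samples=8,
    )


# ---------------------------------------------------------------------------
# Geometry phantoms
# ---------------------------------------------------------------------------

_N_VERTICES = 192
_ACTIVATION_RATIO_BANDS = {"none": (1.0, 1.45), "mild": (1.55, 2.9), "marked": (3.1, 4.5)}
_TRI_DIAMETER_BANDS = {
    SizeClass.SMALL: (150.0, 280.0),
    SizeClass.MEDIUM: (320.0, 780.0),
    SizeClass.LARGE: (820.0, 1200.0),
}
_COVERAGE_TARGETS = {
    ProcessProminence.FOCAL_SMALL: 0.12,
    ProcessProminence.PROMINENT: 0.50,
    ProcessProminence.VERY_PROMINENT: 0.82,
}


def _ring(radii: np.ndarray, angles: np.ndarray, center: tuple[float, float]) -> list[tuple[float, float]]:
    return [
        (center[0] + r * math.cos(a), center[1] + r * math.sin(a))
        for r, a in zip(radii, angles)
    ]


def _offset_for_area(radii: np.ndarray, d_angle: float, target_area: float) -> float:
    """Radial offset t so the polar region between r(theta) and r(theta)+t has
    the requested area (fan-series quadratic, exact up to chord error)."""
    s = float(np.sum(radii) * d_angle)
    disc = s * s + 4.0 * math.pi * target_area
    return (-s + math.sqrt(disc)) / (2.0 * math.pi)


def synthesize_geometry(
    features: CapillaryFeatures,
    seed: int | np.random.Generator = 0,
    config: RubricConfig | None = None,
) -> CapillaryGeometry:
    """Build a polygonal capillary phantom realising a feature record.

    A perturbed-ellipse lumen is wrapped by an endothelial ring whose area
    matches the feature's endothelial area (or a band implied by its
    activation grade), ``bm_layer_count`` contiguous BM annuli of total
    radial width ``bm_thickness_nm``, ``process_count`` wedge-shaped process
    profiles whose angular coverage realises the process prominence, and TRI
    marks with diameters inside the configured size-class bands.  Feeding
    the phantom to :func:`capscore.morphometry.extract_features` recovers
    counts exactly and thickness/area within polygonal tolerance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    config = config or RubricConfig()
    if features.bm_thickness_nm is None or features.bm_thickness_nm <= 0:
        raise ConfigError("phantom needs a positive bm_thickness_nm")
    k = int(features.bm_layer_count or 1)
    if k < 1:
        raise ConfigError("phantom needs bm_layer_count >= 1")

    angles = np.linspace(0.0, 2.0 * math.pi, _N_VERTICES, endpoint=False)
    d_angle = 2.0 * math.pi / _N_VERTICES
    center = (float(rng.uniform(-5e4, 5e4)), float(rng.uniform(-5e4, 5e4)))

    r0 = float(rng.uniform(1200.0, 1800.0))
    ecc = float(rng.uniform(0.0, 0.08))
    phase = float(rng.uniform(0.0, 2.0 * math.pi))
    lumen_r = r0 * (1.0 + ecc * np.cos(2.0 * angles + phase))
    lumen = Polygon(_ring(lumen_r, angles, center))

    endothelium: Polygon | None = None
    base_r = lumen_r
    if not features.degraded:
        if features.endothelial_area_um2 is not None:
            area_nm2 = float(features.endothelial_area_um2) * 1e6
        else:
            grade = (
                features.activation_grade.value
                if features.activation_grade is not None
                else "none"
            )
            lo, hi = _ACTIVATION_RATIO_BANDS[grade]
            ratio = float(rng.uniform(lo, hi))
            area_nm2 = ratio * config.activation.reference_area_um2 * 1e6
        t = _offset_for_area(lumen_r, d_angle, area_nm2)
        endo_r = lumen_r + t
        endothelium = Polygon(_ring(endo_r, angles, center))
        base_r = endo_r
    else:
        base_r = lumen_r + 50.0

    width = float(features.bm_thickness_nm) / k
    bm_layers: list[Polygon] = []
    inner = base_r
    for _ in range(k):
        outer = inner + width
        bm_layers.append(
            Polygon(_ring(outer, angles, center), [_ring(inner, angles, center)])
        )
        inner = outer
    bm_outer_r = inner

    processes: list[ProcessAnnotation] = []
    n_proc = int(features.process_count or 0)
    if n_proc > 0:
        prominence = ProcessProminence(features.process_prominence)
        coverage = _COVERAGE_TARGETS[prominence]
        half_width = coverage * math.pi / n_proc
        centers = np.linspace(0.0, 2.0 * math.pi, n_proc, endpoint=False) + float(
            rng.uniform(0.0, 2.0 * math.pi)
        )
        for theta_c in centers:
            r_at = float(np.interp(theta_c % (2.0 * math.pi), angles, bm_outer_r, period=2.0 * math.pi))
            r_in, r_out = r_at + 20.0, r_at + 520.0
            arc = np.linspace(theta_c - half_width, theta_c + half_width, 24)
            pts = [
                (center[0] + r_out * math.cos(a), center[1] + r_out * math.sin(a)) for a in arc
            ] + [
                (center[0] + r_in * math.cos(a), center[1] + r_in * math.sin(a))
                for a in arc[::-1]
            ]
            processes.append(ProcessAnnotation(polygon=Polygon(pts)))

    tri_marks: list[TriMark] = []
    for obs in features.tri or ():
        lo, hi = _TRI_DIAMETER_BANDS[SizeClass(obs.size_class)]
        for _ in range(obs.count):
            theta = float(rng.uniform(0.0, 2.0 * math.pi))
            r = float(np.interp(theta, angles, lumen_r, period=2.0 * math.pi)) + 30.0
            tri_marks.append(
                TriMark(
                    x_nm=center[0] + r * math.cos(theta),
                    y_nm=center[1] + r * math.sin(theta),
                    diameter_nm=float(rng.uniform(lo, hi)),
                )
            )

    return CapillaryGeometry(
        lumen=lumen,
        endothelium_outer=endothelium,
        bm_layers=bm_layers,
        processes=processes,
        tri_marks=tri_marks,
        pixel_size_nm=config.morphometry.pixel_size_nm,
    )
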