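"""Case- and group-level aggregation of per-capillary scores.

Two summary statistics describe a biopsy:

* **AS** (average sum) — the per-case mean, over its scored capillaries, of
  the sum of the four summed categories (BM thickening, BM reduplication,
  endothelial activation, ensheathment); range 0–8.
* **ACS** (average category sum) — the per-case mean of a single category's
  scores; range 0–2.  The four ACS values of a case sum exactly to its AS.

Cases additionally carry a light-microscopy severity block (a 0–10 cm
visual-analogue-scale score plus 0–3 subscores for capillaries, muscle
fibers and endo/perimysium), per-case additional-findings flags
(tubuloreticular inclusions, myophagocytosis, myonuclear inclusions) and
optional clinical metadata.  For visualisation, cases are ordered by VAS
then AS, and a stacked-bar ACS report renders one bar per case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .rubric import AS_CATEGORIES, CapillaryScore

__all__ = [
    "GROUP_LABELS",
    "LightMicroscopyScore",
    "FindingsFlags",
    "ClinicalRecord",
    "CaseRecord",
    "GroupSummary",
    "as_score",
    "acs_score",
    "summarize_group",
    "summarize_cohort",
    "order_cases",
    "derive_findings_flags",
    "case_table",
    "plot_acs_report",
]

#: Study groups: the SSc pattern groups, the two disease-control entities and
#: the non-diseased control.
GROUP_LABELS: tuple[str, ...] = ("MMCP", "nonMMCP", "DM", "ASyS", "control")

#: Sampling rule: at most this many capillaries are scored per biopsy.
MAX_CAPILLARIES_PER_CASE = 100


@dataclass(frozen=True)
class LightMicroscopyScore:
    """Light-microscopy severity block: VAS in cm on [0, 10] and three 0–3
    ordinal subscores."""

    vas: float
    capillaries: int = 0
    muscle_fibers: int = 0
    endo_perimysium: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.vas) and 0.0 <= self.vas <= 10.0):
            raise InvalidInputError(f"VAS must lie in [0, 10], got {self.vas}")
        for name in ("capillaries", "muscle_fibers", "endo_perimysium"):
            v = getattr(self, name)
            if v not in (0, 1, 2, 3):
                raise InvalidInputError(f"subscore {name} must be in 0..3, got {v!r}")


@dataclass(frozen=True)
class FindingsFlags:
    """Per-case additional ultrastructural findings."""

    tri_present: bool = False
    myophagocytosis: bool = False
    nuclear_inclusions: bool = False


@dataclass(frozen=True)
class ClinicalRecord:
    """Optional clinical metadata for a case."""

    age: float | None = None
    max_ck_u_l: float | None = None
    cutaneous_subtype: str | None = None  # "lcSSc" / "dcSSc" / None
    ild: bool | None = None
    cardiac: bool | None = None
    digital_ulcers: bool | None = None


@dataclass
class CaseRecord:
    """One biopsy: its group label, light-microscopy block, scored
    capillaries and findings flags.

    ``capillary_scores`` holds at most 100 entries (the sampling rule scores
    min(available, 100) capillaries per section).
    """

    case_id: str
    group_label: str
    lm: LightMicroscopyScore
    capillary_scores: Sequence[CapillaryScore]
    htype_label: str = ""
    findings: FindingsFlags = field(default_factory=FindingsFlags)
    clinical: ClinicalRecord | None = None

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise InvalidInputError(
                f"group_label must be one of {GROUP_LABELS}, got {self.group_label!r}"
            )
        self.capillary_scores = list(self.capillary_scores)
        if not self.capillary_scores:
            raise InvalidInputError(f"case {self.case_id}: needs at least one capillary")
        if len(self.capillary_scores) > MAX_CAPILLARIES_PER_CASE:
            raise InvalidInputError(
                f"case {self.case_id}: {len(self.capillary_scores)} capillaries exceeds "
                f"the {MAX_CAPILLARIES_PER_CASE}-capillary sampling rule"
            )

    @property
    def scored_capillaries(self) -> list[CapillaryScore]:
        """Capillaries that contribute to N (fully-missing ones excluded)."""
        return [s for s in self.capillary_scores if not s.fully_missing]

    @property
    def n_capillaries(self) -> int:
        return len(self.scored_capillaries)


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics of per-case AS within one group.

    ``as_sd`` is the sample standard deviation (n−1 denominator); a group of
    a single case reports sd 0 and sets ``single_case``.
    """

    group_label: str
    n_cases: int
    as_mean: float
    as_sd: float
    as_min: float
    as_max: float
    acs_mean: Mapping[str, float]
    single_case: bool = False


def as_score(case: CaseRecord) -> float:
    """Per-case AS: mean over scored capillaries of the four-category sum."""
    scored = case.scored_capillaries
    if not scored:
        raise InvalidInputError(f"case {case.case_id}: no scorable capillaries")
    return float(sum(s.four_category_sum for s in scored) / len(scored))


def acs_score(case: CaseRecord, category: str) -> float:
    """Per-case ACS for one of the four summed categories."""
    if category not in AS_CATEGORIES:
        raise InvalidInputError(
            f"unknown category {category!r}; expected one of {AS_CATEGORIES}"
        )
    scored = case.scored_capillaries
    if not scored:
        raise InvalidInputError(f"case {case.case_id}: no scorable capillaries")
    return float(sum(getattr(s, category) for s in scored) / len(scored))


def summarize_group(cases: Iterable[CaseRecord], group_label: str) -> GroupSummary:
    """Mean, sample SD, min and max of per-case AS plus per-category mean ACS
    over the cases carrying ``group_label``."""
    members = [c for c in cases if c.group_label == group_label]
    if not members:
        raise InvalidInputError(f"no cases with group label {group_label!r}")
    as_values = np.array([as_score(c) for c in members])
    single = len(members) == 1
    sd = 0.0 if single else float(np.std(as_values, ddof=1))
    acs_mean = {
        cat: float(np.mean([acs_score(c, cat) for c in members])) for cat in AS_CATEGORIES
    }
    return GroupSummary(
        group_label=group_label,
        n_cases=len(members),
        as_mean=float(np.mean(as_values)),
        as_sd=sd,
        as_min=float(np.min(as_values)),
        as_max=float(np.max(as_values)),
        acs_mean=acs_mean,
        single_case=single,
    )


def summarize_cohort(cases: Sequence[CaseRecord]) -> pd.DataFrame:
    """One :class:`GroupSummary` row per group label present in the cohort,
    in canonical group order."""
    labels = [g for g in GROUP_LABELS if any(c.group_label == g for c in cases)]
    rows = []
    for label in labels:
        s = summarize_group(cases, label)
        row = {
            "group_label": s.group_label,
            "n_cases": s.n_cases,
            "as_mean": s.as_mean,
            "as_sd": s.as_sd,
            "as_min": s.as_min,
            "as_max": s.as_max,
            "single_case": s.single_case,
        }
        row.update({f"acs_mean_{cat}": v for cat, v in s.acs_mean.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def order_cases(cases: Sequence[CaseRecord], ascending: bool = True) -> list[CaseRecord]:
    """Deterministic display order: VAS, then AS, then case id.

    The id tiebreak is always lexicographically ascending so the order is
    stable regardless of the chosen direction of the severity keys.
    """
    for case in cases:
        if case.lm is None or not np.isfinite(case.lm.vas):
            raise InvalidInputError(f"case {case.case_id}: missing VAS score")
    sign = 1.0 if ascending else -1.0
    return sorted(cases, key=lambda c: (sign * c.lm.vas, sign * as_score(c), c.case_id))


def derive_findings_flags(
    case: CaseRecord,
    myophagocytosis: bool = False,
    nuclear_inclusions: bool = False,
) -> FindingsFlags:
    """TRI presence is derived from the capillary scores (any capillary with
    TRI score >= 1); myophagocytosis and nuclear inclusions are manual
    observations passed through unchanged."""
    tri_present = any(s.tri >= 1 for s in case.capillary_scores)
    return FindingsFlags(
        tri_present=tri_present,
        myophagocytosis=bool(myophagocytosis),
        nuclear_inclusions=bool(nuclear_inclusions),
    )


def case_table(cases: Sequence[CaseRecord]) -> pd.DataFrame:
    """Flatten cases into one row per case with AS, the four ACS values,
    light-microscopy scores, findings flags and clinical fields."""
    rows = []
    for c in cases:
        row: dict = {
            "case_id": c.case_id,
            "group_label": c.group_label,
            "htype_label": c.htype_label,
            "n_capillaries": c.n_capillaries,
            "as_score": as_score(c),
            "vas": c.lm.vas,
            "lm_capillaries": c.lm.capillaries,
            "lm_muscle_fibers": c.lm.muscle_fibers,
            "lm_endo_perimysium": c.lm.endo_perimysium,
            "tri_present": c.findings.tri_present,
            "myophagocytosis": c.findings.myophagocytosis,
            "nuclear_inclusions": c.findings.nuclear_inclusions,
        }
        row.update({f"acs_{cat}": acs_score(c, cat) for cat in AS_CATEGORIES})
        if c.clinical is not None:
            row.update(
                {
                    "age": c.clinical.age,
                    "max_ck_u_l": c.clinical.max_ck_u_l,
                    "cutaneous_subtype": c.clinical.cutaneous_subtype,
                    "ild": c.clinical.ild,
                    "cardiac": c.clinical.cardiac,
                    "digital_ulcers": c.clinical.digital_ulcers,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


_ACS_COLORS = {
    "bm_thickening": "#4472c4",  # blue
    "bm_reduplication": "#ed7d31",  # orange
    "endothelial_activation": "#a5a5a5",  # gray
    "ensheathment": "#ffc000",  # yellow
}
_ACS_LABELS = {
    "bm_thickening": "BM thickening",
    "bm_reduplication": "BM reduplication",
    "endothelial_activation": "Endothelial activation",
    "ensheathment": "Ensheathment",
}


def plot_acs_report(
    cases: Sequence[CaseRecord],
    path: str | None = None,
    ascending: bool = True,
):
    """Stacked-bar ACS report: one bar per case (ordered by VAS then AS),
    four coloured category segments summing to the case AS, annotated with
    the VAS value and the findings flags.  Returns the matplotlib figure;
    writes it to ``path`` (PNG/SVG by extension) when given."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ordered = order_cases(cases, ascending=ascending)
    x = np.arange(len(ordered))
    fig, ax = plt.subplots(figsize=(max(6.0, 0.45 * len(ordered) + 2.0), 4.5))
    bottom = np.zeros(len(ordered))
    for cat in AS_CATEGORIES:
        vals = np.array([acs_score(c, cat) for c in ordered])
        ax.bar(x, vals, bottom=bottom, color=_ACS_COLORS[cat], label=_ACS_LABELS[cat], width=0.8)
        bottom += vals
    flag_text = []
    for c in ordered:
        marks = []
        if c.findings.tri_present:
            marks.append("T")
        if c.findings.myophagocytosis:
            marks.append("M")
        if c.findings.nuclear_inclusions:
            marks.append("N")
        flag_text.append("".join(marks))
    for xi, c, top, flags in zip(x, ordered, bottom, flag_text):
        ax.text(xi, top + 0.08, f"{c.lm.vas:.1f}", ha="center", va="bottom", fontsize=7, rotation=90)
        if flags:
            ax.text(xi, -0.35, flags, ha="center", va="top", fontsize=7, color="crimson")
    ax.set_xticks(x)
    ax.set_xticklabels([c.case_id for c in ordered], rotation=90, fontsize=7)
    ax.set_ylabel("ACS (stacked = AS)")
    ax.set_xlabel("case (sorted by VAS, then AS); bar label = VAS; T/M/N = TRI, myophagocytosis, nuclear inclusions")
    ax.set_ylim(bottom=min(-0.5, ax.get_ylim()[0]))
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
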