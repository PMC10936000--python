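"""Published inputs from the Heilongjiang CDC emergency-drill survey.

The raw respondent data from that survey (N = 1,859 disease-control staff,
5-point effectiveness rating mean-split at 3.16) were never deposited; what
is public are the aggregate tables: the high/low cross-tabulations of every
explanatory variable, the adjusted odds ratios of the seven significant
factors, and the expert-elicited direct-influence (adjacency) matrix over
those factors.  This module ships those aggregates as typed objects so the
screening and ISM stages can be exercised on the exact published inputs, and
so the synthetic generator can target the published marginals and effects.
"""

from __future__ import annotations

import numpy as np

from .survey import Codebook, ContingencyTable, VariableSpec

#: High/low effectiveness group sizes in the published survey.
N_HIGH = 869
N_LOW = 990
N_TOTAL = N_HIGH + N_LOW

#: ISM factor labels in elicitation order -> analysis variable names.
FACTOR_VARIABLES: dict[str, str] = {
    "S1": "training_frequency",
    "S2": "training_quality",
    "S3": "fund_guarantee",
    "S4": "equipment_guarantee",
    "S5": "leaders_focus",
    "S6": "coordination",
    "S7": "plan_design_skill",
}

#: Human-readable factor names for hierarchy rendering.
FACTOR_NAMES: dict[str, str] = {
    "S1": "training frequency",
    "S2": "training quality",
    "S3": "fund guarantee",
    "S4": "equipment and facilities guarantee",
    "S5": "leaders' focus",
    "S6": "inter-departmental coordination",
    "S7": "drill plan designing skill",
}

# Published cross-tabulations: variable -> (levels, [[high, low] per level]).
# Column sums are (869, 990) for every variable.
_CROSSTABS: dict[str, tuple[tuple[str, ...], list[list[int]]]] = {
    "gender": (("male", "female"), [[393, 368], [476, 622]]),
    "age_group": (
        ("<=30", "30-39", "40-49", ">=50"),
        [[114, 124], [261, 297], [362, 411], [132, 158]],
    ),
    "education": (("junior_college_or_below", "college_or_above"), [[118, 179], [751, 811]]),
    "work_tenure": (
        ("0-9", "10-19", "20-29", ">=30"),
        [[325, 341], [228, 263], [231, 290], [85, 96]],
    ),
    "training_frequency": (("none", "at_least_one"), [[396, 337], [473, 653]]),
    "training_quality": (("low", "high"), [[442, 379], [427, 611]]),
    "fund_guarantee": (("yes", "no"), [[612, 790], [257, 200]]),
    "personnel_guarantee": (("yes", "no"), [[452, 484], [417, 506]]),
    "site_guarantee": (("yes", "no"), [[338, 351], [531, 639]]),
    "equipment_guarantee": (("yes", "no"), [[412, 683], [457, 307]]),
    "security_guarantee": (("yes", "no"), [[254, 285], [615, 705]]),
    "leaders_focus": (("yes", "no"), [[474, 647], [395, 343]]),
    "coordination": (("yes", "no"), [[373, 533], [496, 457]]),
    "tabletop_drill": (("yes", "no"), [[81, 66], [788, 924]]),
    "operation_drill": (("yes", "no"), [[91, 75], [778, 915]]),
    "functional_drill": (("yes", "no"), [[49, 45], [820, 945]]),
    "comprehensive_drill": (("yes", "no"), [[34, 28], [835, 962]]),
    "plan_design_skill": (("good", "bad"), [[614, 765], [255, 225]]),
    "script_writing_skill": (("good", "bad"), [[431, 538], [438, 452]]),
    "form_design_skill": (("good", "bad"), [[387, 385], [482, 605]]),
    "needs_assessment_skill": (("good", "bad"), [[279, 394], [590, 596]]),
}

#: Published chi-square statistics (1 decimal) per variable.
REPORTED_CHI_SQUARE: dict[str, float] = {
    "gender": 12.4,
    "age_group": 0.3,
    "education": 7.0,
    "work_tenure": 2.4,
    "training_frequency": 25.8,
    "training_quality": 29.7,
    "fund_guarantee": 21.9,
    "personnel_guarantee": 1.8,
    "site_guarantee": 2.4,
    "equipment_guarantee": 89.0,
    "security_guarantee": 0.0,
    "leaders_focus": 22.6,
    "coordination": 22.1,
    "tabletop_drill": 4.5,
    "operation_drill": 4.8,
    "functional_drill": 1.2,
    "comprehensive_drill": 1.7,
    "plan_design_skill": 10.6,
    "script_writing_skill": 4.2,
    "form_design_skill": 6.1,
    "needs_assessment_skill": 11.9,
}

#: Published adjusted odds ratios (adverse vs reference level) with Wald
#: statistics and 95% CIs for the seven significant factors.
REPORTED_EFFECTS: dict[str, dict[str, float]] = {
    "training_frequency": {"wald": 17.616, "or": 1.539, "lo": 1.258, "hi": 1.882},
    "training_quality": {"wald": 31.066, "or": 1.765, "lo": 1.445, "hi": 2.155},
    "fund_guarantee": {"wald": 8.047, "or": 1.407, "lo": 1.111, "hi": 1.781},
    "equipment_guarantee": {"wald": 62.015, "or": 2.324, "lo": 1.884, "hi": 2.867},
    "leaders_focus": {"wald": 17.174, "or": 1.585, "lo": 1.275, "hi": 1.971},
    "coordination": {"wald": 7.480, "or": 1.335, "lo": 1.085, "hi": 1.641},
    "plan_design_skill": {"wald": 11.151, "or": 1.494, "lo": 1.180, "hi": 1.890},
}

# Expert direct-influence edges among the seven factors (row influences column).
_ADJACENCY_EDGES: dict[str, tuple[str, ...]] = {
    "S1": ("S2", "S6"),
    "S2": ("S5",),
    "S3": ("S1", "S2", "S4", "S5", "S6", "S7"),
    "S4": ("S2", "S6"),
    "S5": ("S1", "S2", "S6"),
    "S6": ("S2",),
    "S7": ("S2", "S6"),
}

#: Published reachable and common sets per factor (factor -> (R(Si), T(Si))).
REPORTED_FACTOR_SETS: dict[str, tuple[frozenset, frozenset]] = {
    "S1": (frozenset({"S1", "S2", "S5", "S6"}), frozenset({"S1", "S2", "S5", "S6"})),
    "S2": (frozenset({"S1", "S2", "S5", "S6"}), frozenset({"S1", "S2", "S5", "S6"})),
    "S3": (
        frozenset({"S1", "S2", "S3", "S4", "S5", "S6", "S7"}),
        frozenset({"S3"}),
    ),
    "S4": (frozenset({"S1", "S2", "S4", "S5", "S6"}), frozenset({"S4"})),
    "S5": (frozenset({"S1", "S2", "S5", "S6"}), frozenset({"S1", "S2", "S5", "S6"})),
    "S6": (frozenset({"S1", "S2", "S5", "S6"}), frozenset({"S1", "S2", "S5", "S6"})),
    "S7": (frozenset({"S1", "S2", "S5", "S6", "S7"}), frozenset({"S7"})),
}

#: Published level partition: surface, middle, bottom.
REPORTED_LEVELS: tuple[frozenset, ...] = (
    frozenset({"S1", "S2", "S5", "S6"}),
    frozenset({"S4", "S7"}),
    frozenset({"S3"}),
)


def effectiveness_crosstabs() -> dict[str, ContingencyTable]:
    """The published r x 2 high/low cross-tabulations, one per variable."""
    return {
        name: ContingencyTable(variable=name, row_labels=levels, counts=np.array(counts))
        for name, (levels, counts) in _CROSSTABS.items()
    }


def expert_adjacency() -> tuple[list[str], np.ndarray]:
    """The expert-elicited 7x7 direct-influence matrix over S1..S7."""
    labels = list(FACTOR_VARIABLES)
    index = {lab: i for i, lab in enumerate(labels)}
    R = np.zeros((7, 7), dtype=int)
    for src, dsts in _ADJACENCY_EDGES.items():
        for dst in dsts:
            R[index[src], index[dst]] = 1
    return labels, R


def marginal_prevalences() -> dict[str, dict[str, float]]:
    """Pooled level prevalences per variable, (high + low count) / N."""
    out: dict[str, dict[str, float]] = {}
    for name, (levels, counts) in _CROSSTABS.items():
        totals = np.asarray(counts).sum(axis=1)
        out[name] = {lev: tot / N_TOTAL for lev, tot in zip(levels, totals)}
    return out


# Adverse/reference orientation for each variable.  For the seven Table-3
# factors the adverse level is the one the published odds ratios contrast
# against its reference; for the remaining variables the orientation is a
# convention (first published level adverse) and carries no effect.
_ADVERSE: dict[str, tuple[str, str]] = {
    "gender": ("female", "male"),
    "education": ("junior_college_or_below", "college_or_above"),
    "training_frequency": ("none", "at_least_one"),
    "training_quality": ("low", "high"),
    "fund_guarantee": ("no", "yes"),
    "personnel_guarantee": ("no", "yes"),
    "site_guarantee": ("no", "yes"),
    "equipment_guarantee": ("no", "yes"),
    "security_guarantee": ("no", "yes"),
    "leaders_focus": ("no", "yes"),
    "coordination": ("no", "yes"),
    "tabletop_drill": ("no", "yes"),
    "operation_drill": ("no", "yes"),
    "functional_drill": ("no", "yes"),
    "comprehensive_drill": ("no", "yes"),
    "plan_design_skill": ("bad", "good"),
    "script_writing_skill": ("bad", "good"),
    "form_design_skill": ("bad", "good"),
    "needs_assessment_skill": ("bad", "good"),
}

_KINDS: dict[str, str] = {
    "age_group": "ordered-categorical",
    "work_tenure": "ordered-categorical",
    "plan_design_skill": "likert-5",
    "script_writing_skill": "likert-5",
    "form_design_skill": "likert-5",
    "needs_assessment_skill": "likert-5",
}


def default_codebook() -> Codebook:
    """Codebook for the full published variable set, threshold 3.16."""
    variables = []
    for name, (levels, _) in _CROSSTABS.items():
        kind = _KINDS.get(name, "binary")
        if name in _ADVERSE:
            adverse, reference = _ADVERSE[name]
        else:  # multi-level demographics: first level vs last as convention
            adverse, reference = levels[0], levels[-1]
        variables.append(
            VariableSpec(
                name=name,
                kind=kind,
                levels=levels,
                adverse_level=adverse,
                reference_level=reference,
            )
        )
    return Codebook(
        outcome_name="effectiveness_score",
        variables=tuple(variables),
        outcome_threshold=3.16,
    )
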