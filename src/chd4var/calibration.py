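"""Calibrated categorical calls and PP3/BP4 evidence from predictor scores.

Four missense predictors are consumed as inputs: MetaRNN, PolyPhen-2,
AlphaMissense and REVEL.  Each score in [0, 1] is mapped to a three-way call
(pathogenic / benign / undetermined) at published thresholds; only REVEL
additionally generates classification evidence, as a strength-tiered PP3 or
BP4 code following the interval calibration of Pejaver and colleagues:

====================  =================
REVEL score           evidence
====================  =================
>= 0.932              PP3 (strong)
>= 0.773              PP3 (moderate)
>= 0.644              PP3 (supporting)
(0.290, 0.644)        undetermined
<= 0.290              BP4 (supporting)
<= 0.183              BP4 (moderate)
====================  =================

All pathogenic bounds are inclusive (>=) and all benign bounds inclusive
(<=); scores in the gap between the supporting bounds carry no evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .variant_model import EvidenceCode, ProteinVariant, Strength

__all__ = [
    "TOOLS",
    "CalibrationTable",
    "DEFAULT_CALIBRATION",
    "ToolCall",
    "revel_to_evidence",
    "tool_call",
    "concordance_profile",
    "ConcordanceProfile",
]

TOOLS = ("metarnn", "polyphen2", "alphamissense", "revel")


@dataclass(frozen=True)
class CalibrationTable:
    """Score thresholds for categorical calls and REVEL evidence tiers.

    ``pathogenic`` / ``benign`` map each tool to its call bound; a score is
    called pathogenic at >= the pathogenic bound and benign at <= the benign
    bound, otherwise undetermined.  The REVEL tier bounds
    (``revel_pp3_*`` / ``revel_bp4_*``) define the strength of the PP3/BP4
    evidence code.
    """

    pathogenic: dict = field(default_factory=lambda: {
        "metarnn": 0.85, "polyphen2": 0.978, "alphamissense": 0.9, "revel": 0.644,
    })
    benign: dict = field(default_factory=lambda: {
        # PolyPhen-2 and REVEL benign bounds are published calibrations
        # (inclusive, <=); MetaRNN and AlphaMissense expose no benign bound,
        # so scores strictly below the midpoint are treated as benign calls
        # for concordance accounting.
        "metarnn": 0.5, "polyphen2": 0.113, "alphamissense": 0.5, "revel": 0.290,
    })
    #: tools whose benign bound is an exclusive midpoint fallback (<), not a
    #: published inclusive calibration (<=)
    benign_exclusive: tuple = ("metarnn", "alphamissense")
    revel_pp3_supporting: float = 0.644
    revel_pp3_moderate: float = 0.773
    revel_pp3_strong: float = 0.932
    revel_bp4_supporting: float = 0.290
    revel_bp4_moderate: float = 0.183

    def __post_init__(self) -> None:
        if not (self.revel_pp3_supporting < self.revel_pp3_moderate < self.revel_pp3_strong):
            raise ValueError("pathogenic REVEL tier bounds must be strictly increasing")
        if not (self.revel_bp4_supporting > self.revel_bp4_moderate):
            raise ValueError("benign REVEL tier bounds must be strictly decreasing")
        if self.revel_pp3_supporting <= self.revel_bp4_supporting:
            raise ValueError("pathogenic-supporting bound must exceed benign-supporting bound")
        for tool in TOOLS:
            if self.pathogenic[tool] <= self.benign[tool]:
                raise ValueError(f"{tool}: pathogenic bound must exceed benign bound")


DEFAULT_CALIBRATION = CalibrationTable()


@dataclass(frozen=True)
class ToolCall:
    tool: str
    call: str  # pathogenic / benign / undetermined


def _check_score(score: float) -> None:
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"score {score} outside [0, 1]")


def revel_to_evidence(score: float,
                      table: CalibrationTable = DEFAULT_CALIBRATION,
                      ) -> EvidenceCode | None:
    """Map a REVEL score to a strength-tiered PP3/BP4 code, or ``None``.

    ``None`` means the score lies in the undetermined gap and contributes no
    classification evidence.  The mapping is piecewise constant and monotone:
    a higher score never yields weaker pathogenic or stronger benign support.
    """
    _check_score(score)
    if score >= table.revel_pp3_strong:
        return EvidenceCode("PP3", Strength.STRONG)
    if score >= table.revel_pp3_moderate:
        return EvidenceCode("PP3", Strength.MODERATE)
    if score >= table.revel_pp3_supporting:
        return EvidenceCode("PP3", Strength.SUPPORTING)
    if score <= table.revel_bp4_moderate:
        return EvidenceCode("BP4", Strength.MODERATE)
    if score <= table.revel_bp4_supporting:
        return EvidenceCode("BP4", Strength.SUPPORTING)
    return None


def tool_call(tool: str, score: float,
              table: CalibrationTable = DEFAULT_CALIBRATION) -> ToolCall:
    """Three-way categorical call for one tool's score."""
    if tool not in TOOLS:
        raise ValueError(f"unknown tool {tool!r}; expected one of {TOOLS}")
    _check_score(score)
    if score >= table.pathogenic[tool]:
        call = "pathogenic"
    elif (score < table.benign[tool] if tool in table.benign_exclusive
          else score <= table.benign[tool]):
        call = "benign"
    else:
        call = "undetermined"
    return ToolCall(tool, call)


@dataclass(frozen=True)
class ConcordanceProfile:
    """Per-tool call fractions and the cross-tool agreement count.

    ``full_agreement`` counts variants on which all four tools make the same
    *determinate* call (all pathogenic or all benign).  A variant on which
    every tool is undetermined carries no concordant prediction and is not
    counted; ``identical_calls`` additionally counts those rows.
    """

    n: int
    fractions: dict  # tool -> {pathogenic, benign, undetermined} fractions
    counts: dict     # tool -> {call: count}
    full_agreement: int
    identical_calls: int
    excluded: tuple[str, ...] = ()  # variant ids skipped for missing scores


def concordance_profile(variants: Sequence[ProteinVariant],
                        table: CalibrationTable = DEFAULT_CALIBRATION,
                        ) -> ConcordanceProfile:
    """Profile the four predictors' calls over a set of missense variants.

    Variants with any missing score are excluded (and reported in
    ``excluded``); fractions are over the included variants and sum to one
    per tool.
    """
    included: list[ProteinVariant] = []
    excluded: list[str] = []
    for v in variants:
        if v.scores.complete:
            included.append(v)
        else:
            excluded.append(v.id)
    counts = {tool: {"pathogenic": 0, "benign": 0, "undetermined": 0} for tool in TOOLS}
    full = identical = 0
    for v in included:
        calls = [tool_call(tool, v.scores.get(tool), table).call for tool in TOOLS]
        for tool, call in zip(TOOLS, calls):
            counts[tool][call] += 1
        if len(set(calls)) == 1:
            identical += 1
            if calls[0] != "undetermined":
                full += 1
    n = len(included)
    fractions = {
        tool: {call: (c / n if n else 0.0) for call, c in tool_counts.items()}
        for tool, tool_counts in counts.items()
    }
    return ConcordanceProfile(n=n, fractions=fractions, counts=counts,
                              full_agreement=full, identical_calls=identical,
                              excluded=tuple(excluded))
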