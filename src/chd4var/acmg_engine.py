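"""Combination of ACMG/AMP evidence into five-tier classifications.

Two combination modes are provided:

``categorical``
    The classical rule table over counts of very-strong / strong / moderate /
    supporting pathogenic criteria and stand-alone / strong / supporting
    benign criteria.
``points``
    The Tavtigian-style point refinement: very strong 8, strong 4, moderate 2,
    supporting 1 (benign criteria negated), with class bands
    P >= 10, LP 6..9, VUS 0..5, LB -6..-1, B <= -7.

Evidence sets mixing pathogenic and benign criteria are resolved by an
explicit conflict policy before the categorical rule table is applied:
``dominant_side_by_points`` (default) drops the side with the smaller
absolute point mass (ties give VUS), while ``richards_vus`` returns VUS for
any mixed set.  By default the REVEL strength modifier on PP3/BP4 is
collapsed to supporting-level when combining (``collapse_to_supporting``),
matching how the study weighed its computational evidence; ``honor_tier``
counts the code at its calibrated strength instead.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .calibration import CalibrationTable, DEFAULT_CALIBRATION, revel_to_evidence
from .variant_model import (
    Classification,
    EvidenceCode,
    ProteinVariant,
    Strength,
)

__all__ = [
    "EvidenceSet",
    "CombinationConfig",
    "PAPER_MODE",
    "combine",
    "combine_categorical",
    "combine_points",
    "classify_all",
    "compare_to_clinvar",
]


@dataclass(frozen=True)
class EvidenceSet:
    """A set of ACMG/AMP criteria applied to one variant.

    No criterion code may appear twice, and PP3/BP4 may not co-occur (the
    calibration stage emits at most one of them).
    """

    codes: tuple[EvidenceCode, ...]

    def __post_init__(self) -> None:
        names = [c.code for c in self.codes]
        dupes = [c for c, k in Counter(names).items() if k > 1]
        if dupes:
            raise ValueError(f"duplicate criteria in evidence set: {dupes}")
        if "PP3" in names and "BP4" in names:
            raise ValueError("PP3 and BP4 cannot co-occur in one evidence set")

    @classmethod
    def of(cls, *codes: str | EvidenceCode) -> "EvidenceSet":
        return cls(tuple(c if isinstance(c, EvidenceCode) else EvidenceCode.parse(c)
                         for c in codes))

    @property
    def pathogenic_codes(self) -> tuple[EvidenceCode, ...]:
        return tuple(c for c in self.codes if not c.is_benign)

    @property
    def benign_codes(self) -> tuple[EvidenceCode, ...]:
        return tuple(c for c in self.codes if c.is_benign)

    def __str__(self) -> str:
        return "+".join(str(c) for c in self.codes) if self.codes else "(none)"


_DEFAULT_WEIGHTS = {
    Strength.SUPPORTING: 1,
    Strength.MODERATE: 2,
    Strength.STRONG: 4,
    Strength.VERY_STRONG: 8,
    Strength.STAND_ALONE: 8,  # BA1 weighed as very strong
}

_DEFAULT_THRESHOLDS = {
    "pathogenic": 10,        # total >= 10
    "likely_pathogenic": 6,  # 6 <= total <= 9
    "likely_benign": -1,     # -6 <= total <= -1
    "benign": -7,            # total <= -7
}


@dataclass(frozen=True)
class CombinationConfig:
    """How evidence is combined; defaults reproduce the study's behaviour."""

    mode: str = "categorical"  # categorical | points
    pp3_tier_handling: str = "collapse_to_supporting"  # | honor_tier
    conflict_policy: str = "dominant_side_by_points"   # | richards_vus
    weights: Mapping[Strength, int] = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    thresholds: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_THRESHOLDS))

    def __post_init__(self) -> None:
        if self.mode not in ("categorical", "points"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.pp3_tier_handling not in ("collapse_to_supporting", "honor_tier"):
            raise ValueError(f"unknown pp3_tier_handling {self.pp3_tier_handling!r}")
        if self.conflict_policy not in ("dominant_side_by_points", "richards_vus"):
            raise ValueError(f"unknown conflict_policy {self.conflict_policy!r}")

    @classmethod
    def from_yaml(cls, path) -> "CombinationConfig":
        """Load a config from a YAML file of flat keys; absent keys default."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("mode", "pp3_tier_handling", "conflict_policy"):
            if key in raw:
                kwargs[key] = raw[key]
        if "weights" in raw:
            kwargs["weights"] = {Strength(k): int(v) for k, v in raw["weights"].items()}
        if "thresholds" in raw:
            kwargs["thresholds"] = {k: int(v) for k, v in raw["thresholds"].items()}
        return cls(**kwargs)


#: The configuration that reproduces the study's published classifications.
PAPER_MODE = CombinationConfig()


def _effective_strength(code: EvidenceCode, cfg: CombinationConfig) -> Strength:
    if cfg.pp3_tier_handling == "collapse_to_supporting" and code.code in ("PP3", "BP4"):
        return code.default_strength  # PP/BP letter class => supporting
    return code.strength


def _side_points(codes: Iterable[EvidenceCode], cfg: CombinationConfig) -> int:
    return sum(cfg.weights[_effective_strength(c, cfg)] for c in codes)


def _resolve_conflict(ev: EvidenceSet, cfg: CombinationConfig) -> EvidenceSet | None:
    """Apply the conflict policy; ``None`` means the set resolves to VUS."""
    path, ben = ev.pathogenic_codes, ev.benign_codes
    if not path or not ben:
        return ev
    if cfg.conflict_policy == "richards_vus":
        return None
    p_mass = _side_points(path, cfg)
    b_mass = _side_points(ben, cfg)
    if p_mass == b_mass:
        return None
    return EvidenceSet(path if p_mass > b_mass else ben)


def combine_categorical(ev: EvidenceSet, cfg: CombinationConfig = PAPER_MODE,
                        ) -> Classification:
    """Classify an evidence set with the categorical ACMG/AMP rule table."""
    resolved = _resolve_conflict(ev, cfg)
    if resolved is None:
        return Classification.VUS

    strengths = Counter(_effective_strength(c, cfg) for c in resolved.codes)
    if resolved.benign_codes:
        ba = any(c.code == "BA1" for c in resolved.codes)
        n_bs = strengths[Strength.STRONG]
        n_bp = strengths[Strength.SUPPORTING]
        if ba or n_bs >= 2:
            return Classification.BENIGN
        if (n_bs == 1 and n_bp >= 1) or n_bp >= 2:
            return Classification.LIKELY_BENIGN
        return Classification.VUS

    n_vs = strengths[Strength.VERY_STRONG]
    n_s = strengths[Strength.STRONG]
    n_m = strengths[Strength.MODERATE]
    n_p = strengths[Strength.SUPPORTING]
    if (n_vs >= 1 and (n_s >= 1 or n_m >= 2 or (n_m == 1 and n_p == 1) or n_p >= 2)) \
            or n_s >= 2 \
            or (n_s == 1 and (n_m >= 3 or (n_m == 2 and n_p >= 2)
                              or (n_m == 1 and n_p >= 4))):
        return Classification.PATHOGENIC
    if (n_vs == 1 and n_m == 1) \
            or (n_s == 1 and 1 <= n_m <= 2) \
            or (n_s == 1 and n_p >= 2) \
            or n_m >= 3 \
            or (n_m == 2 and n_p >= 2) \
            or (n_m == 1 and n_p >= 4):
        return Classification.LIKELY_PATHOGENIC
    return Classification.VUS


def combine_points(ev: EvidenceSet, cfg: CombinationConfig = PAPER_MODE,
                   ) -> tuple[Classification, int]:
    """Classify by summed criterion points; returns (class, total points)."""
    total = _side_points(ev.pathogenic_codes, cfg) - _side_points(ev.benign_codes, cfg)
    t = cfg.thresholds
    if total >= t["pathogenic"]:
        cls = Classification.PATHOGENIC
    elif total >= t["likely_pathogenic"]:
        cls = Classification.LIKELY_PATHOGENIC
    elif total <= t["benign"]:
        cls = Classification.BENIGN
    elif total <= t["likely_benign"]:
        cls = Classification.LIKELY_BENIGN
    else:
        cls = Classification.VUS
    return cls, total


def combine(ev: EvidenceSet, cfg: CombinationConfig = PAPER_MODE) -> Classification:
    """Classify under whichever mode the config selects."""
    if cfg.mode == "points":
        return combine_points(ev, cfg)[0]
    return combine_categorical(ev, cfg)


# --------------------------------------------------------------------------
# ClinVar comparison
# --------------------------------------------------------------------------

def compare_to_clinvar(ours: Classification, clinvar_label: str) -> str:
    """Compare our classification with a prior ClinVar label.

    Returns one of ``Unchanged``, ``Upgraded``, ``Downgraded``,
    ``First classification``.  ``NP`` (no entry) yields a first
    classification; ``CS`` (conflicting submissions) is compared as a
    VUS-equivalent; the range label ``P/LP`` is unchanged when our call
    falls inside it.
    """
    label = clinvar_label.strip()
    if label == "NP":
        return "First classification"
    if label == "P/LP":
        if ours in (Classification.LIKELY_PATHOGENIC, Classification.PATHOGENIC):
            return "Unchanged"
        return "Downgraded"
    if label == "CS":
        prior = Classification.VUS
    else:
        try:
            prior = Classification.from_label(label)
        except KeyError:
            raise ValueError(f"unknown ClinVar label {clinvar_label!r}") from None
    if ours == prior:
        return "Unchanged"
    return "Upgraded" if ours > prior else "Downgraded"


# --------------------------------------------------------------------------
# whole-table classification
# --------------------------------------------------------------------------

def evidence_for(variant: ProteinVariant,
                 calibration: CalibrationTable = DEFAULT_CALIBRATION,
                 ) -> EvidenceSet:
    """Assemble a variant's full evidence set: curated codes plus the
    REVEL-derived PP3/BP4 code (missense variants with a REVEL score only)."""
    codes = list(variant.asserted_evidence)
    if variant.is_missense and variant.scores.revel is not None:
        comp = revel_to_evidence(variant.scores.revel, calibration)
        if comp is not None:
            codes.append(comp)
    return EvidenceSet(tuple(codes))


def classify_all(variants: Sequence[ProteinVariant],
                 cfg: CombinationConfig = PAPER_MODE,
                 calibration: CalibrationTable = DEFAULT_CALIBRATION,
                 ) -> tuple[pd.DataFrame, dict]:
    """Classify every variant; returns (per-variant table, class histogram).

    The table has one row per input variant with columns ``variant``,
    ``type``, ``evidence`` (the combined criteria string), ``classification``,
    ``points`` (points-mode total, always computed), ``clinvar`` and
    ``comparison``.  The histogram maps class label -> count over all rows.
    """
    rows = []
    hist: Counter = Counter()
    for v in variants:
        ev = evidence_for(v, calibration)
        cls = combine(ev, cfg)
        _, points = combine_points(ev, cfg)
        hist[cls.value] += 1
        rows.append({
            "variant": v.id,
            "type": v.vtype.value,
            "evidence": str(ev),
            "classification": cls.value,
            "points": points,
            "clinvar": v.clinvar_label,
            "comparison": compare_to_clinvar(cls, v.clinvar_label),
        })
    return pd.DataFrame(rows, columns=["variant", "type", "evidence", "classification",
                                       "points", "clinvar", "comparison"]), dict(hist)
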