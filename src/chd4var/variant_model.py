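"""Domain types, protein-HGVS parsing and TSV I/O for CHD4 variant tables.

The central container is :class:`ProteinVariant`: one variant of the 1912-residue
chromatin remodeler CHD4, carrying its protein-level notation, predictor scores,
curated (non-computational) ACMG/AMP evidence codes, population frequency,
ClinVar label and phenotype annotation.  Variant tables are plain UTF-8 TSV
files with a header row; the packaged study fixture (``chd4_table1.tsv``)
transcribes the 36 variants analysed in the source study.
"""

from __future__ import annotations

import importlib.resources
import io
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CHD4_LENGTH",
    "AMINO_ACIDS",
    "VariantType",
    "Strength",
    "EvidenceCode",
    "Classification",
    "PredictorScores",
    "PhenotypeAnnotation",
    "ProteinChange",
    "ProteinVariant",
    "ParseError",
    "SchemaError",
    "parse_protein_change",
    "format_protein_change",
    "read_variant_table",
    "write_variant_table",
    "load_study_fixture",
    "frequency_filter",
]

#: Length of the CHD4 protein (UniProt Q14839).
CHD4_LENGTH = 1912

#: Canonical one-letter amino-acid codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

#: TSV columns that must be present in every variant table.
MANDATORY_COLUMNS = (
    "variant", "type", "metarnn", "polyphen2", "alphamissense", "revel",
    "evidence", "clinvar", "heart_anomaly",
)

#: Recognised ClinVar labels (NP = no entry, CS = conflicting submissions).
CLINVAR_LABELS = ("P", "LP", "P/LP", "VUS", "CS", "LB", "B", "NP")


class ParseError(ValueError):
    """A protein-HGVS string or table cell could not be parsed."""


class SchemaError(ValueError):
    """A variant table violates the documented column schema."""


class VariantType(str, Enum):
    MISSENSE = "missense"
    SPLICE_DONOR = "splice_donor"
    INFRAME_DUP = "inframe_dup"
    INFRAME_DEL = "inframe_del"


class Strength(str, Enum):
    """ACMG/AMP evidence strength tiers, ordered weakest to strongest."""

    SUPPORTING = "supporting"
    MODERATE = "moderate"
    STRONG = "strong"
    VERY_STRONG = "very_strong"
    STAND_ALONE = "stand_alone"


_CODE_RE = re.compile(
    r"^(PVS1|PS[1-4]|PM[1-6]|PP[1-5]|BA1|BS[1-4]|BP[1-7])(?:_(\w+))?$"
)

_DEFAULT_STRENGTH = {
    "PVS": Strength.VERY_STRONG,
    "PS": Strength.STRONG,
    "PM": Strength.MODERATE,
    "PP": Strength.SUPPORTING,
    "BA": Strength.STAND_ALONE,
    "BS": Strength.STRONG,
    "BP": Strength.SUPPORTING,
}


@dataclass(frozen=True)
class EvidenceCode:
    """One ACMG/AMP criterion, optionally with a non-default strength.

    Strength overrides are only meaningful for the computational criteria
    PP3/BP4, whose strength is set by REVEL-score calibration; every other
    code carries the default strength of its letter class.
    """

    code: str
    strength: Strength = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = _CODE_RE.match(self.code)
        if m is None:
            raise ParseError(f"unknown ACMG criterion code: {self.code!r}")
        if self.strength is None:
            object.__setattr__(self, "strength", self.default_strength)
        elif self.strength != self.default_strength and self.code not in ("PP3", "BP4"):
            raise ParseError(
                f"strength override {self.strength.value!r} only permitted "
                f"for PP3/BP4, not {self.code}"
            )

    @property
    def letter_class(self) -> str:
        return self.code[:-1] if self.code[-1].isdigit() else self.code

    @property
    def default_strength(self) -> Strength:
        return _DEFAULT_STRENGTH[self.letter_class]

    @property
    def is_benign(self) -> bool:
        return self.code.startswith("B")

    def __str__(self) -> str:
        if self.strength != self.default_strength:
            return f"{self.code}_{self.strength.value}"
        return self.code

    @property
    def tier_label(self) -> str:
        """Code with its strength always spelled out (e.g. ``PP3_supporting``)."""
        return f"{self.code}_{self.strength.value}"

    @classmethod
    def parse(cls, text: str) -> "EvidenceCode":
        """Parse e.g. ``"PS2"`` or ``"PP3_strong"``."""
        m = _CODE_RE.match(text.strip())
        if m is None:
            raise ParseError(f"unknown ACMG criterion code: {text!r}")
        code, suffix = m.groups()
        strength = Strength(suffix) if suffix else None
        return cls(code, strength)


class Classification(Enum):
    """Five-tier ACMG/AMP verdict, totally ordered from benign to pathogenic."""

    BENIGN = "Benign"
    LIKELY_BENIGN = "Likely benign"
    VUS = "VUS"
    LIKELY_PATHOGENIC = "Likely pathogenic"
    PATHOGENIC = "Pathogenic"

    @property
    def rank(self) -> int:
        return _CLASS_RANK[self]

    def __lt__(self, other: "Classification") -> bool:
        return self.rank < other.rank

    def __le__(self, other: "Classification") -> bool:
        return self.rank <= other.rank

    def __gt__(self, other: "Classification") -> bool:
        return self.rank > other.rank

    def __ge__(self, other: "Classification") -> bool:
        return self.rank >= other.rank

    @classmethod
    def from_label(cls, label: str) -> "Classification":
        return _CLASS_ALIASES[label.strip()]


_CLASS_RANK = {
    Classification.BENIGN: 0,
    Classification.LIKELY_BENIGN: 1,
    Classification.VUS: 2,
    Classification.LIKELY_PATHOGENIC: 3,
    Classification.PATHOGENIC: 4,
}

_CLASS_ALIASES = {
    "B": Classification.BENIGN,
    "Benign": Classification.BENIGN,
    "LB": Classification.LIKELY_BENIGN,
    "Likely benign": Classification.LIKELY_BENIGN,
    "VUS": Classification.VUS,
    "LP": Classification.LIKELY_PATHOGENIC,
    "Likely pathogenic": Classification.LIKELY_PATHOGENIC,
    "P": Classification.PATHOGENIC,
    "Pathogenic": Classification.PATHOGENIC,
}


@dataclass(frozen=True)
class PredictorScores:
    """Per-tool pathogenicity scores in [0, 1]; ``None`` marks an absent score."""

    metarnn: float | None = None
    polyphen2: float | None = None
    alphamissense: float | None = None
    revel: float | None = None

    def __post_init__(self) -> None:
        for tool in ("metarnn", "polyphen2", "alphamissense", "revel"):
            v = getattr(self, tool)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{tool} score {v} outside [0, 1]")

    def get(self, tool: str) -> float | None:
        return getattr(self, tool)

    @property
    def complete(self) -> bool:
        return None not in (self.metarnn, self.polyphen2, self.alphamissense, self.revel)


@dataclass(frozen=True)
class PhenotypeAnnotation:
    """Cardiovascular phenotype flags attached to the carrier(s) of a variant."""

    heart_anomaly: str = "unknown"  # yes / no / unknown
    disease_labels: tuple[str, ...] = ()
    syndrome: str = "other"  # SIHIWES / MMA / IP_sinus_arrhythmia / other

    def __post_init__(self) -> None:
        if self.heart_anomaly not in ("yes", "no", "unknown"):
            raise ValueError(f"heart_anomaly must be yes/no/unknown, got {self.heart_anomaly!r}")


@dataclass(frozen=True)
class ProteinChange:
    """A parsed protein-level change: substitution or in-frame dup/del span."""

    ref_aa: str
    start: int
    end: int
    alt_aa: str  # empty for non-missense events
    vtype: VariantType
    #: identity substitutions (e.g. p.A1A) are flagged, not rejected
    synonymous: bool = False
    #: reference residue at ``end`` for multi-residue dup/del spans
    end_ref_aa: str = ""


# --------------------------------------------------------------------------
# protein-HGVS grammar
# --------------------------------------------------------------------------

_AA1 = f"[{AMINO_ACIDS}]"
_AA3 = "|".join(_THREE_TO_ONE)
_AA = f"(?:{_AA3}|{_AA1})"
_SUB_RE = re.compile(rf"^(?:p\.)?\s*({_AA})(\d+)({_AA})$")
_SPAN_RE = re.compile(rf"^(?:p\.)?\s*({_AA})(\d+)(?:_({_AA})(\d+))?(dup|del)$")


def _norm_aa(token: str) -> str:
    return _THREE_TO_ONE.get(token, token)


def parse_protein_change(text: str) -> ProteinChange:
    """Parse a protein-HGVS-like string into a normalized :class:`ProteinChange`.

    Accepts one- and three-letter amino-acid codes and an optional ``p.``
    prefix; substitutions (``p.M202I``), single-residue or span duplications
    and deletions (``p.Leu1009_Val1011dup``, ``p.C1012del``) are recognised.
    Identity substitutions are returned with ``synonymous=True``.

    Raises
    ------
    ParseError
        If the grammar does not match, or a residue lies outside
        [1, 1912].
    """
    if not text or not text.strip():
        raise ParseError("empty protein change string")
    s = text.strip()

    m = _SPAN_RE.match(s)
    if m:
        ref1, pos1, ref2, pos2, kind = m.groups()
        start = int(pos1)
        end = int(pos2) if pos2 else start
        _check_range(start, end, s)
        vtype = VariantType.INFRAME_DUP if kind == "dup" else VariantType.INFRAME_DEL
        return ProteinChange(_norm_aa(ref1), start, end, "", vtype,
                             end_ref_aa=_norm_aa(ref2) if ref2 else "")

    m = _SUB_RE.match(s)
    if m:
        ref, pos, alt = m.groups()
        start = int(pos)
        _check_range(start, start, s)
        ref1, alt1 = _norm_aa(ref), _norm_aa(alt)
        return ProteinChange(ref1, start, start, alt1, VariantType.MISSENSE,
                             synonymous=(ref1 == alt1))

    raise ParseError(f"malformed protein change: {text!r}")


def _check_range(start: int, end: int, text: str) -> None:
    if not (1 <= start <= end <= CHD4_LENGTH):
        raise ParseError(
            f"residue span {start}-{end} outside [1, {CHD4_LENGTH}] in {text!r}"
        )


def format_protein_change(change: ProteinChange) -> str:
    """Render a :class:`ProteinChange` in normalized one-letter notation."""
    if change.vtype == VariantType.MISSENSE:
        return f"p.{change.ref_aa}{change.start}{change.alt_aa}"
    suffix = "dup" if change.vtype == VariantType.INFRAME_DUP else "del"
    if change.end > change.start:
        return f"p.{change.ref_aa}{change.start}_{change.end_ref_aa}{change.end}{suffix}"
    return f"p.{change.ref_aa}{change.start}{suffix}"


@dataclass(frozen=True)
class ProteinVariant:
    """One CHD4 variant with notation, scores, curated evidence and phenotype."""

    id: str
    vtype: VariantType
    change: ProteinChange | None = None  # None for splice variants
    cdna_change: str | None = None
    scores: PredictorScores = field(default_factory=PredictorScores)
    asserted_evidence: tuple[EvidenceCode, ...] = ()
    gnomad_af: float | None = None
    clinvar_label: str = "NP"
    phenotype: PhenotypeAnnotation = field(default_factory=PhenotypeAnnotation)
    #: columns of the source table not part of the schema, raw strings
    annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vtype == VariantType.SPLICE_DONOR:
            if not self.cdna_change:
                raise ValueError(f"{self.id}: splice variants require a cDNA notation")
        elif self.change is None:
            raise ValueError(f"{self.id}: protein-level variants require a parsed change")
        if self.change is not None and self.change.vtype != self.vtype:
            raise ValueError(f"{self.id}: declared type {self.vtype.value} does not "
                             f"match notation-derived type {self.change.vtype.value}")
        if self.clinvar_label not in CLINVAR_LABELS:
            raise ValueError(f"{self.id}: unknown ClinVar label {self.clinvar_label!r}")
        if self.gnomad_af is not None and not (0.0 <= self.gnomad_af <= 1.0):
            raise ValueError(f"{self.id}: gnomAD AF {self.gnomad_af} outside [0, 1]")
        codes = [e.code for e in self.asserted_evidence]
        if len(set(codes)) != len(codes):
            raise ValueError(f"{self.id}: duplicate evidence codes in {codes}")

    @property
    def residue_span(self) -> tuple[int, int] | None:
        """1-based inclusive residue span, or None (splice variant)."""
        if self.change is None:
            return None
        return (self.change.start, self.change.end)

    @property
    def is_missense(self) -> bool:
        return self.vtype == VariantType.MISSENSE


# --------------------------------------------------------------------------
# TSV reading / writing
# --------------------------------------------------------------------------

def _parse_float(cell: str, what: str, row: int) -> float | None:
    if cell is None or cell == "" or pd.isna(cell):
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise ParseError(f"row {row}: unparseable {what} {cell!r}") from exc


def _parse_evidence_string(text: str) -> tuple[EvidenceCode, ...]:
    """Parse a '+'-separated criteria string, dropping the computational
    PP3/BP4 codes (those are recomputed from REVEL by the calibration stage)."""
    if not text or pd.isna(text):
        return ()
    codes = []
    for tok in str(text).split("+"):
        tok = tok.strip()
        if not tok:
            continue
        code = EvidenceCode.parse(tok)
        if code.code in ("PP3", "BP4"):
            continue
        codes.append(code)
    return tuple(codes)


def read_variant_table(path: str | Path | io.TextIOBase) -> list[ProteinVariant]:
    """Read a variant TSV into validated :class:`ProteinVariant` records.

    Mandatory columns: ``variant``, ``type``, ``metarnn``, ``polyphen2``,
    ``alphamissense``, ``revel``, ``evidence``, ``clinvar``,
    ``heart_anomaly``.  ``evidence`` is a '+'-separated ACMG criteria string
    (e.g. ``PS2+PM2+PP3``); PP3/BP4 tokens are accepted but excluded from
    ``asserted_evidence`` since the pipeline re-derives them from the REVEL
    score.  Unknown columns are preserved verbatim in ``annotations``.
    Lines starting with ``#`` are comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"variant table missing mandatory column(s): {missing}")
    extra_cols = [c for c in df.columns if c not in MANDATORY_COLUMNS]

    variants: list[ProteinVariant] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        vtype = VariantType(rec["type"])
        change = None
        if vtype != VariantType.SPLICE_DONOR:
            change = parse_protein_change(rec["variant"])
        scores = PredictorScores(
            metarnn=_parse_float(rec["metarnn"], "metarnn score", i),
            polyphen2=_parse_float(rec["polyphen2"], "polyphen2 score", i),
            alphamissense=_parse_float(rec["alphamissense"], "alphamissense score", i),
            revel=_parse_float(rec["revel"], "revel score", i),
        )
        pheno = PhenotypeAnnotation(
            heart_anomaly=(rec["heart_anomaly"] or "unknown"),
            disease_labels=tuple(t for t in (rec.get("diseases") or "").split("+") if t),
            syndrome=(rec.get("syndrome") or "other"),
        )
        annotations = {c: rec[c] for c in extra_cols}
        annotations["_evidence_raw"] = rec["evidence"]
        for tool in ("metarnn", "polyphen2", "alphamissense", "revel"):
            annotations[f"_raw_{tool}"] = rec[tool]
        variants.append(ProteinVariant(
            id=rec["variant"],
            vtype=vtype,
            change=change,
            cdna_change=(rec.get("cdna") or None),
            scores=scores,
            asserted_evidence=_parse_evidence_string(rec["evidence"]),
            gnomad_af=_parse_float(rec.get("gnomad_af", ""), "gnomAD AF", i),
            clinvar_label=(rec["clinvar"] or "NP"),
            phenotype=pheno,
            annotations=annotations,
        ))
    return variants


def write_variant_table(variants: Sequence[ProteinVariant],
                        path: str | Path | io.TextIOBase) -> None:
    """Write variants back to TSV.

    Mandatory columns round-trip byte-stably with :func:`read_variant_table`:
    score cells and the evidence string are emitted from the raw strings
    preserved at read time when available.
    """
    rows = []
    for v in variants:
        ann = dict(v.annotations)
        raw_ev = ann.pop("_evidence_raw", None)
        if raw_ev is None:
            raw_ev = "+".join(str(c) for c in v.asserted_evidence)
        row = {
            "variant": v.id,
            "type": v.vtype.value,
            "metarnn": ann.pop("_raw_metarnn", _fmt_score(v.scores.metarnn)),
            "polyphen2": ann.pop("_raw_polyphen2", _fmt_score(v.scores.polyphen2)),
            "alphamissense": ann.pop("_raw_alphamissense", _fmt_score(v.scores.alphamissense)),
            "revel": ann.pop("_raw_revel", _fmt_score(v.scores.revel)),
            "evidence": raw_ev,
            "clinvar": v.clinvar_label,
            "heart_anomaly": v.phenotype.heart_anomaly,
        }
        row.update(ann)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _fmt_score(v: float | None) -> str:
    return "" if v is None else format(v, "g")


def load_study_fixture() -> list[ProteinVariant]:
    """Load the packaged 36-variant CHD4 study fixture."""
    ref = importlib.resources.files("chd4var.data").joinpath("chd4_table1.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return read_variant_table(fh)


def fixture_path() -> Path:
    """Filesystem path of the packaged study fixture TSV."""
    return Path(str(importlib.resources.files("chd4var.data").joinpath("chd4_table1.tsv")))


def frequency_filter(variants: Iterable[ProteinVariant],
                     af_threshold: float = 0.001,
                     ) -> tuple[list[ProteinVariant], list[ProteinVariant]]:
    """Split variants into (kept, removed) by gnomAD allele frequency.

    A variant is removed iff its allele frequency is present and strictly
    greater than ``af_threshold`` (default 0.001); variants with no
    recorded frequency are kept.
    """
    if not (0.0 < af_threshold < 1.0):
        raise ValueError(f"af_threshold must be in (0, 1), got {af_threshold}")
    kept, removed = [], []
    for v in variants:
        (removed if (v.gnomad_af is not None and v.gnomad_af > af_threshold) else kept).append(v)
    return kept, removed
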