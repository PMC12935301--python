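"""The CHD4 domain map as named residue intervals, and variant localisation.

The architecture is shipped as a versioned TSV (``chd4_domains.tsv``) with
columns ``name``, ``parent``, ``kind``, ``start``, ``end``, ``note`` so that
other proteins can be described in the same format.  Intervals are 1-based
inclusive.  Three kinds are distinguished: top-level ``domain`` entries
(mutually non-overlapping), ``subdomain`` entries nested inside a parent
(sibling overlaps such as C1a vs. the first disordered segment are allowed
and both reported), and ``composite`` spans that union other intervals —
notably ``ATPase_motor_region`` (731-1192), the contiguous ATPase + inter-lobe
linker + helicase span used as the enrichment grouping.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .variant_model import CHD4_LENGTH, ProteinVariant

__all__ = [
    "DomainInterval",
    "DomainArchitecture",
    "DomainHit",
    "load_chd4_architecture",
    "locate",
    "count_by_region",
]


@dataclass(frozen=True)
class DomainInterval:
    name: str
    start: int
    end: int
    kind: str = "domain"  # domain | subdomain | composite
    parent: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.name}: invalid interval {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def intersects(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered set of named residue intervals over a protein."""

    intervals: tuple[DomainInterval, ...]
    protein_length: int = CHD4_LENGTH

    def __post_init__(self) -> None:
        names = [iv.name for iv in self.intervals]
        if len(set(names)) != len(names):
            raise ValueError("duplicate interval names in architecture")
        for iv in self.intervals:
            if iv.end > self.protein_length:
                raise ValueError(f"{iv.name}: end {iv.end} beyond protein "
                                 f"length {self.protein_length}")
            if iv.parent:
                parent = self[iv.parent]
                if not (parent.start <= iv.start and iv.end <= parent.end):
                    raise ValueError(f"{iv.name} does not nest within parent {iv.parent}")
        tops = sorted(self.top_level, key=lambda iv: iv.start)
        for a, b in zip(tops, tops[1:]):
            if a.end >= b.start:
                raise ValueError(f"top-level domains {a.name} and {b.name} overlap")

    def __getitem__(self, name: str) -> DomainInterval:
        for iv in self.intervals:
            if iv.name == name:
                return iv
        raise KeyError(f"unknown region {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(iv.name == name for iv in self.intervals)

    @property
    def top_level(self) -> tuple[DomainInterval, ...]:
        return tuple(iv for iv in self.intervals if iv.kind == "domain")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"name": iv.name, "parent": iv.parent, "kind": iv.kind,
              "start": iv.start, "end": iv.end, "note": iv.note}
             for iv in self.intervals]
        )

    @classmethod
    def from_tsv(cls, path, protein_length: int = CHD4_LENGTH) -> "DomainArchitecture":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
        ivs = tuple(
            DomainInterval(name=r["name"], parent=r["parent"], kind=r["kind"],
                           start=int(r["start"]), end=int(r["end"]), note=r["note"])
            for r in df.to_dict("records")
        )
        return cls(ivs, protein_length)


def load_chd4_architecture() -> DomainArchitecture:
    """Load the packaged CHD4 (1912 aa) architecture."""
    ref = importlib.resources.files("chd4var.data").joinpath("chd4_domains.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return DomainArchitecture.from_tsv(fh)


@dataclass(frozen=True)
class DomainHit:
    """Where a residue span falls in the architecture.

    ``domains`` lists all non-composite intervals intersecting the span,
    most specific (smallest) first, ties broken by start position;
    ``composites`` lists intersecting composite spans.  If no non-composite
    interval is hit, ``interdomain`` names the flanking top-level domains
    and ``top_level`` reads ``interdomain(left,right)``.
    """

    span: tuple[int, int]
    domains: tuple[str, ...]
    composites: tuple[str, ...] = ()
    interdomain: tuple[str, str] | None = None

    @property
    def top_level(self) -> str:
        if self.interdomain is not None:
            return f"interdomain({self.interdomain[0]},{self.interdomain[1]})"
        return self.domains[-1] if self.domains else ""


def locate(span: tuple[int, int], arch: DomainArchitecture) -> DomainHit:
    """Locate a residue span within the architecture.

    Returns every interval intersecting the span; a span that touches no
    domain or subdomain is labelled interdomain with its flanking top-level
    domains.  Raises ``ValueError`` for spans outside the protein.
    """
    start, end = span
    if not (1 <= start <= end <= arch.protein_length):
        raise ValueError(f"span {span} outside [1, {arch.protein_length}]")
    hits = [iv for iv in arch.intervals
            if iv.kind != "composite" and iv.intersects(start, end)]
    hits.sort(key=lambda iv: (iv.length, iv.start))
    composites = tuple(iv.name for iv in arch.intervals
                       if iv.kind == "composite" and iv.intersects(start, end))
    interdomain = None
    if not hits:
        left = [iv for iv in arch.top_level if iv.end < start]
        right = [iv for iv in arch.top_level if iv.start > end]
        left_name = max(left, key=lambda iv: iv.end).name if left else "N-terminus"
        right_name = min(right, key=lambda iv: iv.start).name if right else "C-terminus"
        interdomain = (left_name, right_name)
    # order: most specific first, then enclosing intervals by increasing size;
    # finish with top-level container last so `top_level` reads naturally
    return DomainHit(span=(start, end),
                     domains=tuple(iv.name for iv in hits),
                     composites=composites,
                     interdomain=interdomain)


def count_by_region(variants: Iterable[ProteinVariant], region: str,
                    arch: DomainArchitecture) -> int:
    """Count variants whose protein span intersects ``region``.

    Variants without a protein span (splice variants) are excluded.
    Raises ``KeyError`` for a region not defined in the architecture.
    """
    iv = arch[region]
    n = 0
    for v in variants:
        span = v.residue_span
        if span is not None and iv.intersects(*span):
            n += 1
    return n
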