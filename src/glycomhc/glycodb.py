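"""Glycan composition database: masses, parsing, generation, classification.

A glycan is represented purely as a monosaccharide composition (no topology).
The default database is generated combinatorially within per-residue count
limits and a global mass window; users can instead load an explicit TSV.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .constants import MONOSACCHARIDE_MASSES, MONOSACCHARIDE_ORDER

TRUNCATED = "truncated"
HIGH_MANNOSE = "high-mannose"
COMPLEX_HYBRID = "complex/hybrid"

TYPE_CLASSES = (TRUNCATED, HIGH_MANNOSE, COMPLEX_HYBRID)


class MonosaccharideTable(dict):
    """Residue name -> monoisotopic residue mass (Da)."""

    def __init__(self, entries: Mapping[str, float] | None = None):
        super().__init__(entries if entries is not None else MONOSACCHARIDE_MASSES)
        for name, mass in self.items():
            if mass <= 0:
                raise ValueError(f"non-positive mass for residue {name!r}: {mass}")


DEFAULT_TABLE = MonosaccharideTable()

_TOKEN_RE = re.compile(r"([A-Za-z]+)\((\d+)\)")


@dataclass(frozen=True)
class GlycanComposition:
    """Immutable monosaccharide count vector with a derived mass."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self):
        if not self.counts or all(c == 0 for _, c in self.counts):
            raise ValueError("empty glycan composition")
        for name, count in self.counts:
            if count < 0:
                raise ValueError(f"negative count for {name!r}")

    @classmethod
    def from_dict(cls, counts: Mapping[str, int]) -> "GlycanComposition":
        ordered = tuple(
            (name, counts[name])
            for name in _canonical_names(counts)
            if counts[name] > 0
        )
        return cls(ordered)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def get(self, name: str) -> int:
        return dict(self.counts).get(name, 0)

    @property
    def mass(self) -> float:
        return glycan_mass(self, DEFAULT_TABLE)

    @property
    def type_class(self) -> str:
        return classify_glycan(self)

    def __str__(self) -> str:
        return format_glycan(self)


def _canonical_names(counts: Mapping[str, int]) -> list[str]:
    known = [n for n in MONOSACCHARIDE_ORDER if n in counts]
    extra = sorted(n for n in counts if n not in MONOSACCHARIDE_ORDER)
    return known + extra


def glycan_mass(comp: GlycanComposition, table: Mapping[str, float] = DEFAULT_TABLE) -> float:
    """Sum of count * residue mass over the composition.

    Raises ``KeyError``-derived :class:`ValueError` naming any residue
    absent from *table*.
    """
    total = 0.0
    for name, count in comp.counts:
        if name not in table:
            raise ValueError(f"unknown monosaccharide residue: {name!r}")
        total += count * table[name]
    return total


def format_glycan(comp: GlycanComposition) -> str:
    """Canonical 'Name(count)...' string in fixed residue order."""
    return "".join(f"{name}({count})" for name, count in comp.counts)


def parse_glycan_string(text: str) -> GlycanComposition:
    """Parse 'HexNAc(2)Hex(5)...' into a composition (order-insensitive).

    Malformed input raises ``ValueError`` with the character offset of the
    first unparseable token.
    """
    counts: dict[str, int] = {}
    pos = 0
    text = text.strip()
    if not text:
        raise ValueError("empty glycan string")
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ValueError(f"malformed glycan token at offset {pos}: {text[pos:pos+12]!r}")
        name, count = m.group(1), int(m.group(2))
        counts[name] = counts.get(name, 0) + count
        pos = m.end()
    return GlycanComposition.from_dict(counts)


@dataclass(frozen=True)
class ClassificationRule:
    """Count thresholds separating truncated / high-mannose / complex-hybrid.

    The boundaries are conventions, not measurements, so every threshold is
    overridable.
    """

    truncated_max_hexnac: int = 2
    truncated_max_hex: int = 3
    high_mannose_min_hex: int = 4


DEFAULT_RULE = ClassificationRule()


def classify_glycan(comp: GlycanComposition, rule: ClassificationRule = DEFAULT_RULE) -> str:
    """Assign exactly one type class to a composition.

    high-mannose: the Man-extended core (HexNAc2 Hex>=4) with no fucose or
    sialic acid. truncated: at or below the N-glycan core (HexNAc<=2,
    Hex<=3) without sialylation. Everything else is complex/hybrid.
    """
    hexnac = comp.get("HexNAc")
    hexose = comp.get("Hex")
    fuc = comp.get("Fuc")
    sialic = comp.get("NeuAc") + comp.get("NeuGc")
    if hexnac == 2 and hexose >= rule.high_mannose_min_hex and fuc == 0 and sialic == 0:
        return HIGH_MANNOSE
    if hexnac <= rule.truncated_max_hexnac and hexose <= rule.truncated_max_hex and sialic == 0:
        return TRUNCATED
    return COMPLEX_HYBRID


@dataclass(frozen=True)
class GlycanLimits:
    """Per-residue maximum counts plus a global mass window for generation."""

    max_counts: tuple[tuple[str, int], ...] = (
        ("HexNAc", 6), ("Hex", 10), ("Fuc", 3), ("NeuAc", 4), ("NeuGc", 0),
    )
    min_mass: float = 145.0
    max_mass: float = 4000.0

    def as_dict(self) -> dict[str, int]:
        return dict(self.max_counts)


DEFAULT_LIMITS = GlycanLimits()


def build_default_glycan_db(
    limits: GlycanLimits = DEFAULT_LIMITS,
    table: Mapping[str, float] = DEFAULT_TABLE,
) -> list[GlycanComposition]:
    """Enumerate every composition within the limits, mass-sorted.

    The N-glycan core HexNAc(2)Hex(3) and its truncations down to HexNAc(1)
    fall inside the default limits by construction.
    """
    maxima = limits.as_dict()
    if not maxima or all(v == 0 for v in maxima.values()):
        raise ValueError("empty glycan limit set")
    names = [n for n in maxima if maxima[n] > 0]
    out: list[GlycanComposition] = []
    for combo in itertools.product(*(range(maxima[n] + 1) for n in names)):
        if sum(combo) == 0:
            continue
        comp = GlycanComposition.from_dict(dict(zip(names, combo)))
        m = glycan_mass(comp, table)
        if limits.min_mass <= m <= limits.max_mass:
            out.append(comp)
    out.sort(key=lambda c: (glycan_mass(c, table), format_glycan(c)))
    return out


def read_glycan_tsv(path: str | Path, table: Mapping[str, float] = DEFAULT_TABLE,
                    mass_tol_da: float = 0.01) -> list[GlycanComposition]:
    """Load a glycan TSV with columns ``composition`` and optional ``mass``.

    A declared mass is recomputed and checked against the composition.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if "composition" not in df.columns:
        raise ValueError("glycan TSV must have a 'composition' column")
    comps = []
    for _, row in df.iterrows():
        comp = parse_glycan_string(str(row["composition"]))
        if "mass" in df.columns and not pd.isna(row["mass"]):
            declared = float(row["mass"])
            computed = glycan_mass(comp, table)
            if abs(declared - computed) > mass_tol_da:
                raise ValueError(
                    f"mass mismatch for {comp}: declared {declared}, computed {computed:.4f}"
                )
        comps.append(comp)
    comps.sort(key=lambda c: (glycan_mass(c, table), format_glycan(c)))
    return comps


def write_glycan_tsv(comps: Iterable[GlycanComposition], path: str | Path) -> None:
    import pandas as pd

    rows = [{"composition": format_glycan(c), "mass": round(c.mass, 6),
             "type_class": c.type_class} for c in comps]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
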