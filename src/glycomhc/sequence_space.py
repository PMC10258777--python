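"""Protein/peptide sequence space: FASTA I/O, reversed decoys, nonspecific
peptide enumeration, sequon detection and mass-indexed candidate lookup.

Decoy proteins are full sequence reversals. Decoy peptides are scanned for
the *reversed* sequon pattern so that the number of potential glycopeptides
is identical between target and decoy space (reversal is a bijection on
substrings, so parity is exact).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from . import constants
from .constants import AA_RESIDUE_MASSES, ISOTOPE_SPACING, peptide_mass

DECOY_PREFIX = "rev_"

_VALID_RESIDUES = frozenset(constants.AMINO_ACIDS) | {"X"}


@dataclass(frozen=True)
class ProteinEntry:
    accession: str
    sequence: str
    is_decoy: bool = False
    species_tag: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession!r}")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in {self.accession!r}")


@dataclass(frozen=True)
class Modification:
    """A single variable modification placed on a peptide.

    position is 0-based within the peptide; -1 denotes the N-terminus.
    """

    position: int
    name: str
    mass_delta: float


@dataclass
class PeptideCandidate:
    """A nonspecific peptide with merged protein provenance."""

    sequence: str
    is_decoy: bool
    protein_refs: list[tuple[str, int, int]]  # (accession, start, end) 0-based half-open
    sequon_positions: tuple[int, ...]
    mass: float = field(init=False)

    def __post_init__(self):
        self.mass = peptide_mass(self.sequence)

    @property
    def has_sequon(self) -> bool:
        return len(self.sequon_positions) > 0

    @property
    def at_protein_nterm(self) -> bool:
        return any(start == 0 for _, start, _ in self.protein_refs)


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide candidate plus a (possibly empty) set of modifications."""

    candidate: PeptideCandidate
    mods: tuple[Modification, ...] = ()

    @property
    def mass(self) -> float:
        return self.candidate.mass + sum(m.mass_delta for m in self.mods)

    @property
    def sequence(self) -> str:
        return self.candidate.sequence

    @property
    def is_decoy(self) -> bool:
        return self.candidate.is_decoy

    def mod_string(self) -> str:
        return ";".join(f"{m.position}:{m.name}" for m in self.mods)


def read_fasta(path: str | Path, entrapment_tag: str | None = None) -> list[ProteinEntry]:
    """Read a FASTA file into ProteinEntry records, order preserved.

    The accession is the full first whitespace-delimited token of the
    header. A header containing ``entrapment_tag`` (when given) or an
    ``OS=<species>`` field is used to populate ``species_tag``.
    """
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in seen:
            raise ValueError(f"duplicate accession in FASTA: {acc!r}")
        seen.add(acc)
        tag = None
        desc = rec.description
        if entrapment_tag and entrapment_tag in desc:
            tag = entrapment_tag
        elif " OS=" in desc:
            tag = desc.split(" OS=", 1)[1].split(" OX=", 1)[0].strip() or None
        entries.append(ProteinEntry(acc, str(rec.seq).upper(),
                                    is_decoy=acc.startswith(DECOY_PREFIX),
                                    species_tag=tag))
    if not entries:
        raise ValueError(f"no FASTA records in {path}")
    return entries


def make_decoys(proteins: Sequence[ProteinEntry], prefix: str = DECOY_PREFIX) -> list[ProteinEntry]:
    """One reversed-sequence decoy per target protein."""
    decoys = []
    for p in proteins:
        if p.is_decoy:
            raise ValueError(f"input protein {p.accession!r} is already a decoy")
        decoys.append(ProteinEntry(prefix + p.accession, p.sequence[::-1],
                                   is_decoy=True, species_tag=p.species_tag))
    return decoys


def find_sequons(sequence: str, is_decoy: bool = False, allow_proline: bool = False) -> list[int]:
    """0-based anchor positions of the N-glycosylation consensus motif.

    Targets match N-X-S/T (X != P unless allow_proline); decoys match the
    reversed pattern S/T-X-N so target/decoy glycopeptide counts stay equal.
    """
    hits = []
    for i in range(len(sequence) - 2):
        a, b, c = sequence[i], sequence[i + 1], sequence[i + 2]
        if not allow_proline and b == "P":
            continue
        if is_decoy:
            if a in ("S", "T") and c == "N":
                hits.append(i)
        else:
            if a == "N" and c in ("S", "T"):
                hits.append(i)
    return hits


def enumerate_nonspecific_peptides(
    proteins: Sequence[ProteinEntry],
    length_range: tuple[int, int] = (7, 25),
    allow_proline_in_sequon: bool = False,
) -> list[PeptideCandidate]:
    """Every substring with length in range, deduplicated by
    (sequence, is_decoy) with merged provenance.

    Substrings containing 'X' are skipped (unknown residue mass).
    """
    lo, hi = length_range
    if not (5 <= lo <= hi <= 60):
        raise ValueError(f"length range must satisfy 5 <= lo <= hi <= 60, got {length_range}")
    by_key: dict[tuple[str, bool], PeptideCandidate] = {}
    for prot in proteins:
        seq = prot.sequence
        n = len(seq)
        for start in range(n):
            for length in range(lo, min(hi, n - start) + 1):
                sub = seq[start:start + length]
                if "X" in sub:
                    continue
                key = (sub, prot.is_decoy)
                cand = by_key.get(key)
                if cand is None:
                    cand = PeptideCandidate(
                        sequence=sub,
                        is_decoy=prot.is_decoy,
                        protein_refs=[],
                        sequon_positions=tuple(find_sequons(
                            sub, prot.is_decoy, allow_proline_in_sequon)),
                    )
                    by_key[key] = cand
                cand.protein_refs.append((prot.accession, start, start + length))
    return list(by_key.values())


@dataclass(frozen=True)
class ModConfig:
    """Variable modification settings expanded at index build."""

    met_oxidation: bool = True
    nterm_acetyl: bool = True          # protein N-terminus only
    cys_cysteinylation: bool = True
    max_mods: int = 2


def expand_modifications(candidate: PeptideCandidate, config: ModConfig) -> list[ModifiedPeptide]:
    """All modification variants of a candidate, up to max_mods mods each.

    The unmodified form is always included and listed first.
    """
    sites: list[Modification] = []
    if config.nterm_acetyl and candidate.at_protein_nterm:
        sites.append(Modification(-1, "Acetyl", constants.MOD_NTERM_ACETYL))
    if config.met_oxidation:
        sites.extend(Modification(i, "Oxidation", constants.MOD_MET_OXIDATION)
                     for i, a in enumerate(candidate.sequence) if a == "M")
    if config.cys_cysteinylation:
        sites.extend(Modification(i, "Cysteinylation", constants.MOD_CYS_CYSTEINYLATION)
                     for i, a in enumerate(candidate.sequence) if a == "C")
    variants = [ModifiedPeptide(candidate, ())]
    import itertools
    for k in range(1, min(config.max_mods, len(sites)) + 1):
        for combo in itertools.combinations(sites, k):
            ordered = tuple(sorted(combo, key=lambda m: m.position))
            variants.append(ModifiedPeptide(candidate, ordered))
    return variants


class PeptideIndex:
    """Mass-sorted index over (modified) peptide candidates.

    Non-glyco lookup matches |precursor - iso*1.00335 - mass| within a ppm
    tolerance for iso in the allowed set; glyco lookup additionally offsets
    by a glycan mass and is restricted to sequon-bearing candidates.
    """

    def __init__(self, candidates: Sequence[PeptideCandidate],
                 mod_config: ModConfig | None = None):
        mod_config = mod_config if mod_config is not None else ModConfig()
        variants: list[ModifiedPeptide] = []
        for cand in candidates:
            variants.extend(expand_modifications(cand, mod_config))
        variants.sort(key=lambda v: v.mass)
        self.variants = variants
        self._masses = np.array([v.mass for v in variants], dtype=np.float64)
        sequon_idx = [i for i, v in enumerate(variants) if v.candidate.has_sequon]
        self._sequon_positions = np.array(sequon_idx, dtype=np.int64)
        self._sequon_masses = self._masses[self._sequon_positions] if sequon_idx else np.empty(0)

    def __len__(self) -> int:
        return len(self.variants)

    def _window(self, masses: np.ndarray, target: float, tol_ppm: float) -> tuple[int, int]:
        tol = abs(target) * tol_ppm * 1e-6
        lo = int(np.searchsorted(masses, target - tol, side="left"))
        hi = int(np.searchsorted(masses, target + tol, side="right"))
        return lo, hi

    def lookup(
        self,
        precursor_mass: float,
        tol_ppm: float,
        isotope_errors: Iterable[int] = (0, 1, 2),
        glycan_masses: Sequence[float] | None = None,
    ) -> list[tuple[ModifiedPeptide, int, int | None]]:
        """Return (peptide, isotope_error, glycan_index|None) hits.

        glycan_index refers into the glycan_masses sequence passed in;
        None marks a non-glyco hit.
        """
        if tol_ppm <= 0:
            raise ValueError(f"tolerance must be positive, got {tol_ppm}")
        hits: list[tuple[ModifiedPeptide, int, int | None]] = []
        for iso in isotope_errors:
            base = precursor_mass - iso * ISOTOPE_SPACING
            lo, hi = self._window(self._masses, base, tol_ppm)
            hits.extend((self.variants[i], iso, None) for i in range(lo, hi))
            if glycan_masses is not None and len(self._sequon_masses):
                for gi, gmass in enumerate(glycan_masses):
                    target = base - gmass
                    if target <= 0:
                        continue
                    lo, hi = self._window(self._sequon_masses, target, tol_ppm)
                    hits.extend(
                        (self.variants[int(self._sequon_positions[i])], iso, gi)
                        for i in range(lo, hi)
                    )
        return hits


def build_peptide_index(candidates: Sequence[PeptideCandidate],
                        mod_config: ModConfig | None = None) -> PeptideIndex:
    return PeptideIndex(candidates, mod_config)


def write_fasta(entries: Sequence[ProteinEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            header = e.accession
            if e.species_tag:
                header += f" OS={e.species_tag}"
            fh.write(f">{header}\n")
            for i in range(0, len(e.sequence), 60):
                fh.write(e.sequence[i:i + 60] + "\n")
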