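"""Mass-offset glycopeptide search: theoretical b/y (+Y) fragments,
hyperscore, and best-PSM-per-spectrum selection.

Spectra passing the oxonium gate are searched against both the plain and
the glycan-offset candidate space; all others only against the plain
space. Scoring is identical for targets and decoys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import constants
from .constants import AA_RESIDUE_MASSES, ISOTOPE_SPACING, PROTON, WATER
from .glycodb import GlycanComposition, glycan_mass
from .sequence_space import ModifiedPeptide, PeptideIndex
from .spectra import DEFAULT_PANEL, OxoniumPanel, SpectrumRecord, oxonium_gate

HEXNAC = constants.MONOSACCHARIDE_MASSES["HexNAc"]
CORE_MASS = 2 * HEXNAC + 3 * constants.MONOSACCHARIDE_MASSES["Hex"]  # HexNAc2Hex3


@dataclass(frozen=True)
class SearchConfig:
    precursor_tol_ppm: float = 20.0
    fragment_tol_ppm: float = 15.0
    isotope_errors: tuple[int, ...] = (0, 1, 2)
    peptide_length_range: tuple[int, int] = (7, 25)
    oxonium_threshold: float = 0.10
    glyco_delta_cutoff: float = 145.0
    psm_fdr: float = 0.01
    peptide_fdr: float = 0.01
    protein_fdr: float = 0.01
    glycan_q_threshold: float = 0.05
    rank_threshold: float = 20.0
    max_fragment_charge: int = 2

    def __post_init__(self):
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        for frac in (self.oxonium_threshold, self.psm_fdr, self.peptide_fdr,
                     self.protein_fdr, self.glycan_q_threshold):
            if not (0 < frac < 1):
                raise ValueError(f"fractional threshold out of (0,1): {frac}")


GROUP_GLYCO = "glyco"
GROUP_NONGLYCO = "nonglyco"


@dataclass
class Psm:
    scan_id: str
    peptide: ModifiedPeptide
    precursor_mass: float
    isotope_error: int
    delta_mass: float              # precursor - peptide mass - isotope correction
    hyperscore: float
    group: str
    matched_b: int
    matched_y: int
    glycan: GlycanComposition | None = None
    posterior: float | None = None
    psm_q: float | None = None
    glycan_score: float | None = None
    glycan_q: float | None = None

    @property
    def is_decoy(self) -> bool:
        return self.peptide.is_decoy

    @property
    def n_sequons(self) -> int:
        return len(self.peptide.candidate.sequon_positions)

    @property
    def glyco_site(self) -> int | None:
        """First sequon position (0-based within peptide), glyco PSMs only."""
        if self.group != GROUP_GLYCO or self.n_sequons == 0:
            return None
        return self.peptide.candidate.sequon_positions[0]


def theoretical_fragments(
    peptide: ModifiedPeptide | str,
    glycan_mass_da: float | None = None,
    max_charge: int = 2,
) -> list[tuple[str, float]]:
    """(label, m/z) for b1..b(n-1), y1..y(n-1); plus a Y-ion ladder
    (Y0, Y1, Y2, Ycore) when a glycan mass is given.

    Backbone ions of glycopeptides are computed from the bare peptide
    (glycan loss dominates under HCD); Y ions retain the intact peptide.
    """
    if isinstance(peptide, str):
        seq = peptide
        mod_at: dict[int, float] = {}
        nterm_mod = 0.0
    else:
        seq = peptide.sequence
        mod_at = {m.position: m.mass_delta for m in peptide.mods if m.position >= 0}
        nterm_mod = sum(m.mass_delta for m in peptide.mods if m.position < 0)
    n = len(seq)
    residue = [AA_RESIDUE_MASSES[a] + mod_at.get(i, 0.0) for i, a in enumerate(seq)]
    prefix = np.cumsum(residue)
    total = prefix[-1] + nterm_mod

    out: list[tuple[str, float]] = []
    for z in range(1, max_charge + 1):
        for i in range(1, n):
            b_neutral = prefix[i - 1] + nterm_mod
            # y ions never carry the N-terminal mod
            y_neutral = total - nterm_mod - prefix[i - 1] + WATER
            out.append((f"b{i}^{z}", (b_neutral + z * PROTON) / z))
            out.append((f"y{n - i}^{z}", (y_neutral + z * PROTON) / z))
    if glycan_mass_da is not None:
        pep_neutral = total + WATER
        y_ladder = [
            ("Y0", pep_neutral),
            ("Y1", pep_neutral + HEXNAC),
            ("Y2", pep_neutral + 2 * HEXNAC),
            ("Yc", pep_neutral + CORE_MASS),
        ]
        for z in range(1, max_charge + 1):
            for label, neutral in y_ladder:
                out.append((f"{label}^{z}", (neutral + z * PROTON) / z))
    return out


def _match_fragments(
    spectrum: SpectrumRecord,
    fragments: Sequence[tuple[str, float]],
    frag_tol_ppm: float,
) -> list[tuple[str, float]]:
    """(label, matched intensity) for fragments with a peak in tolerance.

    Each theoretical ion takes at most one peak (the most intense in
    tolerance); a peak may satisfy several theoretical ions.
    """
    mz = spectrum.peaks_mz
    inten = spectrum.peaks_intensity
    frag_mz = np.array([f for _, f in fragments])
    tol = frag_mz * frag_tol_ppm * 1e-6
    lo = np.searchsorted(mz, frag_mz - tol, side="left")
    hi = np.searchsorted(mz, frag_mz + tol, side="right")
    matches = []
    for k in np.flatnonzero(hi > lo):
        matches.append((fragments[k][0], float(inten[lo[k]:hi[k]].max())))
    return matches


def hyperscore(spectrum: SpectrumRecord, fragments: Sequence[tuple[str, float]],
               frag_tol_ppm: float = 15.0) -> tuple[float, int, int]:
    """MSFragger-style hyperscore; returns (score, n_b_matched, n_y_matched).

    score = ln(Nb!) + ln(Ny!) + ln(max(1, sum I_b)) + ln(max(1, sum I_y)).
    Y/oxonium-type matches are pooled into the y term.
    """
    if not fragments:
        raise ValueError("no theoretical fragments supplied")
    matches = _match_fragments(spectrum, fragments, frag_tol_ppm)
    if not matches:
        return 0.0, 0, 0
    nb = ny = 0
    sib = siy = 0.0
    for label, intensity in matches:
        if label.startswith("b"):
            nb += 1
            sib += intensity
        else:
            ny += 1
            siy += intensity
    score = (math.lgamma(nb + 1) + math.lgamma(ny + 1)
             + math.log(max(1.0, sib)) + math.log(max(1.0, siy)))
    return score, nb, ny


def search_spectrum(
    spectrum: SpectrumRecord,
    index: PeptideIndex,
    glycan_db: Sequence[GlycanComposition] | None,
    config: SearchConfig = SearchConfig(),
    panel: OxoniumPanel = DEFAULT_PANEL,
    gate_result: tuple[bool, float] | None = None,
) -> Psm | None:
    """Best PSM for one spectrum, or None if no candidate matches.

    Glyco candidates are considered only when the oxonium gate passes.
    Ties on hyperscore break by smaller |delta mass|, then lexicographic
    peptide sequence, for determinism.
    """
    if gate_result is None:
        gate_result = oxonium_gate(spectrum, panel, config.fragment_tol_ppm,
                                   config.oxonium_threshold)
    gate_pass, _ = gate_result
    glycan_masses = None
    if gate_pass and glycan_db:
        glycan_masses = [glycan_mass(g) for g in glycan_db]
    hits = index.lookup(spectrum.precursor_mass, config.precursor_tol_ppm,
                        config.isotope_errors, glycan_masses)
    # fragments depend on the peptide, not the glycan identity, so score
    # once per (peptide, glyco-branch) and pick the best-fitting mass
    # interpretation among its (isotope, glycan) alternatives afterwards
    grouped: dict[tuple[int, bool], tuple[ModifiedPeptide, list]] = {}
    for peptide, iso, glycan_idx in hits:
        key = (id(peptide), glycan_idx is not None)
        grouped.setdefault(key, (peptide, []))[1].append((iso, glycan_idx))
    best: Psm | None = None
    best_key: tuple | None = None
    for (_, is_glyco), (peptide, occs) in grouped.items():
        frags = theoretical_fragments(peptide, CORE_MASS if is_glyco else None,
                                      config.max_fragment_charge)
        score, nb, ny = hyperscore(spectrum, frags, config.fragment_tol_ppm)

        def mass_err(occ):
            iso, gi = occ
            delta = spectrum.precursor_mass - peptide.mass - iso * ISOTOPE_SPACING
            return abs(delta - glycan_masses[gi]) if gi is not None else abs(delta)

        iso, glycan_idx = min(occs, key=lambda occ: (mass_err(occ), occ[0]))
        delta = spectrum.precursor_mass - peptide.mass - iso * ISOTOPE_SPACING
        key = (-score, mass_err((iso, glycan_idx)), peptide.sequence,
               peptide.mod_string(), peptide.is_decoy)
        if best_key is None or key < best_key:
            best_key = key
            glycan = glycan_db[glycan_idx] if glycan_idx is not None else None
            group = GROUP_GLYCO if delta >= config.glyco_delta_cutoff else GROUP_NONGLYCO
            best = Psm(
                scan_id=spectrum.scan_id,
                peptide=peptide,
                precursor_mass=spectrum.precursor_mass,
                isotope_error=iso,
                delta_mass=delta,
                hyperscore=score,
                group=group,
                matched_b=nb,
                matched_y=ny,
                glycan=glycan,
            )
    return best


def search_spectra(
    spectra,
    index: PeptideIndex,
    glycan_db: Sequence[GlycanComposition] | None,
    config: SearchConfig = SearchConfig(),
    panel: OxoniumPanel = DEFAULT_PANEL,
) -> list[Psm]:
    """Rank-1 PSMs for a stream of spectra (spectra with no candidate are
    dropped)."""
    psms = []
    for spectrum in spectra:
        psm = search_spectrum(spectrum, index, glycan_db, config, panel)
        if psm is not None:
            psms.append(psm)
    return psms


def psms_to_frame(psms: Sequence[Psm]):
    """Tabular PSM export (one row per PSM)."""
    import pandas as pd

    columns = ["scan", "peptide", "mods", "proteins", "is_decoy",
               "precursor_mass", "isotope_error", "delta_mass", "hyperscore",
               "group", "n_sequons", "matched_b", "matched_y", "glycan",
               "glycan_score", "glycan_q", "psm_q"]
    if not psms:
        return pd.DataFrame(columns=columns)
    rows = []
    for p in psms:
        rows.append({
            "scan": p.scan_id,
            "peptide": p.peptide.sequence,
            "mods": p.peptide.mod_string(),
            "proteins": ";".join(sorted({acc for acc, _, _ in p.peptide.candidate.protein_refs})),
            "is_decoy": p.is_decoy,
            "precursor_mass": round(p.precursor_mass, 5),
            "isotope_error": p.isotope_error,
            "delta_mass": round(p.delta_mass, 5),
            "hyperscore": round(p.hyperscore, 5),
            "group": p.group,
            "n_sequons": p.n_sequons,
            "matched_b": p.matched_b,
            "matched_y": p.matched_y,
            "glycan": str(p.glycan) if p.glycan is not None else "",
            "glycan_score": p.glycan_score if p.glycan_score is not None else "",
            "glycan_q": p.glycan_q if p.glycan_q is not None else "",
            "psm_q": p.psm_q if p.psm_q is not None else "",
        })
    return pd.DataFrame(rows)
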