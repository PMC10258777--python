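"""Glycan composition assignment with decoy-glycan q-values.

Each glyco PSM's delta mass is matched against target compositions and
against decoy compositions (same composition, mass shifted by a random
0.5-2.5 Da offset, fixed seed). Candidates are scored on composition-
dependent diagnostic ions plus a mass-error penalty; the per-PSM best
target competes against the best decoy, and q-values over the winners
estimate the assignment FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import constants
from .constants import ISOTOPE_SPACING, PROTON
from .fdr import tdc_qvalues
from .glycodb import GlycanComposition, format_glycan
from .search import CORE_MASS, HEXNAC, Psm
from .sequence_space import ModifiedPeptide
from .spectra import SpectrumRecord

FUC = constants.MONOSACCHARIDE_MASSES["Fuc"]

# oxonium m/z by diagnostic role
_HEXNAC_OXONIUM = (126.0550, 138.0550, 168.0655, 186.0761, 204.0867)
_HEX_OXONIUM = (163.0601,)
_HEXNAC_HEX_OXONIUM = (366.1395,)
_NEUAC_OXONIUM = (274.0921, 292.1027)


@dataclass(frozen=True)
class GlycanScoreConfig:
    w_hit: float = 1.0
    w_miss: float = 0.5
    lambda_ppm: float = 0.02
    frag_tol_ppm: float = 15.0
    max_charge: int = 2


@dataclass(frozen=True)
class GlycanRecord:
    """A (possibly decoy) entry of the assignment database."""

    composition: GlycanComposition
    mass: float
    is_decoy: bool = False


def build_assignment_db(
    compositions: Sequence[GlycanComposition],
    seed: int = 0,
    shift_range: tuple[float, float] = (0.5, 2.5),
) -> list[GlycanRecord]:
    """Targets plus one mass-shifted decoy per target composition.

    Decoy shift = sign * Uniform(shift_range) Da, reproducible from seed.
    """
    rng = np.random.default_rng(seed)
    records = [GlycanRecord(c, c.mass, False) for c in compositions]
    for c in compositions:
        shift = rng.uniform(*shift_range) * rng.choice([-1.0, 1.0])
        records.append(GlycanRecord(c, c.mass + shift, True))
    return records


def candidate_glycans(
    delta_mass: float,
    db: Sequence[GlycanRecord] | Sequence[GlycanComposition],
    tol_ppm: float = 20.0,
    isotope_errors: Sequence[int] = (0, 1, 2),
) -> list[tuple[GlycanRecord, int]]:
    """(record, isotope_error) pairs whose mass matches the delta mass."""
    if not db:
        raise ValueError("empty glycan database")
    records = [r if isinstance(r, GlycanRecord) else GlycanRecord(r, r.mass, False)
               for r in db]
    hits = []
    for rec in records:
        tol = rec.mass * tol_ppm * 1e-6
        for iso in isotope_errors:
            if abs(delta_mass - iso * ISOTOPE_SPACING - rec.mass) <= tol:
                hits.append((rec, iso))
                break
    return hits


def expected_diagnostic_ions(
    comp: GlycanComposition,
    peptide_mass: float,
    max_charge: int = 2,
) -> list[tuple[str, float]]:
    """Composition-dependent oxonium ions plus the Y-ion ladder.

    NeuAc oxonium ions are expected only for sialylated compositions, the
    fucose diagnostic (Y1+Fuc) only when Fuc > 0, and Y ions only as far
    as the composition reaches.
    """
    ox: list[tuple[str, float]] = []
    hexnac = comp.get("HexNAc")
    hexose = comp.get("Hex")
    if hexnac > 0:
        ox.extend((f"ox{mz:.0f}", mz) for mz in _HEXNAC_OXONIUM)
    if hexose > 0:
        ox.extend((f"ox{mz:.0f}", mz) for mz in _HEX_OXONIUM)
    if hexnac > 0 and hexose > 0:
        ox.extend((f"ox{mz:.0f}", mz) for mz in _HEXNAC_HEX_OXONIUM)
    if comp.get("NeuAc") > 0:
        ox.extend((f"ox{mz:.0f}", mz) for mz in _NEUAC_OXONIUM)

    y_neutrals: list[tuple[str, float]] = [("Y0", peptide_mass)]
    if hexnac >= 1:
        y_neutrals.append(("Y1", peptide_mass + HEXNAC))
    if hexnac >= 2:
        y_neutrals.append(("Y2", peptide_mass + 2 * HEXNAC))
    if hexnac >= 2 and hexose >= 3:
        y_neutrals.append(("Yc", peptide_mass + CORE_MASS))
    if comp.get("Fuc") > 0 and hexnac >= 1:
        y_neutrals.append(("Y1F", peptide_mass + HEXNAC + FUC))
    ions = list(ox)
    for z in range(1, max_charge + 1):
        ions.extend((f"{label}^{z}", (neutral + z * PROTON) / z)
                    for label, neutral in y_neutrals)
    return ions


def score_glycan(
    spectrum: SpectrumRecord,
    peptide: ModifiedPeptide | float,
    comp: GlycanComposition,
    observed_glycan_mass: float,
    record_mass: float | None = None,
    config: GlycanScoreConfig = GlycanScoreConfig(),
) -> float:
    """Hit/miss diagnostic-ion score minus a ppm mass-error penalty.

    peptide may be a ModifiedPeptide or a bare neutral peptide mass.
    record_mass defaults to the composition mass (pass the shifted mass
    for decoy records so target and decoy are scored identically).
    """
    pep_mass = peptide if isinstance(peptide, (int, float)) else peptide.mass
    if record_mass is None:
        record_mass = comp.mass
    ions = expected_diagnostic_ions(comp, pep_mass, config.max_charge)
    mz = spectrum.peaks_mz
    score = 0.0
    for _, ion_mz in ions:
        tol = ion_mz * config.frag_tol_ppm * 1e-6
        lo = int(np.searchsorted(mz, ion_mz - tol, side="left"))
        hi = int(np.searchsorted(mz, ion_mz + tol, side="right"))
        score += config.w_hit if hi > lo else -config.w_miss
    ppm_err = abs(observed_glycan_mass - record_mass) / record_mass * 1e6
    return score - config.lambda_ppm * ppm_err


@dataclass
class GlycanAssignment:
    psm_index: int
    composition: GlycanComposition | None
    glycan_score: float
    best_decoy_score: float
    is_decoy_glycan_best: bool
    glycan_q: float | None = None


def glycan_qvalues(assignments: Sequence[GlycanAssignment]) -> np.ndarray:
    """q per assignment via competition-winner target-decoy counting.

    Decoy-winning PSMs receive q = 1 regardless of their tdc position.
    """
    if not assignments:
        return np.empty(0)
    scores = np.array([max(a.glycan_score, a.best_decoy_score) for a in assignments])
    decoy_won = np.array([a.is_decoy_glycan_best for a in assignments])
    if (~decoy_won).sum() == 0:
        q = np.ones(len(assignments))
    else:
        q = tdc_qvalues(scores, decoy_won)
        q[decoy_won] = 1.0
    for a, qi in zip(assignments, q):
        a.glycan_q = float(qi)
    return q


def _compete_assignments(
    items: Sequence[tuple[int, str, float, float]],
    spectra: Mapping[str, SpectrumRecord],
    records: Sequence[GlycanRecord],
    tol_ppm: float,
    isotope_errors: Sequence[int],
    score_config: GlycanScoreConfig,
) -> tuple[list[GlycanAssignment], int]:
    """Score target vs decoy glycans per item = (id, scan, pep_mass, delta).

    Returns (assignments with q filled, n unassigned)."""
    assignments: list[GlycanAssignment] = []
    unassigned = 0
    for i, scan_id, pep_mass, observed in items:
        spectrum = spectra[scan_id]
        hits = candidate_glycans(observed, records, tol_ppm, isotope_errors)
        best_t: tuple[float, str, GlycanComposition] | None = None
        best_d = -np.inf
        for rec, iso in hits:
            corrected = observed - iso * ISOTOPE_SPACING
            s = score_glycan(spectrum, pep_mass, rec.composition, corrected,
                            rec.mass, score_config)
            if rec.is_decoy:
                best_d = max(best_d, s)
            else:
                key = (-s, format_glycan(rec.composition))
                if best_t is None or key < (-best_t[0], best_t[1]):
                    best_t = (s, format_glycan(rec.composition), rec.composition)
        if best_t is None and best_d == -np.inf:
            unassigned += 1
            continue
        t_score = best_t[0] if best_t is not None else -np.inf
        decoy_wins = best_d >= t_score  # conservative tie to decoy
        assignments.append(GlycanAssignment(
            psm_index=i,
            composition=None if decoy_wins or best_t is None else best_t[2],
            glycan_score=t_score,
            best_decoy_score=best_d,
            is_decoy_glycan_best=bool(decoy_wins),
        ))
    glycan_qvalues(assignments)
    return assignments, unassigned


def assign_glycans(
    psms: Sequence[Psm],
    spectra: Mapping[str, SpectrumRecord],
    db: Sequence[GlycanComposition],
    q_threshold: float = 0.05,
    tol_ppm: float = 20.0,
    isotope_errors: Sequence[int] = (0, 1, 2),
    seed: int = 0,
    score_config: GlycanScoreConfig = GlycanScoreConfig(),
) -> tuple[list[Psm], dict[str, int]]:
    """Annotate glyco-group PSMs with compositions and q-values; drop those
    failing the q threshold (they are removed, not relabeled non-glyco).

    Returns (retained glyco PSMs, summary counts). Missing spectra raise.
    """
    glyco = [(i, p) for i, p in enumerate(psms) if p.group == "glyco"]
    missing = [p.scan_id for _, p in glyco if p.scan_id not in spectra]
    if missing:
        raise ValueError(f"spectra missing for scans: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    records = build_assignment_db(db, seed=seed)
    items = [(i, p.scan_id, p.peptide.mass, p.delta_mass) for i, p in glyco]
    assignments, unassigned = _compete_assignments(
        items, spectra, records, tol_ppm, isotope_errors, score_config)
    retained: list[Psm] = []
    for a in assignments:
        psm = psms[a.psm_index]
        psm.glycan_score = a.glycan_score if np.isfinite(a.glycan_score) else None
        psm.glycan_q = a.glycan_q
        if not a.is_decoy_glycan_best and a.glycan_q is not None \
                and a.glycan_q <= q_threshold:
            psm.glycan = a.composition
            retained.append(psm)
    summary = {
        "glyco_psms": len(glyco),
        "unassigned": unassigned,
        "decoy_won": sum(a.is_decoy_glycan_best for a in assignments),
        "retained": len(retained),
    }
    return retained, summary


_MOD_MASSES = {
    "Acetyl": constants.MOD_NTERM_ACETYL,
    "Oxidation": constants.MOD_MET_OXIDATION,
    "Cysteinylation": constants.MOD_CYS_CYSTEINYLATION,
}


def _mass_from_row(sequence: str, mods: str) -> float:
    mass = constants.peptide_mass(sequence)
    if isinstance(mods, str) and mods:
        for token in mods.split(";"):
            _, name = token.split(":")
            mass += _MOD_MASSES[name]
    return mass


def assign_glycans_frame(
    psms,
    spectra: Mapping[str, SpectrumRecord],
    db: Sequence[GlycanComposition],
    q_threshold: float = 0.05,
    tol_ppm: float = 20.0,
    isotope_errors: Sequence[int] = (0, 1, 2),
    seed: int = 0,
    score_config: GlycanScoreConfig = GlycanScoreConfig(),
):
    """Table-level variant of :func:`assign_glycans` for the CLI.

    Expects columns scan, peptide, mods, delta_mass, group; returns the
    frame with glycan/glycan_score/glycan_q columns and failing glyco rows
    dropped, plus the summary dict."""
    import pandas as pd

    df = psms.copy()
    glyco = df[df["group"] == "glyco"]
    missing = [s for s in glyco["scan"] if s not in spectra]
    if missing:
        raise ValueError(f"spectra missing for scans: {missing[:10]}")
    records = build_assignment_db(db, seed=seed)
    items = [(idx, row.scan, _mass_from_row(row.peptide, row.mods), row.delta_mass)
             for idx, row in zip(glyco.index, glyco.itertuples())]
    assignments, unassigned = _compete_assignments(
        items, spectra, records, tol_ppm, isotope_errors, score_config)
    df["glycan"] = ""
    df["glycan_score"] = np.nan
    df["glycan_q"] = np.nan
    drop = set(glyco.index)
    for a in assignments:
        df.loc[a.psm_index, "glycan_score"] = a.glycan_score
        df.loc[a.psm_index, "glycan_q"] = a.glycan_q
        if not a.is_decoy_glycan_best and a.glycan_q <= q_threshold:
            df.loc[a.psm_index, "glycan"] = format_glycan(a.composition)
            drop.discard(a.psm_index)
    summary = {
        "glyco_psms": len(glyco),
        "unassigned": unassigned,
        "decoy_won": sum(a.is_decoy_glycan_best for a in assignments),
        "retained": len(glyco) - len(drop),
    }
    return df.drop(index=drop), summary
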