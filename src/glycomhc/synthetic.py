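"""Ground-truth generators: proteomes with planted sequons, spectra with
b/y (+Y, oxonium) peaks, scored PSM populations with a search-space
asymmetry, and percentile-rank tables with planted binding motifs.

Everything is a pure function of (config, seed) and every generator emits
a truth table whose join keys match the corresponding output table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import constants
from .constants import AMINO_ACIDS, ISOTOPE_SPACING, PROTON, peptide_mass
from .glycodb import GlycanComposition
from .hla_deconv import CORE_LENGTH
from .search import theoretical_fragments
from .sequence_space import ProteinEntry, find_sequons
from .spectra import SpectrumRecord

ENTRAPMENT_TAG = "entrapment"

_NOT_P = AMINO_ACIDS.replace("P", "")


def generate_proteome(
    n_proteins: int = 50,
    length: int = 120,
    sequon_density: float = 0.02,
    entrapment_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[ProteinEntry], pd.DataFrame]:
    """Random proteins (uniform residues) with sequons planted at the given
    per-residue density; a fraction are tagged as entrapment species.

    Returns (entries, truth) where truth lists planted sequon positions.
    """
    if not 0 <= sequon_density <= 0.2:
        raise ValueError("sequon density must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    not_p = np.array(list(_NOT_P))
    n_entrap = int(round(n_proteins * entrapment_fraction))
    entries = []
    truth_rows = []
    for i in range(n_proteins):
        seq = rng.choice(aa, size=length)
        n_plant = rng.binomial(length, sequon_density)
        planted = []
        positions = rng.permutation(length - 3)
        for pos in positions:
            if len(planted) >= n_plant:
                break
            if any(abs(pos - q) < 3 for q in planted):
                continue
            seq[pos] = "N"
            seq[pos + 1] = rng.choice(not_p)
            seq[pos + 2] = rng.choice(["S", "T"])
            planted.append(int(pos))
        is_entrap = i < n_entrap
        acc = f"{'ent' if is_entrap else 'syn'}|P{i:05d}"
        entries.append(ProteinEntry(
            acc, "".join(seq), is_decoy=False,
            species_tag=ENTRAPMENT_TAG if is_entrap else "synthetic"))
        truth_rows.append({"accession": acc, "planted_sequons": sorted(planted),
                           "is_entrapment": is_entrap})
    return entries, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class SpectrumSpec:
    """One spectrum to generate: a peptide, optional glycan, charge."""

    sequence: str
    glycan: GlycanComposition | None = None
    charge: int = 2
    isotope_error: int = 0


@dataclass(frozen=True)
class IntensityModel:
    log_mean: float = float(np.log(1000.0))
    log_sigma: float = 1.0


# oxonium ions injected into glyco spectra (matches the diagnostic panel)
_OXONIUM_FOR_GLYCO = {
    "HexNAc": (126.0550, 138.0550, 168.0655, 186.0761, 204.0867),
    "Hex": (163.0601,),
    "HexNAc+Hex": (366.1395,),
    "NeuAc": (274.0921, 292.1027),
}


def generate_spectra(
    specs: Sequence[SpectrumSpec],
    noise_peaks: int = 0,
    intensity_model: IntensityModel = IntensityModel(),
    seed: int = 0,
    gate_pass: bool = True,
    fragment_charges: int = 2,
) -> tuple[list[SpectrumRecord], pd.DataFrame]:
    """Spectra containing the theoretical b/y (+Y, +oxonium) peaks of each
    spec, log-normal intensities, plus uniform-m/z noise peaks.

    When gate_pass is True the oxonium peaks of glyco spectra are scaled so
    their summed intensity reaches at least 10% of the base peak.
    """
    from .glycan_assign import expected_diagnostic_ions

    rng = np.random.default_rng(seed)
    spectra = []
    truth_rows = []
    for idx, spec in enumerate(specs):
        pep_mass = peptide_mass(spec.sequence)
        gmass = spec.glycan.mass if spec.glycan is not None else None
        frags = theoretical_fragments(spec.sequence, None, fragment_charges)
        mzs = [mz for _, mz in frags]
        intens = list(rng.lognormal(intensity_model.log_mean,
                                    intensity_model.log_sigma, size=len(mzs)))
        if spec.glycan is not None:
            # the same composition-dependent diagnostic ions the assignment
            # stage models: oxonium subset + Y ladder (+Fuc diagnostic)
            diag = expected_diagnostic_ions(spec.glycan, pep_mass,
                                            fragment_charges)
            y_mzs = [mz for label, mz in diag if not label.startswith("ox")]
            y_int = list(rng.lognormal(intensity_model.log_mean,
                                       intensity_model.log_sigma, size=len(y_mzs)))
            mzs.extend(y_mzs)
            intens.extend(y_int)
            ox = sorted({mz for label, mz in diag if label.startswith("ox")})
            if not ox:  # e.g. Fuc-only compositions: generic HexNAc ion
                ox = list(_OXONIUM_FOR_GLYCO["HexNAc"])
            ox_int = list(rng.lognormal(intensity_model.log_mean,
                                        intensity_model.log_sigma, size=len(ox)))
            if gate_pass:
                base = max(intens + ox_int)
                need = 0.12 * base  # slack above the 10% gate
                if sum(ox_int) < need:
                    scale = need / sum(ox_int)
                    ox_int = [x * scale for x in ox_int]
            mzs.extend(ox)
            intens.extend(ox_int)
        if noise_peaks:
            lo, hi = 100.0, max(mzs) * 1.1
            noise_mz = rng.uniform(lo, hi, size=noise_peaks)
            noise_int = rng.lognormal(intensity_model.log_mean - 1.5,
                                      intensity_model.log_sigma, size=noise_peaks)
            mzs.extend(noise_mz)
            intens.extend(noise_int)
        neutral = pep_mass + (gmass or 0.0) + spec.isotope_error * ISOTOPE_SPACING
        scan = f"syn_scan_{idx:06d}"
        spectra.append(SpectrumRecord(
            scan_id=scan,
            precursor_mz=(neutral + spec.charge * PROTON) / spec.charge,
            charge=spec.charge,
            peaks_mz=np.array(mzs),
            peaks_intensity=np.array(intens),
        ))
        truth_rows.append({
            "scan": scan,
            "peptide": spec.sequence,
            "glycan": str(spec.glycan) if spec.glycan is not None else "",
            "glycan_mass": gmass if gmass is not None else 0.0,
            "charge": spec.charge,
            "isotope_error": spec.isotope_error,
        })
    return spectra, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class ScoreParams:
    mu_correct: float = 10.0
    sigma_correct: float = 1.0
    mu_incorrect: float = 5.0
    sigma_incorrect: float = 1.0
    base_incorrect_rate: float = 0.02


def generate_psm_population(
    n: int = 100_000,
    glyco_fraction: float = 0.03,
    space_asymmetry: float = 30.0,
    score_params: ScoreParams = ScoreParams(),
    seed: int = 0,
    glyco_delta_cutoff: float = 145.0,
) -> pd.DataFrame:
    """Scored PSM population with known correct/incorrect labels.

    Each spectrum yields one best match: correct (target, N(mu1, s1)) with
    probability 1-r, otherwise a false match - target or decoy with equal
    probability - scored N(mu0, s0). The glyco group's false-match rate r
    is the base rate multiplied by the search-space asymmetry, which is
    what makes pooled filtering unsafe for the small glyco group.
    """
    if n < 1000:
        raise ValueError("population size must be >= 1000")
    if score_params.mu_correct <= score_params.mu_incorrect:
        raise ValueError("mu_correct must exceed mu_incorrect (unidentifiable)")
    rng = np.random.default_rng(seed)
    n_glyco = int(round(n * glyco_fraction))
    is_glyco = np.zeros(n, dtype=bool)
    is_glyco[rng.choice(n, size=n_glyco, replace=False)] = True
    r_non = min(0.95, score_params.base_incorrect_rate)
    r_gly = min(0.95, score_params.base_incorrect_rate * space_asymmetry)
    r = np.where(is_glyco, r_gly, r_non)
    u = rng.random(n)
    is_correct = u >= r
    is_decoy = (~is_correct) & (rng.random(n) < 0.5)
    scores = np.where(
        is_correct,
        rng.normal(score_params.mu_correct, score_params.sigma_correct, n),
        rng.normal(score_params.mu_incorrect, score_params.sigma_incorrect, n),
    )
    delta = np.where(
        is_glyco,
        rng.uniform(203.0, 2400.0, n),
        rng.normal(0.0, 0.002, n),
    )
    return pd.DataFrame({
        "psm_id": np.arange(n),
        "hyperscore": scores,
        "delta_mass": delta,
        "is_decoy": is_decoy,
        "is_correct": is_correct & ~is_decoy,
        "is_glyco_truth": is_glyco,
    })


def make_motif_pwm(rng: np.random.Generator, anchor_weight: float = 0.8,
                   n_anchors: int = 4) -> np.ndarray:
    """A sharp 9x20 PWM with a few high-information anchor positions."""
    pwm = rng.dirichlet(np.full(20, 2.0), size=CORE_LENGTH)
    anchors = rng.choice(CORE_LENGTH, size=n_anchors, replace=False)
    for pos in anchors:
        res = rng.integers(20)
        pwm[pos] = (1 - anchor_weight) * pwm[pos]
        pwm[pos, res] += anchor_weight
    return pwm / pwm.sum(axis=1, keepdims=True)


def generate_motif_peptides(
    alleles_with_motifs: Mapping[str, np.ndarray],
    n_per_allele: int = 100,
    n_trash: int = 50,
    length_range: tuple[int, int] = (13, 21),
    seed: int = 0,
) -> pd.DataFrame:
    """Peptides embedding a 9-mer core sampled from each allele's PWM at a
    random offset, plus motif-free trash peptides.

    Truth columns: peptide, true_allele ('' for trash), core_offset."""
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    rows = []
    seen: set[str] = set()
    for allele, pwm in alleles_with_motifs.items():
        made = 0
        while made < n_per_allele:
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            pep = rng.choice(aa, size=length)
            offset = int(rng.integers(0, length - CORE_LENGTH + 1))
            for j in range(CORE_LENGTH):
                pep[offset + j] = aa[rng.choice(20, p=pwm[j])]
            pep_s = "".join(pep)
            if pep_s in seen:
                continue
            seen.add(pep_s)
            rows.append({"peptide": pep_s, "true_allele": allele,
                         "core_offset": offset})
            made += 1
    made = 0
    while made < n_trash:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        pep_s = "".join(rng.choice(aa, size=length))
        if pep_s in seen:
            continue
        seen.add(pep_s)
        rows.append({"peptide": pep_s, "true_allele": "", "core_offset": -1})
        made += 1
    return pd.DataFrame(rows)


def generate_rank_table(
    peptide_truth: pd.DataFrame,
    alleles: Sequence[str],
    seed: int = 0,
    rank_threshold: float = 20.0,
) -> pd.DataFrame:
    """Percentile ranks consistent with planted motifs.

    The planted allele gets a low Beta-shaped rank in [0, threshold); all
    other alleles (and every allele of trash peptides) get ranks well
    above the threshold.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for row in peptide_truth.itertuples():
        for allele in alleles:
            if row.true_allele == allele:
                rank = float(rank_threshold * rng.beta(1.0, 9.0))
                offset = int(row.core_offset)
            else:
                rank = float(rng.uniform(rank_threshold + 5.0, 95.0))
                offset = -1
            rows.append({"peptide": row.peptide, "allele": allele,
                         "rank": round(rank, 4),
                         "core_offset": offset if offset >= 0 else np.nan})
    return pd.DataFrame(rows)
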