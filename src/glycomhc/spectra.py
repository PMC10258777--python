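"""Spectrum I/O (MGF) and oxonium-ion triage.

Input spectra are assumed centroided and deisotoped. The oxonium gate
decides which spectra are eligible for the glyco search branch: a spectrum
passes when peaks matching the diagnostic panel sum to at least a fraction
(default 10%) of the base-peak intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .constants import mass_from_mz

logger = logging.getLogger(__name__)


@dataclass
class SpectrumRecord:
    scan_id: str
    precursor_mz: float
    charge: int
    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray
    retention_time: float | None = None
    charge_imputed: bool = False

    def __post_init__(self):
        order = np.argsort(self.peaks_mz, kind="stable")
        self.peaks_mz = np.asarray(self.peaks_mz, dtype=np.float64)[order]
        self.peaks_intensity = np.asarray(self.peaks_intensity, dtype=np.float64)[order]
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1 ({self.scan_id})")
        if np.any(self.peaks_intensity < 0):
            raise ValueError(f"negative intensity in {self.scan_id}")

    @property
    def precursor_mass(self) -> float:
        return mass_from_mz(self.precursor_mz, self.charge)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.peaks_intensity.max()) if len(self.peaks_intensity) else 0.0

    @property
    def n_peaks(self) -> int:
        return len(self.peaks_mz)


# Diagnostic low-mass glycan fragments. Editable; see also oxonium TSV I/O.
DEFAULT_OXONIUM_PANEL: tuple[tuple[str, float], ...] = (
    ("HexNAc-C2H6O3", 126.0550),
    ("HexNAc-2H2O-CH2O", 138.0550),
    ("HexNAc-2H2O", 168.0655),
    ("HexNAc-H2O", 186.0761),
    ("HexNAc", 204.0867),
    ("Hex", 163.0601),
    ("HexHexNAc", 366.1395),
    ("NeuAc-H2O", 274.0921),
    ("NeuAc", 292.1027),
)


@dataclass(frozen=True)
class OxoniumPanel:
    ions: tuple[tuple[str, float], ...] = DEFAULT_OXONIUM_PANEL

    def __post_init__(self):
        mzs = [mz for _, mz in self.ions]
        if len(set(mzs)) != len(mzs):
            raise ValueError("duplicate m/z in oxonium panel")
        if any(mz <= 0 for mz in mzs):
            raise ValueError("non-positive m/z in oxonium panel")

    @property
    def mz_values(self) -> np.ndarray:
        return np.array([mz for _, mz in self.ions], dtype=np.float64)


DEFAULT_PANEL = OxoniumPanel()


def oxonium_gate(
    spectrum: SpectrumRecord,
    panel: OxoniumPanel = DEFAULT_PANEL,
    frag_tol_ppm: float = 15.0,
    threshold_fraction: float = 0.10,
) -> tuple[bool, float]:
    """(pass, fraction) where fraction = summed matched oxonium intensity
    over base-peak intensity.

    Each panel ion contributes at most one peak: the most intense peak
    within tolerance (avoids double counting near-isobaric noise).
    """
    if spectrum.n_peaks == 0:
        raise ValueError(f"empty spectrum {spectrum.scan_id}")
    base = spectrum.base_peak_intensity
    if base <= 0:
        return False, 0.0
    matched = 0.0
    mz = spectrum.peaks_mz
    inten = spectrum.peaks_intensity
    for _, ion_mz in panel.ions:
        tol = ion_mz * frag_tol_ppm * 1e-6
        lo = int(np.searchsorted(mz, ion_mz - tol, side="left"))
        hi = int(np.searchsorted(mz, ion_mz + tol, side="right"))
        if hi > lo:
            matched += float(inten[lo:hi].max())
    fraction = matched / base
    return fraction >= threshold_fraction, fraction


def read_mgf(path: str | Path, default_charge: int = 2) -> Iterator[SpectrumRecord]:
    """Lazily parse an MGF file (BEGIN/END IONS, PEPMASS, CHARGE dialect).

    Records without a precursor are skipped with a warning; records without
    a charge get ``default_charge`` and are flagged as imputed.
    """
    scan_counter = 0
    with open(path) as fh:
        in_block = False
        title = None
        pepmass = None
        charge = None
        rtime = None
        mzs: list[float] = []
        intens: list[float] = []
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line == "BEGIN IONS":
                in_block = True
                title = pepmass = charge = rtime = None
                mzs, intens = [], []
            elif line == "END IONS":
                scan_counter += 1
                scan_id = title if title else f"scan_{scan_counter}"
                if pepmass is None:
                    logger.warning("skipping spectrum %s: missing PEPMASS", scan_id)
                else:
                    imputed = charge is None
                    yield SpectrumRecord(
                        scan_id=scan_id,
                        precursor_mz=pepmass,
                        charge=charge if charge is not None else default_charge,
                        peaks_mz=np.array(mzs),
                        peaks_intensity=np.array(intens),
                        retention_time=rtime,
                        charge_imputed=imputed,
                    )
                in_block = False
            elif in_block:
                if line.startswith("TITLE="):
                    title = line[6:]
                elif line.startswith("PEPMASS="):
                    pepmass = float(line[8:].split()[0])
                elif line.startswith("CHARGE="):
                    charge = int(line[7:].rstrip("+-"))
                elif line.startswith("RTINSECONDS="):
                    rtime = float(line[12:])
                elif line[0].isdigit() or line[0] in ".-":
                    parts = line.split()
                    mzs.append(float(parts[0]))
                    intens.append(float(parts[1]) if len(parts) > 1 else 1.0)


def read_spectra(path: str | Path, fmt: str | None = None,
                 default_charge: int = 2) -> Iterator[SpectrumRecord]:
    """Dispatch on format (MGF supported; mzML not available offline)."""
    if fmt is None:
        fmt = "mgf" if str(path).lower().endswith(".mgf") else "mzml"
    fmt = fmt.lower()
    if fmt == "mgf":
        yield from read_mgf(path, default_charge=default_charge)
    else:
        raise NotImplementedError(
            "mzML support requires an external reader not bundled here; "
            "convert to MGF"
        )


def write_mgf(spectra: Sequence[SpectrumRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.scan_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.charge}+\n")
            if s.retention_time is not None:
                fh.write(f"RTINSECONDS={s.retention_time:.2f}\n")
            for mz, inten in zip(s.peaks_mz, s.peaks_intensity):
                fh.write(f"{mz:.5f} {inten:.2f}\n")
            fh.write("END IONS\n")


def read_oxonium_tsv(path: str | Path) -> OxoniumPanel:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return OxoniumPanel(tuple(zip(df["name"].astype(str), df["mz"].astype(float))))
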