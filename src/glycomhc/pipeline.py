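"""End-to-end orchestration: search -> layered FDR -> glycan assignment ->
allele assignment / positional characterization, with TSV outputs and
per-stage count logging."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import fdr, glycan_assign, hla_deconv
from .glycodb import build_default_glycan_db, read_glycan_tsv
from .search import GROUP_GLYCO, SearchConfig, psms_to_frame, search_spectra
from .sequence_space import (ModConfig, enumerate_nonspecific_peptides,
                             make_decoys, read_fasta, build_peptide_index)
from .spectra import read_spectra

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run settings; defaults are the class II presets.

    Serialized as JSON; unknown keys are rejected on load."""

    fasta: str = ""
    spectra: str = ""
    glycan_tsv: str | None = None
    rank_tsv: str | None = None
    known_sites_tsv: str | None = None
    out_dir: str = "glycomhc_out"
    seed: int = 0
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
    variable_mods: bool = True
    max_mods: int = 2
    entrapment_tag: str | None = None

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("isotope_errors", "peptide_length_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            precursor_tol_ppm=self.precursor_tol_ppm,
            fragment_tol_ppm=self.fragment_tol_ppm,
            isotope_errors=self.isotope_errors,
            peptide_length_range=self.peptide_length_range,
            oxonium_threshold=self.oxonium_threshold,
            glyco_delta_cutoff=self.glyco_delta_cutoff,
            psm_fdr=self.psm_fdr,
            peptide_fdr=self.peptide_fdr,
            protein_fdr=self.protein_fdr,
            glycan_q_threshold=self.glycan_q_threshold,
            rank_threshold=self.rank_threshold,
        )


def annotate_known_sites(final_psms: pd.DataFrame,
                         known_sites: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Label each glyco PSM's protein site against a known-site table.

    known_sites columns: 'accession', 'site_1b' (1-based protein position).
    Categories: known_site, known_protein_new_site, new_protein. Returns
    (annotated rows, summary fractions at PSM / peptide / site level)."""
    if not {"accession", "site_1b"} <= set(known_sites.columns):
        raise ValueError("known-site table needs 'accession' and 'site_1b' columns")
    known_pairs = set(zip(known_sites["accession"].astype(str),
                          known_sites["site_1b"].astype(int)))
    known_prots = {acc for acc, _ in known_pairs}
    rows = []
    for row in final_psms.itertuples():
        if row.group != GROUP_GLYCO or row.protein_site_1b in ("", None) \
                or pd.isna(row.protein_site_1b):
            continue
        acc = row.proteins[0] if isinstance(row.proteins, (list, tuple)) else str(row.proteins).split(";")[0]
        site = int(row.protein_site_1b)
        if (acc, site) in known_pairs:
            category = "known_site"
        elif acc in known_prots:
            category = "known_protein_new_site"
        else:
            category = "new_protein"
        rows.append({"scan": row.scan, "peptide": row.peptide, "accession": acc,
                     "site_1b": site, "category": category})
    ann = pd.DataFrame(rows)
    summary = {}
    if not ann.empty:
        for level, key in (("psm", ["scan"]), ("peptide", ["peptide"]),
                           ("site", ["accession", "site_1b"])):
            dedup = ann.drop_duplicates(key + ["category"]).drop_duplicates(key)
            frac = dedup["category"].value_counts(normalize=True).to_dict()
            summary[level] = {c: round(float(frac.get(c, 0.0)), 6)
                              for c in ("known_site", "known_protein_new_site",
                                        "new_protein")}
    return ann, summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; writes per-stage TSVs under out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("fasta", "spectra"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"missing input {name}: {path!r}")

    targets = read_fasta(config.fasta, entrapment_tag=config.entrapment_tag)
    targets = [t for t in targets if not t.is_decoy]
    proteins = targets + make_decoys(targets)
    logger.info("proteins: %d targets + %d decoys", len(targets), len(targets))
    candidates = enumerate_nonspecific_peptides(proteins, config.peptide_length_range)
    mod_config = ModConfig(max_mods=config.max_mods) if config.variable_mods \
        else ModConfig(False, False, False, 0)
    index = build_peptide_index(candidates, mod_config)
    logger.info("peptide index: %d candidates, %d variants", len(candidates), len(index))

    if config.glycan_tsv:
        glycan_db = read_glycan_tsv(config.glycan_tsv)
    else:
        glycan_db = build_default_glycan_db()
    logger.info("glycan database: %d compositions", len(glycan_db))

    spectra = list(read_spectra(config.spectra))
    logger.info("spectra read: %d", len(spectra))
    search_cfg = config.search_config()
    psms = search_spectra(spectra, index, glycan_db, search_cfg)
    logger.info("rank-1 PSMs: %d", len(psms))
    df = psms_to_frame(psms)
    df["proteins"] = [tuple(sorted({acc for acc, _, _ in
                                    p.peptide.candidate.protein_refs}))
                      for p in psms]
    df.to_csv(out_dir / "psm.tsv", sep="\t", index=False)

    psm_outcome = fdr.group_specific_filter(df, config.glyco_delta_cutoff,
                                            config.psm_fdr)
    accepted = psm_outcome.table.loc[psm_outcome.accepted]
    logger.info("PSM filter: %s", psm_outcome.counts)

    pep_outcome = fdr.peptide_level_filter(accepted, config.peptide_fdr)
    pep_table = pep_outcome.table.loc[pep_outcome.accepted].copy()
    logger.info("peptide filter: %s", pep_outcome.counts)

    # posterior for protein scoring: mixture fit when feasible, else 1 - q
    t_scores = df.loc[~df["is_decoy"], "hyperscore"].to_numpy()
    d_scores = df.loc[df["is_decoy"], "hyperscore"].to_numpy()
    try:
        model = fdr.fit_score_mixture(t_scores, d_scores)
        pep_table["posterior"] = model.posterior(pep_table["hyperscore"].to_numpy())
    except ValueError:
        pep_table["posterior"] = np.clip(1.0 - pep_table["pep_q"], 0.0, 1.0)

    # decoy peptides are needed for the protein-level target-decoy estimate
    pep_all = pep_outcome.table.copy()
    pep_all["posterior"] = np.interp(
        pep_all["hyperscore"], pep_table["hyperscore"].sort_values(),
        pep_table.sort_values("hyperscore")["posterior"]) \
        if not pep_table.empty else 0.0
    prot_outcome, accepted_proteins = fdr.protein_level_filter(
        pep_all, config.protein_fdr)
    logger.info("protein filter: %s", prot_outcome.counts)

    accepted_pepset = set(pep_table["peptide"])
    final = accepted[accepted["peptide"].isin(accepted_pepset)]
    final = fdr.sequential_protein_filter(final, accepted_proteins)
    final_psms = [psms[i] for i in final.index]
    logger.info("after sequential protein filter: %d PSMs", len(final))

    spectra_by_scan = {s.scan_id: s for s in spectra}
    retained_glyco, glyco_summary = glycan_assign.assign_glycans(
        final_psms, spectra_by_scan, glycan_db,
        q_threshold=config.glycan_q_threshold,
        tol_ppm=config.precursor_tol_ppm,
        isotope_errors=config.isotope_errors,
        seed=config.seed)
    logger.info("glycan assignment: %s", glyco_summary)

    retained_scans = {p.scan_id for p in retained_glyco}
    final = final[(final["group"] != GROUP_GLYCO) | final["scan"].isin(retained_scans)]
    final_psms = [psms[i] for i in final.index]
    final = psms_to_frame(final_psms)
    final["proteins"] = [tuple(sorted({acc for acc, _, _ in
                                       p.peptide.candidate.protein_refs}))
                         for p in final_psms]
    # 1-based protein coordinate of the first sequon (glyco PSMs)
    sites = []
    for p in final_psms:
        if p.group == GROUP_GLYCO and p.glyco_site is not None:
            acc, start, _ = sorted(p.peptide.candidate.protein_refs)[0]
            sites.append(start + p.glyco_site + 1)
        else:
            sites.append("")
    final["protein_site_1b"] = sites
    final.to_csv(out_dir / "glycopsm.tsv", sep="\t", index=False)

    outputs = {"psm": df, "final": final, "glyco_summary": glyco_summary,
               "psm_outcome": psm_outcome, "peptide_outcome": pep_outcome,
               "protein_outcome": prot_outcome}

    if config.entrapment_tag:
        species = {p.accession: p.species_tag for p in proteins}
        rate, offenders = fdr.entrapment_rate(final, species, config.entrapment_tag)
        outputs["entrapment_rate"] = rate
        logger.info("entrapment rate: %.4f (%d offending PSMs)", rate, len(offenders))

    if config.rank_tsv:
        rank_table = hla_deconv.load_rank_table(config.rank_tsv)
        glyco_final = final[final["group"] == GROUP_GLYCO]
        peptides = sorted(set(final["peptide"]) & set(rank_table["peptide"]))
        assignments = hla_deconv.assign_alleles(peptides, rank_table,
                                                config.rank_threshold)
        site_map = {p.peptide.sequence: list(p.peptide.candidate.sequon_positions)
                    for p in final_psms if p.group == GROUP_GLYCO}
        hla_deconv.annotate_glyco_positions(assignments, site_map)
        rows = [{
            "peptide": a.peptide, "allele": a.allele, "rank": a.rank,
            "core_offset": a.core_offset if a.core_offset is not None else "",
            "core_offset_1b": a.core_offset + 1 if a.core_offset is not None else "",
            "relative_positions": ";".join(map(str, a.relative_positions)),
            "categories": ";".join(a.position_categories),
        } for a in assignments]
        pd.DataFrame(rows).to_csv(out_dir / "assignments.tsv", sep="\t", index=False)
        outputs["assignments"] = assignments
        glyco_types = {p.peptide.sequence: p.glycan.type_class
                       for p in final_psms
                       if p.group == GROUP_GLYCO and p.glycan is not None}
        summary = hla_deconv.summarize_positions(assignments, glyco_types)
        summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
        outputs["position_summary"] = summary
    else:
        pd.DataFrame([glyco_summary]).to_csv(out_dir / "summary.tsv", sep="\t",
                                             index=False)

    if config.known_sites_tsv:
        known = pd.read_csv(config.known_sites_tsv, sep="\t")
        ann, site_summary = annotate_known_sites(final, known)
        ann.to_csv(out_dir / "known_sites.tsv", sep="\t", index=False)
        outputs["known_site_summary"] = site_summary
        logger.info("known-site categories: %s", site_summary)

    return outputs
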