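# glycomhc

A desk-scale toolkit for glyco-immunopeptidomics: a sequon-aware,
nonspecific (open mass-offset) glycopeptide search with oxonium-ion
triage, group-specific target-decoy FDR control with glycan-level
q-value filtering, and HLA class II binding-core deconvolution with
glycosite positional characterization. Every stage is testable
end-to-end on synthetic data with known ground truth — no external
datasets or predictors are required.

## What it does

1. **Digest** — reads a protein FASTA, builds reversed decoys, and
   enumerates nonspecific peptides (default lengths 7–25). Target
   peptides carrying the N-X-S/T sequon (X ≠ P) and decoy peptides
   carrying the reversed pattern are flagged as potential
   glycopeptides; reversal is a bijection on substrings, so the
   potential-glycopeptide counts are exactly equal between target and
   decoy space.
2. **Search** — MGF spectra are matched against a mass-sorted peptide
   index (20 ppm precursor / 15 ppm fragment tolerance, isotope errors
   0/+1/+2, variable Met oxidation, protein N-term acetylation and Cys
   cysteinylation). Spectra whose oxonium-ion peaks sum to ≥ 10 % of
   the base peak additionally enter the glyco branch, where precursor
   mass minus any database glycan mass is looked up among
   sequon-bearing peptides and Y-ions augment the b/y fragment set.
   Scoring is an MSFragger-style hyperscore.
3. **FDR** — PSMs are split at a 145 Da delta-mass cutoff into glyco
   and non-glyco groups and filtered *separately* to 1 % FDR by
   target-decoy q-values (the small glyco group gets its own, stricter
   threshold). Peptide-level, protein-level (greedy parsimony with
   decoy proteins) and sequential protein filters follow; an optional
   entrapment-species audit reports the fraction of glyco PSMs mapping
   only to foreign proteins.
4. **Glycan assignment** — each glyco PSM's delta mass is matched
   against target compositions and mass-shifted decoy compositions;
   candidates are scored on composition-dependent diagnostic ions
   (oxonium subset + Y ladder + fucose diagnostic) minus a ppm
   mass-error penalty, and assignments are filtered at a 0.05 glycan
   q-value.
5. **HLA class II deconvolution** — peptides are assigned to their
   lowest-percentile-rank allele (rank ≤ 20, else TRASH) from an
   externally produced rank table, or deconvolved without a predictor
   by a PWM-mixture EM over latent (motif class, 9-mer core offset)
   with a flat background class and BIC model selection. Glycosites
   are reported relative to the binding-core start (negative =
   upstream, 0–8 = core, ≥ 9 = downstream) and summarized per DP/DQ/DR
   gene group, with two-sided Fisher tests for motif conservation.
6. **Synthetic generators** — proteomes with planted sequons, spectra
   with b/y (+Y, +oxonium) peaks and configurable noise, scored PSM
   populations with a tunable search-space asymmetry, and
   percentile-rank tables with planted binding motifs. All generators
   are deterministic under a seed and emit truth tables.

## CLI

```sh
glycomhc glycans build --out glycans.tsv
glycomhc simulate proteome --n-proteins 20 --entrapment-fraction 0.2 \
    --out-fasta prot.fasta --out-truth prot_truth.tsv
glycomhc simulate spectra --fasta prot.fasta --n-spectra 500 \
    --out-mgf spec.mgf --out-truth spec_truth.tsv
glycomhc search --fasta prot.fasta --mgf spec.mgf --out psm.tsv
glycomhc filter --psm-tsv psm.tsv --psm-fdr 0.01 --pep-fdr 0.01 \
    --prot-fdr 0.01 --glyco-cutoff 145 --out filtered.tsv
glycomhc assign-glycans --psm-tsv filtered.tsv --mgf spec.mgf --out glyco.tsv
glycomhc simulate ranks --out-ranks ranks.tsv --out-truth rank_truth.tsv
glycomhc deconvolve --peptides-tsv rank_truth.tsv --rank-tsv ranks.tsv \
    --out-prefix deconv
glycomhc run-all --config config.json
```

`run-all` takes a JSON config (see `glycomhc.pipeline.PipelineConfig`;
unknown keys are rejected, defaults are the class II presets: lengths
7–25, 20/15 ppm, isotope errors {0,+1,+2}, oxonium gate 0.10, delta
cutoff 145 Da, 1 % FDR levels, glycan q ≤ 0.05, rank ≤ 20) and writes
`psm.tsv`, `glycopsm.tsv`, `assignments.tsv` and `summary.tsv` to the
output directory.

## Notes

- Spectra are assumed centroided/deisotoped; the MGF dialect uses
  BEGIN/END IONS, PEPMASS and CHARGE. mzML input is not supported in
  this offline build — convert to MGF first.
- The default glycan database is generated combinatorially (HexNAc ≤ 6,
  Hex ≤ 10, Fuc ≤ 3, NeuAc ≤ 4, mass 145–4000 Da); a custom list can be
  supplied as a TSV with a `composition` column.
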