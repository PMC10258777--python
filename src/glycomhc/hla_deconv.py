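"""HLA class II allele assignment and binding-core deconvolution.

Percentile ranks from an external class II binding predictor drive allele
assignment: a peptide goes to its lowest-rank allele when that rank is at
or below the threshold (default 20), otherwise to TRASH (assumed
co-immunoprecipitated contaminant). A PWM-mixture EM over latent
(motif class, 9-mer core offset) provides predictor-free deconvolution,
and glycosites are reported relative to the binding-core start:
negative = upstream, 0-8 = inside the core, >=9 = downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .constants import AMINO_ACIDS

logger = logging.getLogger(__name__)

TRASH = "TRASH"
CORE_LENGTH = 9

UPSTREAM = "upstream"
CORE = "core"
DOWNSTREAM = "downstream"

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class AlleleAssignment:
    peptide: str
    allele: str            # allele name or TRASH
    rank: float
    core_offset: int | None = None
    glyco_sites: tuple[int, ...] = ()       # 0-based peptide positions
    relative_positions: tuple[int, ...] = ()
    position_categories: tuple[str, ...] = ()


def load_rank_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "allele", "rank"}
    if not required <= set(df.columns):
        raise ValueError(f"rank table must have columns {sorted(required)}")
    if ((df["rank"] < 0) | (df["rank"] > 100)).any():
        raise ValueError("percentile ranks must lie in [0, 100]")
    if df.duplicated(["peptide", "allele"]).any():
        raise ValueError("duplicate (peptide, allele) rows in rank table")
    return df


def assign_alleles(
    peptides: Sequence[str],
    rank_table: pd.DataFrame,
    threshold: float = 20.0,
) -> list[AlleleAssignment]:
    """Lowest-rank allele if min rank <= threshold, else TRASH.

    Rank ties go to the lexicographically first allele (logged). Peptides
    absent from the table raise.
    """
    grouped = {pep: sub for pep, sub in rank_table.groupby("peptide")}
    missing = [p for p in peptides if p not in grouped]
    if missing:
        raise ValueError(f"peptides absent from rank table: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    out = []
    for pep in peptides:
        sub = grouped[pep].sort_values(["rank", "allele"], kind="stable")
        best = sub.iloc[0]
        if len(sub) > 1 and sub.iloc[1]["rank"] == best["rank"]:
            logger.info("rank tie for %s; taking %s", pep, best["allele"])
        if best["rank"] <= threshold:
            offset = None
            if "core_offset" in sub.columns and not pd.isna(best.get("core_offset")):
                offset = int(best["core_offset"])
                if offset + CORE_LENGTH > len(pep) or offset < 0:
                    raise ValueError(f"core offset {offset} does not fit in {pep!r}")
            out.append(AlleleAssignment(pep, str(best["allele"]),
                                        float(best["rank"]), offset))
        else:
            out.append(AlleleAssignment(pep, TRASH, float(best["rank"]), None))
    return out


def relative_glyco_position(site_index: int, core_offset: int,
                            peptide_length: int | None = None) -> tuple[int, str]:
    """Site position relative to the binding-core start and its category.

    p < 0 upstream; 0 <= p <= 8 inside the core; p >= 9 downstream."""
    if site_index < 0 or (peptide_length is not None and site_index >= peptide_length):
        raise ValueError(f"glycosite index {site_index} outside peptide")
    if peptide_length is not None and core_offset + CORE_LENGTH > peptide_length:
        raise ValueError(f"core offset {core_offset} does not fit in peptide")
    p = site_index - core_offset
    if p < 0:
        category = UPSTREAM
    elif p <= CORE_LENGTH - 1:
        category = CORE
    else:
        category = DOWNSTREAM
    return p, category


def annotate_glyco_positions(
    assignments: Sequence[AlleleAssignment],
    glyco_sites: Mapping[str, Sequence[int]],
) -> list[AlleleAssignment]:
    """Fill relative positions/categories for peptides with known offsets."""
    for a in assignments:
        sites = tuple(glyco_sites.get(a.peptide, ()))
        a.glyco_sites = sites
        if a.core_offset is None or not sites:
            continue
        rels, cats = [], []
        for s in sites:
            p, cat = relative_glyco_position(s, a.core_offset, len(a.peptide))
            rels.append(p)
            cats.append(cat)
        a.relative_positions = tuple(rels)
        a.position_categories = tuple(cats)
    return assignments


# ---------------------------------------------------------------------------
# PWM mixture deconvolution


@dataclass
class MotifModel:
    pwms: np.ndarray              # (K, 9, 20), rows sum to 1
    class_weights: np.ndarray     # (K + 1,), last = trash/background class
    offset_weights: np.ndarray    # (K, max_offsets), per-class offset prefs
    background: np.ndarray        # (20,)
    responsibilities: np.ndarray  # (n_peptides, K + 1)
    log_likelihood: float
    loglik_trace: list[float] = field(default_factory=list)
    bic: float = 0.0

    @property
    def n_classes(self) -> int:
        return self.pwms.shape[0]

    def best_offset(self, peptide: str, k: int) -> int:
        """Max-likelihood core offset of a peptide under motif k."""
        enc = encode_peptide(peptide)
        n_off = len(peptide) - CORE_LENGTH + 1
        scores = [
            sum(math.log(self.pwms[k, j, enc[o + j]] / self.background[enc[o + j]])
                for j in range(CORE_LENGTH))
            + math.log(self.offset_weights[k, o] + 1e-12)
            for o in range(n_off)
        ]
        return int(np.argmax(scores))


def encode_peptide(peptide: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[a] for a in peptide], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in {peptide!r}") from None


def _em_once(
    encoded: list[np.ndarray],
    n_classes: int,
    background: np.ndarray,
    rng: np.random.Generator,
    max_offsets: int,
    max_iter: int = 80,
    tol: float = 1e-6,
    pseudocount: float = 0.1,
) -> MotifModel:
    """One EM run over latent (class, offset) plus a flat trash class."""
    n = len(encoded)
    K = n_classes
    if K == 0:  # trash-only model: likelihood ratio 1 for every peptide
        resp = np.ones((n, 1))
        return MotifModel(pwms=np.empty((0, CORE_LENGTH, 20)),
                          class_weights=np.ones(1),
                          offset_weights=np.empty((0, max_offsets)),
                          background=background, responsibilities=resp,
                          log_likelihood=0.0, loglik_trace=[0.0], bic=0.0)
    # data-driven init: seed each class PWM from a random 9-mer occurrence
    # (smoothed toward background) so EM starts near a real motif phase
    pwms = np.empty((K, CORE_LENGTH, 20))
    for k in range(K):
        enc = encoded[int(rng.integers(len(encoded)))]
        off = int(rng.integers(len(enc) - CORE_LENGTH + 1))
        onehot = np.zeros((CORE_LENGTH, 20))
        onehot[np.arange(CORE_LENGTH), enc[off:off + CORE_LENGTH]] = 1.0
        pwms[k] = 0.5 * onehot + 0.5 * background[None, :]
    class_w = np.full(K + 1, 1.0 / (K + 1))
    offset_w = np.full((K, max_offsets), 1.0 / max_offsets)

    # Per-peptide log background of every 9-mer window, cached
    log_bg = np.log(background)
    windows = []   # per peptide: (n_off, 9) residue indices
    for enc in encoded:
        n_off = len(enc) - CORE_LENGTH + 1
        win = np.stack([enc[o:o + CORE_LENGTH] for o in range(n_off)])
        windows.append(win)

    trace: list[float] = []
    resp_class = np.zeros((n, K + 1))
    for _ in range(max_iter):
        log_pwm = np.log(pwms + 1e-300)
        ll_total = 0.0
        new_pwm = np.full((K, CORE_LENGTH, 20), pseudocount)
        new_class = np.full(K + 1, pseudocount)
        new_offset = np.full((K, max_offsets), pseudocount)
        for i, win in enumerate(windows):
            n_off = win.shape[0]
            # log ratio PWM/background per (class, offset)
            lr = np.zeros((K, n_off))
            for k in range(K):
                lr[k] = log_pwm[k][np.arange(CORE_LENGTH)[None, :], win].sum(axis=1) \
                    - log_bg[win].sum(axis=1)
            with np.errstate(divide="ignore"):
                joint = lr + np.log(class_w[:K, None]) \
                    + np.log(offset_w[:, :n_off] / offset_w[:, :n_off].sum(axis=1, keepdims=True))
            trash_log = math.log(class_w[K])  # flat class: likelihood ratio 1
            m = max(joint.max(initial=-np.inf), trash_log)
            probs = np.exp(joint - m)
            trash_p = math.exp(trash_log - m)
            z = probs.sum() + trash_p
            ll_total += m + math.log(z)
            probs /= z
            trash_p /= z
            resp_class[i, :K] = probs.sum(axis=1)
            resp_class[i, K] = trash_p
            new_class[:K] += probs.sum(axis=1)
            new_class[K] += trash_p
            new_offset[:, :n_off] += probs
            for k in range(K):
                np.add.at(new_pwm[k], (np.arange(CORE_LENGTH)[None, :].repeat(n_off, 0), win),
                          probs[k][:, None])
        trace.append(ll_total)
        class_w = new_class / new_class.sum()
        offset_w = new_offset / new_offset.sum(axis=1, keepdims=True)
        pwms = new_pwm / new_pwm.sum(axis=2, keepdims=True)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1):
            break

    n_params = K * CORE_LENGTH * 19 + K + K * (max_offsets - 1)
    bic = -2 * trace[-1] + n_params * math.log(max(n, 2))
    return MotifModel(pwms=pwms, class_weights=class_w, offset_weights=offset_w,
                      background=background, responsibilities=resp_class.copy(),
                      log_likelihood=trace[-1], loglik_trace=trace, bic=bic)


def deconvolve_motifs(
    peptides: Sequence[str],
    k_max: int = 10,
    runs: int = 20,
    min_length: int = 12,
    seed: int = 0,
    background: np.ndarray | None = None,
    max_iter: int = 80,
) -> MotifModel:
    """Best-of-`runs` EM deconvolution; K <= k_max selected by BIC.

    Peptides shorter than min_length are excluded. A flat-background trash
    class is always present in addition to the K motif classes.
    """
    kept = [p for p in peptides if len(p) >= min_length]
    if len(kept) < 50:
        raise ValueError(f"need >=50 peptides of length >= {min_length}, got {len(kept)}")
    encoded = [encode_peptide(p) for p in kept]
    if background is None:
        counts = np.bincount(np.concatenate(encoded), minlength=20).astype(float)
        background = (counts + 1) / (counts.sum() + 20)
    max_offsets = max(len(e) for e in encoded) - CORE_LENGTH + 1
    rng = np.random.default_rng(seed)
    best: MotifModel | None = None
    # K = 0 (trash-only) competes too: on motif-free peptides it wins the
    # BIC comparison and the background class absorbs everything
    for k in range(0, k_max + 1):
        if len(kept) < k:
            raise ValueError("fewer peptides than motif classes")
        best_k: MotifModel | None = None
        for _ in range(1 if k == 0 else runs):
            model = _em_once(encoded, k, background, rng, max_offsets, max_iter)
            if best_k is None or model.log_likelihood > best_k.log_likelihood:
                best_k = model
        if best is None or best_k.bic < best.bic:
            best = best_k
    return best


# ---------------------------------------------------------------------------
# Fisher exact test and cohort summaries


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    tables (with fixed margins) no more likely than the observed one."""
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError(f"counts must be non-negative integers, got {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    pmf = hypergeom.pmf(np.arange(lo, hi + 1), n, col1, row1)
    observed = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= observed * (1 + 1e-7)].sum()))


def motif_conservation_test(
    assignments: Sequence[AlleleAssignment],
    glyco_flags: Mapping[str, bool],
) -> dict[str, float]:
    """Per-allele Fisher test of (assigned vs TRASH) x (glyco vs non-glyco).

    Only alleles seen with both classes are tested; degenerate margins give
    p = 1.0 with a warning.
    """
    rows = [(a.allele, bool(glyco_flags[a.peptide])) for a in assignments
            if a.peptide in glyco_flags]
    if not any(g for _, g in rows) or not any(not g for _, g in rows):
        raise ValueError("need at least one glyco and one non-glyco peptide")
    alleles = sorted({al for al, _ in rows if al != TRASH})
    out = {}
    for allele in alleles:
        a = sum(1 for al, g in rows if al == allele and g)
        b = sum(1 for al, g in rows if al == TRASH and g)
        c = sum(1 for al, g in rows if al == allele and not g)
        d = sum(1 for al, g in rows if al == TRASH and not g)
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            logger.warning("degenerate margins for %s; p set to 1.0", allele)
            out[allele] = 1.0
        else:
            out[allele] = fisher_exact_two_sided([[a, b], [c, d]])
    return out


def gene_group(allele: str) -> str:
    """DP / DQ / DR from the allele name prefix."""
    for prefix, group in (("DPA", "DP"), ("DPB", "DP"), ("DQA", "DQ"),
                          ("DQB", "DQ"), ("DRB", "DR"), ("DRA", "DR")):
        if allele.upper().startswith(prefix):
            return group
    raise ValueError(f"cannot parse HLA gene group from allele {allele!r}")


def summarize_positions(
    assignments: Sequence[AlleleAssignment],
    glycan_types: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per gene group: fraction of glycosites inside vs outside the binding
    core, and glycan type-class fractions when annotations are given."""
    rows = []
    for a in assignments:
        if a.allele == TRASH or not a.relative_positions:
            continue
        group = gene_group(a.allele)
        for cat in a.position_categories:
            rows.append({
                "group": group,
                "inside_core": cat == CORE,
                "glycan_type": (glycan_types or {}).get(a.peptide, ""),
            })
    if not rows:
        return pd.DataFrame(columns=["group", "n_sites", "fraction_inside",
                                     "fraction_outside"])
    df = pd.DataFrame(rows)
    out = []
    for group, sub in df.groupby("group"):
        rec = {
            "group": group,
            "n_sites": len(sub),
            "fraction_inside": float(sub["inside_core"].mean()),
            "fraction_outside": float(1 - sub["inside_core"].mean()),
        }
        if glycan_types:
            for t in sorted(x for x in sub["glycan_type"].unique() if x):
                rec[f"fraction_{t}"] = float((sub["glycan_type"] == t).mean())
        out.append(rec)
    return pd.DataFrame(out)
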