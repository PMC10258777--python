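"""Layered false-discovery-rate control.

PSMs are split at a delta-mass cutoff (default 145 Da, the smallest glycan
searched) into glycosylated and non-glycosylated groups and filtered
*separately* by target-decoy q-values — the small glyco group gets its own
(usually stricter) score threshold instead of inheriting the permissive
pooled one. Peptide- and protein-level filters and a sequential protein
filter follow, plus an entrapment audit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

GROUP_GLYCO = "glyco"
GROUP_NONGLYCO = "nonglyco"


def tdc_qvalues(scores: Sequence[float], decoy_flags: Sequence[bool],
                add_one: bool = False) -> np.ndarray:
    """Target-decoy competition q-values, one per input item.

    At a score threshold t: FDR-hat(t) = #decoys>=t / max(1, #targets>=t),
    capped at 1. q(i) is the minimum FDR-hat over thresholds <= score(i).
    Items of equal score share one threshold, with decoys counted before
    targets (conservative).

    With ``add_one`` the numerator becomes #decoys + 1, the finite-sample
    correction that makes the accepted set's expected FDP <= the level
    (the bare ratio is anti-conservative when few decoys sit near the
    threshold; the PSM-level filters use the corrected form).
    """
    scores = np.asarray(scores, dtype=np.float64)
    decoys = np.asarray(decoy_flags, dtype=bool)
    if scores.shape != decoys.shape:
        raise ValueError("scores and decoy_flags length mismatch")
    if len(scores) == 0 or int((~decoys).sum()) == 0:
        raise ValueError("need at least one target PSM")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    d_sorted = decoys[order]
    cum_d = np.cumsum(d_sorted)
    cum_t = np.cumsum(~d_sorted)
    # score-level granularity: counts evaluated at the end of each tie block
    is_block_end = np.ones(len(s_sorted), dtype=bool)
    is_block_end[:-1] = s_sorted[:-1] != s_sorted[1:]
    block_end_idx = np.flatnonzero(is_block_end)
    # map every sorted position to the end of its block
    block_of = np.searchsorted(block_end_idx, np.arange(len(s_sorted)))
    end_pos = block_end_idx[block_of]
    numerator = cum_d[end_pos] + (1 if add_one else 0)
    fdr_hat = np.minimum(1.0, numerator / np.maximum(1, cum_t[end_pos]))
    q_sorted = np.minimum.accumulate(fdr_hat[::-1])[::-1]
    q = np.empty(len(scores))
    q[order] = q_sorted
    return q


@dataclass
class FilterOutcome:
    """Result of one FDR filtering level."""

    level: str
    table: pd.DataFrame            # input rows + 'q' column
    accepted: pd.Index             # row labels of accepted *target* rows
    thresholds: dict[str, float]   # per group (or 'all'): min accepted score
    counts: dict[str, dict[str, int]] = field(default_factory=dict)


def group_specific_filter(
    psms: pd.DataFrame,
    cutoff_da: float = 145.0,
    fdr_level: float = 0.01,
    score_col: str = "hyperscore",
    add_one: bool = True,
) -> FilterOutcome:
    """Split PSMs at the delta-mass cutoff and q-filter each group separately.

    Requires columns: score_col, 'is_decoy', 'delta_mass'. Adds 'group' and
    'psm_q' columns; accepts target rows with q <= fdr_level in each group.
    """
    df = psms.copy()
    df["group"] = np.where(df["delta_mass"] >= cutoff_da, GROUP_GLYCO, GROUP_NONGLYCO)
    df["psm_q"] = np.nan
    thresholds: dict[str, float] = {}
    counts: dict[str, dict[str, int]] = {}
    accepted_labels: list = []
    for group, sub in df.groupby("group"):
        n_targets = int((~sub["is_decoy"]).sum())
        counts[group] = {"targets": n_targets, "decoys": int(sub["is_decoy"].sum())}
        if n_targets == 0:
            logger.warning("group %r has no target PSMs; returning empty", group)
            thresholds[group] = math.inf
            counts[group]["accepted"] = 0
            continue
        q = tdc_qvalues(sub[score_col].to_numpy(), sub["is_decoy"].to_numpy(),
                        add_one=add_one)
        df.loc[sub.index, "psm_q"] = q
        ok = (~sub["is_decoy"].to_numpy()) & (q <= fdr_level)
        accepted_labels.extend(sub.index[ok])
        thresholds[group] = float(sub[score_col].to_numpy()[ok].min()) if ok.any() else math.inf
        counts[group]["accepted"] = int(ok.sum())
    return FilterOutcome("psm", df, pd.Index(accepted_labels), thresholds, counts)


def pooled_filter(
    psms: pd.DataFrame,
    fdr_level: float = 0.01,
    score_col: str = "hyperscore",
    add_one: bool = True,
) -> FilterOutcome:
    """Single pooled target-decoy filter over all PSMs (for comparison with
    the group-specific procedure; this is the pathological baseline)."""
    df = psms.copy()
    q = tdc_qvalues(df[score_col].to_numpy(), df["is_decoy"].to_numpy(),
                    add_one=add_one)
    df["psm_q"] = q
    ok = (~df["is_decoy"].to_numpy()) & (q <= fdr_level)
    threshold = float(df[score_col].to_numpy()[ok].min()) if ok.any() else math.inf
    counts = {"all": {"targets": int((~df["is_decoy"]).sum()),
                      "decoys": int(df["is_decoy"].sum()),
                      "accepted": int(ok.sum())}}
    return FilterOutcome("psm-pooled", df, df.index[ok], {"all": threshold}, counts)


def peptide_level_filter(
    accepted_psms: pd.DataFrame,
    fdr_level: float = 0.01,
    score_col: str = "hyperscore",
) -> FilterOutcome:
    """Collapse to best PSM per (peptide, is_decoy) and q-filter peptides."""
    if "peptide" not in accepted_psms.columns:
        raise ValueError("peptide_level_filter requires a 'peptide' column")
    if accepted_psms.empty:
        empty = accepted_psms.assign(pep_q=pd.Series(dtype=float))
        return FilterOutcome("peptide", empty, pd.Index([]), {"all": math.inf},
                             {"all": {"targets": 0, "decoys": 0, "accepted": 0}})
    best = (accepted_psms
            .sort_values(score_col, ascending=False, kind="stable")
            .groupby(["peptide", "is_decoy"], as_index=False, sort=True)
            .first())
    q = tdc_qvalues(best[score_col].to_numpy(), best["is_decoy"].to_numpy())
    best["pep_q"] = q
    ok = (~best["is_decoy"].to_numpy()) & (q <= fdr_level)
    threshold = float(best[score_col].to_numpy()[ok].min()) if ok.any() else math.inf
    counts = {"all": {"targets": int((~best["is_decoy"]).sum()),
                      "decoys": int(best["is_decoy"].sum()),
                      "accepted": int(ok.sum())}}
    return FilterOutcome("peptide", best, best.index[ok], {"all": threshold}, counts)


def greedy_parsimony(peptide_proteins: dict[str, Sequence[str]]) -> dict[str, list[str]]:
    """Minimal-ish protein set explaining all peptides, greedily.

    Iteratively picks the protein covering the most unexplained peptides
    (ties: more total peptides, then accession order) and assigns those
    peptides to it. Returns protein -> assigned peptides.
    """
    protein_to_peps: dict[str, set[str]] = {}
    for pep, prots in peptide_proteins.items():
        for prot in prots:
            protein_to_peps.setdefault(prot, set()).add(pep)
    unexplained = set(peptide_proteins)
    assignment: dict[str, list[str]] = {}
    while unexplained:
        best_prot = None
        best_key = None
        for prot, peps in protein_to_peps.items():
            novel = len(peps & unexplained)
            if novel == 0:
                continue
            key = (-novel, -len(peps), prot)
            if best_key is None or key < best_key:
                best_key = key
                best_prot = prot
        if best_prot is None:  # peptides with no protein refs
            break
        covered = protein_to_peps[best_prot] & unexplained
        assignment[best_prot] = sorted(covered)
        unexplained -= covered
    return assignment


def protein_level_filter(
    peptides: pd.DataFrame,
    fdr_level: float = 0.01,
    posterior_col: str = "posterior",
) -> tuple[FilterOutcome, set[str]]:
    """Greedy-parsimony protein inference with decoy-based protein q-values.

    Requires columns 'peptide', 'is_decoy', 'proteins' (iterable of
    accessions) and a posterior column. Protein score is
    sum(-ln(1 - posterior)) over its parsimoniously assigned peptides.
    Returns (outcome, accepted target protein accessions).
    """
    pep_prots = {row.peptide: list(row.proteins) for row in peptides.itertuples()}
    posterior = {row.peptide: float(getattr(row, posterior_col))
                 for row in peptides.itertuples()}
    decoy_pep = {row.peptide: bool(row.is_decoy) for row in peptides.itertuples()}
    assignment = greedy_parsimony(pep_prots)
    rows = []
    for prot, peps in assignment.items():
        score = sum(-math.log(max(1e-9, 1.0 - min(posterior[p], 1 - 1e-9))) for p in peps)
        is_decoy = all(decoy_pep[p] for p in peps)
        rows.append({"protein": prot, "score": score, "is_decoy": is_decoy,
                     "n_peptides": len(peps), "peptides": peps})
    prot_df = pd.DataFrame(rows)
    if prot_df.empty or not (~prot_df["is_decoy"]).any():
        return (FilterOutcome("protein", prot_df, pd.Index([]), {"all": math.inf}),
                set())
    q = tdc_qvalues(prot_df["score"].to_numpy(), prot_df["is_decoy"].to_numpy())
    prot_df["prot_q"] = q
    ok = (~prot_df["is_decoy"].to_numpy()) & (q <= fdr_level)
    threshold = float(prot_df["score"].to_numpy()[ok].min()) if ok.any() else math.inf
    counts = {"all": {"targets": int((~prot_df["is_decoy"]).sum()),
                      "decoys": int(prot_df["is_decoy"].sum()),
                      "accepted": int(ok.sum())}}
    outcome = FilterOutcome("protein", prot_df, prot_df.index[ok], {"all": threshold}, counts)
    return outcome, set(prot_df.loc[outcome.accepted, "protein"])


def sequential_protein_filter(
    psms: pd.DataFrame, accepted_proteins: set[str]
) -> pd.DataFrame:
    """Keep PSMs with at least one protein in the accepted set."""
    keep = psms["proteins"].map(
        lambda prots: any(p in accepted_proteins for p in prots))
    return psms.loc[keep]


def entrapment_rate(
    final_psms: pd.DataFrame,
    protein_species: dict[str, str | None],
    entrapment_tag: str,
) -> tuple[float, pd.DataFrame]:
    """Fraction of glyco-group PSMs mapping *only* to entrapment proteins.

    Mixed-provenance PSMs (target + entrapment proteins) do not count."""
    if entrapment_tag not in set(protein_species.values()):
        raise ValueError(f"entrapment tag {entrapment_tag!r} absent from database")
    glyco = final_psms[final_psms["group"] == GROUP_GLYCO]
    if glyco.empty:
        return 0.0, glyco
    only_entrap = glyco["proteins"].map(
        lambda prots: all(protein_species.get(p) == entrapment_tag for p in prots))
    offenders = glyco.loc[only_entrap]
    return len(offenders) / len(glyco), offenders


@dataclass
class MixtureModel:
    """Semi-parametric two-component score model.

    Negative density is a kernel estimate anchored on decoy scores; the
    positive component is a Gaussian fitted by EM on target scores.
    """

    pi: float
    mu: float
    sigma: float
    neg_density: Callable[[np.ndarray], np.ndarray]
    loglik_trace: list[float]
    _grid: np.ndarray
    _posterior_grid: np.ndarray

    def posterior(self, scores) -> np.ndarray:
        """P(correct | score), clipped to [0,1] and monotone in score."""
        s = np.asarray(scores, dtype=np.float64)
        out = np.interp(s, self._grid, self._posterior_grid)
        return float(out) if s.ndim == 0 else out


def fit_score_mixture(
    target_scores: Sequence[float],
    decoy_scores: Sequence[float],
    max_iter: int = 200,
    tol: float = 1e-8,
) -> MixtureModel:
    """EM fit of pi * N(mu, sigma) + (1-pi) * KDE(decoys) to target scores."""
    t = np.asarray(target_scores, dtype=np.float64)
    d = np.asarray(decoy_scores, dtype=np.float64)
    if len(t) < 100 or len(d) < 100:
        raise ValueError("need at least 100 scores per class")
    if np.ptp(t) == 0 or np.ptp(d) == 0:
        raise ValueError(
            "degenerate (all-equal) scores; fall back to raw tdc_qvalues")
    kde = gaussian_kde(d, bw_method="silverman")
    f_neg = np.maximum(kde(t), 1e-300)

    pi = 0.5
    mu = float(np.percentile(t, 75))
    sigma = max(float(np.std(t)) / 2, 1e-3)
    trace: list[float] = []
    for _ in range(max_iter):
        f_pos = np.exp(-0.5 * ((t - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
        num = pi * np.maximum(f_pos, 1e-300)
        den = num + (1 - pi) * f_neg
        ll = float(np.sum(np.log(den)))
        trace.append(ll)
        resp = num / den
        w = resp.sum()
        pi = float(w / len(t))
        pi = min(max(pi, 1e-6), 1 - 1e-6)
        mu = float((resp * t).sum() / max(w, 1e-12))
        sigma = max(math.sqrt(float((resp * (t - mu) ** 2).sum() / max(w, 1e-12))), 1e-3)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-2]):
            break

    grid = np.linspace(min(t.min(), d.min()) - 1, max(t.max(), d.max()) + 1, 2001)
    f_pos_g = np.exp(-0.5 * ((grid - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    f_neg_g = np.maximum(kde(grid), 1e-300)
    post = pi * f_pos_g / (pi * f_pos_g + (1 - pi) * f_neg_g)
    post = np.clip(np.maximum.accumulate(post), 0.0, 1.0)
    return MixtureModel(pi=pi, mu=mu, sigma=sigma, neg_density=kde,
                        loglik_trace=trace, _grid=grid, _posterior_grid=post)
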