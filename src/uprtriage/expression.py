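"""Arm-selective transcriptional scoring and classification.

The central quantity is the reference-normalized induction of a gene: the
log fold change under a compound divided by the log fold change under the
global-stressor reference condition, times 100.  Genesets (one per UPR arm
plus off-pathway controls) are scored by the central tendency of their
genes' normalized inductions, restricted to genes the reference itself
induces more than ``min_fold`` (default 1.5, strict).  Profiles are
classified by a transparent rule — one-way ANOVA gate plus two one-sided
pairwise comparisons plus activity floors — because the published analysis
separated "global" from "preferential" by clustering and inspection, which
is not reproducible as a decision procedure.

Logs are taken in the natural base internally; the normalized induction is
base-invariant (log_b(a)/log_b(c) is independent of b).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import cluster, stats

__all__ = [
    "GenesetScore",
    "UPRProfileCall",
    "ClassifierConfig",
    "rpkm",
    "benjamini_hochberg",
    "differential_expression",
    "reference_filter",
    "tg_normalized_induction",
    "geneset_score",
    "classify_upr_profile",
    "cluster_profiles",
]


def rpkm(counts, gene_lengths_bp, library_size: float):
    """Reads per kilobase of transcript per million mapped reads."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths_bp, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    out = counts / ((lengths / 1e3) * (library_size / 1e6))
    return out if out.ndim else float(out)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def differential_expression(group_a: pd.DataFrame, group_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene two-sample t-test between replicate groups, BH-corrected.

    Parameters
    ----------
    group_a, group_b
        Genes x replicates frames on a shared gene index, positive linear
        expression values.  log2 fold change is mean(log2 a) - mean(log2 b).

    Notes
    -----
    Genes with zero variance in both groups and equal means get p = 1 by
    convention (no evidence of change, rather than NaN).
    """
    if not group_a.index.equals(group_b.index):
        raise ValueError("groups must share a gene index")
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    a = group_a.to_numpy(float)
    b = group_b.to_numpy(float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("expression values must be positive")

    log2fc = np.log2(a).mean(axis=1) - np.log2(b).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    p = np.where(degenerate & (a.mean(axis=1) == b.mean(axis=1)), 1.0, p)
    p = np.where(degenerate & (a.mean(axis=1) != b.mean(axis=1)), 0.0, p)
    return pd.DataFrame(
        {"log2_fc": log2fc, "p_value": p, "p_adjusted": benjamini_hochberg(p)},
        index=group_a.index,
    )


def reference_filter(
    table: pd.DataFrame, geneset: list[str], *, reference: str, min_fold: float = 1.5
) -> list[str]:
    """Genes of ``geneset`` whose reference-condition induction is strictly
    above ``min_fold`` (linear scale)."""
    if reference not in table.columns:
        raise ValueError(f"reference condition {reference!r} not in table")
    present = [g for g in geneset if g in table.index]
    ref = table.loc[present, reference].to_numpy(float)
    return [g for g, f in zip(present, ref) if f > min_fold]


def tg_normalized_induction(gene_fc_compound, gene_fc_reference):
    """Percent-of-reference induction on the log scale.

    ``100 * ln(fc_compound) / ln(fc_reference)``; may exceed 100 (stronger
    than reference) or go negative (repression).  Requires a reference fold
    change > 1 — callers should apply :func:`reference_filter` first.
    """
    fc_c = np.asarray(gene_fc_compound, dtype=float)
    fc_r = np.asarray(gene_fc_reference, dtype=float)
    if np.any(fc_c <= 0):
        raise ValueError("compound fold changes must be positive (linear scale)")
    if np.any(fc_r <= 1):
        raise ValueError("reference fold changes must exceed 1; filter genes first")
    out = 100.0 * np.log(fc_c) / np.log(fc_r)
    return out if out.ndim else float(out)


@dataclass
class GenesetScore:
    """Per-geneset activation score for one compound/condition."""

    condition: str
    geneset: str
    gene_ids: list[str]
    values: np.ndarray  # per-gene % of reference
    usable: bool = True

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def median(self) -> float:
        return float(np.median(self.values)) if self.usable else float("nan")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.usable else float("nan")


def geneset_score(
    table: pd.DataFrame,
    geneset: list[str],
    condition: str,
    *,
    reference: str,
    geneset_name: str = "",
    min_fold: float = 1.5,
    min_genes: int = 3,
) -> GenesetScore:
    """Score one geneset for one condition against the reference.

    Applies the reference filter, normalizes each retained gene's induction
    to the reference on the log scale, and retains the full per-gene
    distribution (median and mean summaries are derived properties).  Scores
    with fewer than ``min_genes`` retained genes are flagged unusable.
    """
    retained = reference_filter(table, geneset, reference=reference, min_fold=min_fold)
    if len(retained) < min_genes:
        return GenesetScore(condition, geneset_name, retained, np.array([]), usable=False)
    values = tg_normalized_induction(
        table.loc[retained, condition].to_numpy(float),
        table.loc[retained, reference].to_numpy(float),
    )
    return GenesetScore(condition, geneset_name, retained, np.asarray(values))


@dataclass
class ClassifierConfig:
    alpha: float = 0.05
    global_floor: float = 25.0   # all three arms at >= this % of reference
    activity_floor: float = 10.0  # below this on all arms -> weak/none
    summary: str = "median"

    def summarize(self, score: GenesetScore) -> float:
        return score.median if self.summary == "median" else score.mean


@dataclass
class UPRProfileCall:
    condition: str
    call: str  # 'preferential_ATF6' | 'global' | 'weak_none'
    anova_p: float
    pairwise_p: dict[str, float] = field(default_factory=dict)
    summaries: dict[str, float] = field(default_factory=dict)
    note: str = ""


def classify_upr_profile(
    atf6: GenesetScore,
    xbp1s: GenesetScore,
    perk: GenesetScore,
    config: ClassifierConfig | None = None,
) -> UPRProfileCall:
    """Classify a compound's UPR profile from its three arm scores.

    Decision rule (every threshold configurable):

    1. ``preferential_ATF6`` — one-way ANOVA across the three per-gene
       distributions significant at ``alpha``, both one-sided t-tests
       (ATF6 > XBP1s, ATF6 > PERK) significant at ``alpha``, and the ATF6
       summary at or above ``activity_floor``.
    2. ``global`` — all three summaries at or above ``global_floor`` and
       rule 1 not met.
    3. ``weak_none`` — everything else (including degenerate inputs).
    """
    cfg = config or ClassifierConfig()
    scores = {"ATF6": atf6, "XBP1s": xbp1s, "PERK": perk}
    for name, s in scores.items():
        if s.usable and s.n_genes < 2:
            raise ValueError(f"{name} score needs >= 2 genes")
    condition = atf6.condition
    if not all(s.usable for s in scores.values()):
        return UPRProfileCall(condition, "weak_none", float("nan"),
                              note="unusable geneset score (too few retained genes)")

    summaries = {k: cfg.summarize(s) for k, s in scores.items()}
    groups = [s.values for s in scores.values()]
    if all(np.ptp(g) == 0 for g in groups) and len({float(g[0]) for g in groups}) == 1:
        # identical degenerate distributions: no separation is testable, so
        # fall back to the floor rules (the reference scored against itself
        # lands here at 100% and must read as global, not weak).
        call = "global" if all(v >= cfg.global_floor for v in summaries.values()) else "weak_none"
        return UPRProfileCall(condition, call, float("nan"),
                              summaries=summaries, note="degenerate identical scores")

    anova_p = float(stats.f_oneway(*groups).pvalue)
    pairwise = {
        "ATF6_vs_XBP1s": float(
            stats.ttest_ind(atf6.values, xbp1s.values, alternative="greater").pvalue
        ),
        "ATF6_vs_PERK": float(
            stats.ttest_ind(atf6.values, perk.values, alternative="greater").pvalue
        ),
    }
    preferential = (
        anova_p < cfg.alpha
        and all(p < cfg.alpha for p in pairwise.values())
        and summaries["ATF6"] >= cfg.activity_floor
    )
    if preferential:
        call = "preferential_ATF6"
    elif all(v >= cfg.global_floor for v in summaries.values()):
        call = "global"
    else:
        call = "weak_none"
    return UPRProfileCall(condition, call, anova_p, pairwise, summaries)


def cluster_profiles(
    log2_matrix: pd.DataFrame, *, n_clusters: int | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Hierarchically cluster compound profiles (rows) by expression.

    Ward's method on Euclidean distances, matching standard practice for
    log2-transformed expression panels.  Ties are broken by input order
    (scipy's deterministic behaviour); permuting rows preserves the multiset
    of merge heights but may relabel clusters.

    Returns the scipy linkage matrix and, when ``n_clusters`` is given, flat
    cluster labels from cutting the dendrogram.
    """
    x = log2_matrix.to_numpy(float)
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values; impute before clustering")
    z = cluster.hierarchy.ward(x)
    labels = None
    if n_clusters is not None:
        labels = cluster.hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    return z, labels


def score_conditions(
    table: pd.DataFrame,
    genesets: pd.DataFrame,
    *,
    reference: str,
    conditions: list[str] | None = None,
    classifier: ClassifierConfig | None = None,
    min_fold: float = 1.5,
    min_genes: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score and classify every condition of an expression table.

    Convenience wrapper around :func:`geneset_score` and
    :func:`classify_upr_profile` over the three UPR arm genesets.

    Returns (scores, calls) frames; ``scores`` has one row per
    condition x geneset with median/mean/n columns, ``calls`` one row per
    condition with the profile call and test p-values.
    """
    arm_sets = {
        name: genesets.loc[genesets["geneset"] == name, "gene_id"].tolist()
        for name in ("ATF6", "XBP1s", "PERK")
    }
    for name, genes in arm_sets.items():
        if not genes:
            raise ValueError(f"geneset catalog has no {name} genes")
    if conditions is None:
        conditions = [c for c in table.columns if c != reference]

    score_rows, call_rows = [], []
    for cond in conditions:
        scores = {
            name: geneset_score(
                table, genes, cond, reference=reference, geneset_name=name,
                min_fold=min_fold, min_genes=min_genes,
            )
            for name, genes in arm_sets.items()
        }
        for name, s in scores.items():
            score_rows.append(
                dict(condition=cond, geneset=name, median=s.median, mean=s.mean,
                     n_genes=s.n_genes, usable=s.usable)
            )
        call = classify_upr_profile(
            scores["ATF6"], scores["XBP1s"], scores["PERK"], classifier
        )
        call_rows.append(
            dict(condition=cond, call=call.call, anova_p=call.anova_p,
                 p_atf6_vs_xbp1s=call.pairwise_p.get("ATF6_vs_XBP1s", float("nan")),
                 p_atf6_vs_perk=call.pairwise_p.get("ATF6_vs_PERK", float("nan")),
                 atf6_score=call.summaries.get("ATF6", float("nan")),
                 xbp1s_score=call.summaries.get("XBP1s", float("nan")),
                 perk_score=call.summaries.get("PERK", float("nan")),
                 note=call.note)
        )
    return pd.DataFrame(score_rows), pd.DataFrame(call_rows)
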