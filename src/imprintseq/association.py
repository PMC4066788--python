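"""Genomic-feature association tests for imprinted genes.

Transposable-element proximity (overall and per family, Fisher exact on
presence/absence within 4-kb flanks), imprinted-gene mini-cluster
testing by permutation of the informative gene set, and the shared
two-sided Fisher machinery (probability-mass rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnrichmentResult:
    contrast: str
    table: list
    p_value: float
    odds_ratio: float


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test by the probability-mass rule.

    P is the sum of hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed one.
    Returns (p_two_sided, cross-product odds ratio); a zero margin
    gives P = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0, np.nan
    res = stats.fisher_exact(t, alternative="two-sided")
    return float(res.pvalue), float(res.statistic)


def te_flank_presence(
    genes: pd.DataFrame,
    tes: pd.DataFrame,
    flank: int = 4000,
    exclude_body: bool = False,
) -> pd.DataFrame:
    """Per-gene TE presence and per-family counts within the flank window.

    A TE counts for a gene when it overlaps [gene_start - flank,
    gene_end + flank) (half-open); with ``exclude_body`` TEs overlapping
    only the gene body are ignored.
    """
    families = sorted(tes["family"].unique())
    rows = []
    tes_by_scaffold = {s: d for s, d in tes.groupby("scaffold")}
    for g in genes.itertuples():
        counts = dict.fromkeys(families, 0)
        d = tes_by_scaffold.get(g.scaffold)
        if d is not None:
            hit = d[(d["end"] > g.start - flank) & (d["start"] < g.end + flank)]
            if exclude_body:
                in_flank = (hit["start"] < g.start) | (hit["end"] > g.end)
                hit = hit[in_flank]
            for fam, n in hit["family"].value_counts().items():
                counts[fam] = int(n)
        total = sum(counts.values())
        rows.append({"gene_id": g.gene_id, "n_te": total, "has_te": total > 0, **counts})
    return pd.DataFrame(rows)


def te_enrichment(
    imprinted_genes: pd.DataFrame,
    background_genes: pd.DataFrame,
    tes: pd.DataFrame,
    flank: int = 4000,
    per_family: bool = True,
) -> pd.DataFrame:
    """Fisher enrichment of TE presence near imprinted vs background genes.

    Background should be the non-imprinted genes informative in both
    crosses, not the whole annotation.  One overall presence/absence
    test plus, optionally, one per family; per-family P-values are
    reported raw and Benjamini-Hochberg adjusted.
    """
    imp = te_flank_presence(imprinted_genes, tes, flank=flank)
    bg = te_flank_presence(background_genes, tes, flank=flank)
    results = []

    def _one(contrast, imp_has, bg_has):
        a, b = int(imp_has.sum()), int((~imp_has).sum())
        c, d = int(bg_has.sum()), int((~bg_has).sum())
        p, orr = fisher_exact_2x2([[a, b], [c, d]])
        results.append(
            {
                "contrast": contrast,
                "imprinted_with": a,
                "imprinted_without": b,
                "background_with": c,
                "background_without": d,
                "p_value": p,
                "odds_ratio": orr,
            }
        )

    if len(imp) and len(bg):
        _one("any_TE", imp["has_te"], bg["has_te"])
        if per_family:
            for fam in sorted(tes["family"].unique()):
                if fam in imp.columns and (imp[fam].sum() + bg[fam].sum()) > 0:
                    _one(fam, imp[fam] > 0, bg[fam] > 0)
    out = pd.DataFrame(
        results,
        columns=[
            "contrast", "imprinted_with", "imprinted_without",
            "background_with", "background_without", "p_value", "odds_ratio",
        ],
    )
    if len(out) > 1:
        fam_mask = out["contrast"] != "any_TE"
        adj = np.full(len(out), np.nan)
        adj[fam_mask.to_numpy()] = _bh_adjust(out.loc[fam_mask, "p_value"].to_numpy())
        out["p_adjusted"] = adj
    else:
        out["p_adjusted"] = np.nan
    return out


def _bh_adjust(ps: np.ndarray) -> np.ndarray:
    n = len(ps)
    order = np.argsort(ps)
    adj = ps[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def cluster_test(
    imprinted_genes: pd.DataFrame,
    informative_genes: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
):
    """Permutation test for physical clustering of imprinted genes.

    The statistic is the mean distance between consecutive imprinted
    genes along each scaffold (gene starts, scaffolds with fewer than
    two imprinted genes contribute nothing).  The null draws the same
    number of genes uniformly without replacement from the informative
    set ``n_perm`` times; P = (1 + #{null <= observed}) / (n_perm + 1).
    Also reports mini-clusters: runs of two or more imprinted genes
    adjacent in the informative gene order with no intervening
    informative gene.

    Returns a dict with observed_mean_distance, p_value, n_perm and
    mini_clusters (list of gene-id tuples).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    info = informative_genes.sort_values(["scaffold", "start"]).reset_index(drop=True)
    imp_ids = set(imprinted_genes["gene_id"])
    is_imp = info["gene_id"].isin(imp_ids).to_numpy()
    n_imp = int(is_imp.sum())

    def _stat(mask: np.ndarray) -> float:
        dists = []
        for _, d in info[mask].groupby("scaffold"):
            starts = d["start"].to_numpy()
            if len(starts) >= 2:
                dists.extend(np.diff(starts))
        return float(np.mean(dists)) if dists else np.nan

    observed = _stat(is_imp)
    if np.isnan(observed):
        raise ValueError("need at least two imprinted genes on some scaffold")
    rng = np.random.default_rng(seed)
    hits = 0
    n = len(info)
    for _ in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_imp, replace=False)] = True
        s = _stat(mask)
        if not np.isnan(s) and s <= observed:
            hits += 1
    p = (1 + hits) / (n_perm + 1)

    clusters = []
    run = []
    prev_scaffold = None
    for row in info.itertuples():
        if is_imp[row.Index] and row.scaffold == prev_scaffold and run:
            run.append(row.gene_id)
        elif is_imp[row.Index]:
            if len(run) >= 2:
                clusters.append(tuple(run))
            run = [row.gene_id]
        else:
            if len(run) >= 2:
                clusters.append(tuple(run))
            run = []
        prev_scaffold = row.scaffold
    if len(run) >= 2:
        clusters.append(tuple(run))
    return {
        "observed_mean_distance": observed,
        "p_value": p,
        "n_perm": n_perm,
        "mini_clusters": clusters,
    }
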