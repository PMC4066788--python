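"""Parent-of-origin tests for triploid endosperm allele counts.

The null model is dosage-proportional expression in a 2-maternal :
1-paternal tissue: at an unbiased locus each read is maternal with
probability 2/3.  For each locus a one-sided exact binomial P-value is
computed in each reciprocal cross; the two are combined via the
second-order statistic, P = max(p1, p2)^2, which is uniform under the
null.  Joint P-values for maternal and paternal bias are ranked
separately and converted to a rank FDR (P * n / i).  Loci pass when the
FDR is at or below the cutoff AND at least 90% of reads come from the
same parent in BOTH crosses; the second filter guards against maternal
RNA contamination mimicking imprinting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def binom_onesided(k: int, n: int, p0: float, direction: str = "greater") -> float:
    """Exact one-sided binomial tail probability (no approximation)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if direction == "greater":
        return float(stats.binom.sf(k - 1, n, p0))
    if direction == "less":
        return float(stats.binom.cdf(k, n, p0))
    raise ValueError(f"unknown direction: {direction!r}")


def joint_p(p1: float, p2: float) -> float:
    """Joint reciprocal P-value: square of the larger of the two.

    For independent uniforms this is the CDF-transformed second-order
    statistic and is itself uniform on [0, 1].
    """
    for p in (p1, p2):
        if not 0 <= p <= 1:
            raise ValueError("P-values must lie in [0, 1]")
    return max(p1, p2) ** 2


def fdr_rank(joint_ps, monotone: bool = False) -> np.ndarray:
    """Rank-based FDR: sort ascending, FDR_i = P_(i) * n / i.

    Values are mapped back to the input order.  With ``monotone`` a
    step-up pass (cumulative minimum from the largest P downward) makes
    the FDR non-increasing in significance, i.e. the standard
    Benjamini-Hochberg adjusted value; it is off by default.
    """
    ps = np.asarray(joint_ps, dtype=float)
    if ps.size == 0:
        return ps.copy()
    if ps.min() < 0 or ps.max() > 1:
        raise ValueError("P-values must lie in [0, 1]")
    n = ps.size
    order = np.argsort(ps, kind="stable")
    ranks = np.arange(1, n + 1)
    fdr_sorted = ps[order] * n / ranks
    if monotone:
        fdr_sorted = np.minimum.accumulate(fdr_sorted[::-1])[::-1]
    out = np.empty(n, dtype=float)
    out[order] = fdr_sorted
    return out


def _required_columns(counts: pd.DataFrame):
    needed = {"mat_AxB", "pat_AxB", "mat_BxA", "pat_BxA"}
    missing = needed - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")


def classify_loci(
    counts: pd.DataFrame,
    fdr_threshold: float = 0.05,
    uniparental_fraction: float = 0.90,
    null_maternal: float = 2 / 3,
    monotone_fdr: bool = False,
) -> pd.DataFrame:
    """Per-locus imprinting test and MEG/PEG/biallelic classification.

    Input columns: mat_AxB, pat_AxB, mat_BxA, pat_BxA (one row per
    locus informative in both crosses).  Loci with zero reads in either
    cross are excluded.  Maternal and paternal joint P-value lists are
    FDR-ranked separately.  A locus is called MEG when its maternal FDR
    passes the threshold and its maternal fraction reaches
    ``uniparental_fraction`` in both crosses; PEG symmetric.
    """
    _required_columns(counts)
    df = counts.copy()
    n_axb = df["mat_AxB"] + df["pat_AxB"]
    n_bxa = df["mat_BxA"] + df["pat_BxA"]
    keep = (n_axb > 0) & (n_bxa > 0)
    if (~keep).any():
        logger.info("excluding %d loci with zero reads in a cross", int((~keep).sum()))
    df = df[keep].reset_index(drop=True)
    n_axb = np.asarray(n_axb[keep])
    n_bxa = np.asarray(n_bxa[keep])
    mat_axb = df["mat_AxB"].to_numpy()
    mat_bxa = df["mat_BxA"].to_numpy()
    p0 = null_maternal

    # maternal bias: more maternal reads than the dosage null predicts
    p1_mat = stats.binom.sf(mat_axb - 1, n_axb, p0)
    p2_mat = stats.binom.sf(mat_bxa - 1, n_bxa, p0)
    # paternal bias: more paternal reads than 1 - null
    p1_pat = stats.binom.sf(n_axb - mat_axb - 1, n_axb, 1 - p0)
    p2_pat = stats.binom.sf(n_bxa - mat_bxa - 1, n_bxa, 1 - p0)

    df["p1_mat"], df["p2_mat"] = p1_mat, p2_mat
    df["p1_pat"], df["p2_pat"] = p1_pat, p2_pat
    df["joint_P_mat"] = np.maximum(p1_mat, p2_mat) ** 2
    df["joint_P_pat"] = np.maximum(p1_pat, p2_pat) ** 2
    df["fdr_mat"] = fdr_rank(df["joint_P_mat"], monotone=monotone_fdr)
    df["fdr_pat"] = fdr_rank(df["joint_P_pat"], monotone=monotone_fdr)
    df["mat_frac_AxB"] = mat_axb / n_axb
    df["mat_frac_BxA"] = mat_bxa / n_bxa
    df["n_AxB"] = n_axb
    df["n_BxA"] = n_bxa

    meg = (
        (df["fdr_mat"] <= fdr_threshold)
        & (df["mat_frac_AxB"] >= uniparental_fraction)
        & (df["mat_frac_BxA"] >= uniparental_fraction)
    )
    peg = (
        (df["fdr_pat"] <= fdr_threshold)
        & (1 - df["mat_frac_AxB"] >= uniparental_fraction)
        & (1 - df["mat_frac_BxA"] >= uniparental_fraction)
    )
    df["class"] = np.select([meg, peg], ["MEG", "PEG"], default="biallelic")

    complete_meg = meg & (df["pat_AxB"] == 0) & (df["pat_BxA"] == 0)
    complete_peg = peg & (df["mat_AxB"] == 0) & (df["mat_BxA"] == 0)
    df["completeness"] = np.select(
        [complete_meg | complete_peg, meg | peg], ["complete", "partial"], default=""
    )
    return df


def detect_accession_bias(
    counts: pd.DataFrame,
    bias_fraction: float = 0.90,
    fdr_threshold: float = 0.05,
    null_maternal: float = 2 / 3,
) -> pd.DataFrame:
    """Loci biased toward one parental LINE in both cross directions.

    Unlike imprinting, accession bias follows the line, not the parent
    of origin: line-X read fraction must exceed ``bias_fraction`` in
    both crosses and the binomial deviation from the dosage null (2/3
    when X is the mother of that cross, 1/3 otherwise) must be
    FDR-significant in both crosses.  Adds a ``biased_line`` column
    ('p1', 'p2' or '').
    """
    _required_columns(counts)
    df = counts.copy()
    n_axb = (df["mat_AxB"] + df["pat_AxB"]).to_numpy()
    n_bxa = (df["mat_BxA"] + df["pat_BxA"]).to_numpy()
    # line p1 is maternal in AxB, paternal in BxA
    p1_axb = df["mat_AxB"].to_numpy()
    p1_bxa = df["pat_BxA"].to_numpy()
    p0 = null_maternal
    calls = np.full(len(df), "", dtype=object)
    for line, x_axb, x_bxa, null_axb, null_bxa in (
        ("p1", p1_axb, p1_bxa, p0, 1 - p0),
        ("p2", n_axb - p1_axb, n_bxa - p1_bxa, 1 - p0, p0),
    ):
        with np.errstate(invalid="ignore"):
            frac_axb = x_axb / n_axb
            frac_bxa = x_bxa / n_bxa
        pa = stats.binom.sf(x_axb - 1, n_axb, null_axb)
        pb = stats.binom.sf(x_bxa - 1, n_bxa, null_bxa)
        fa = fdr_rank(pa)
        fb = fdr_rank(pb)
        hit = (
            (frac_axb > bias_fraction)
            & (frac_bxa > bias_fraction)
            & (fa <= fdr_threshold)
            & (fb <= fdr_threshold)
        )
        calls[hit] = line
    df["biased_line"] = calls
    return df


def aggregate_to_genes(loci: pd.DataFrame, genes: pd.DataFrame):
    """Roll per-locus imprinting calls up to gene level.

    ``loci`` is a classify_loci result; ``genes`` needs gene_id,
    scaffold, start, end, strand (0-based half-open).  A gene's class is
    the unanimous class of its significant loci; genes whose loci
    disagree are flagged 'discordant' and excluded from MEG/PEG totals.
    Imprinted loci outside every gene body are reported per locus as
    intergenic (class ``intergenic_MEG_like`` / ``intergenic_PEG_like``)
    with the distance and side of the nearest gene.

    Returns ``(gene_calls, intergenic_loci)``.
    """
    sig = loci[loci["class"].isin(["MEG", "PEG"])].copy()
    by_scaffold = {s: d.sort_values("start") for s, d in genes.groupby("scaffold")}
    gene_hit = []
    for row in sig.itertuples():
        g = ""
        d = by_scaffold.get(row.scaffold)
        if d is not None:
            i = np.searchsorted(d["start"].to_numpy(), row.pos, side="right") - 1
            if i >= 0 and row.pos < d["end"].iloc[i]:
                g = d["gene_id"].iloc[i]
        gene_hit.append(g)
    sig["gene_id"] = gene_hit

    rows = []
    genic = sig[sig.gene_id != ""]
    for gene_id, d in genic.groupby("gene_id"):
        classes = set(d["class"])
        call = d["class"].iloc[0] if len(classes) == 1 else "discordant"
        rows.append(
            {
                "gene_id": gene_id,
                "class": call,
                "location": "genic",
                "supporting_loci": len(d),
                "mat_AxB": int(d["mat_AxB"].sum()),
                "pat_AxB": int(d["pat_AxB"].sum()),
                "mat_BxA": int(d["mat_BxA"].sum()),
                "pat_BxA": int(d["pat_BxA"].sum()),
            }
        )
    gene_calls = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "class", "location", "supporting_loci",
            "mat_AxB", "pat_AxB", "mat_BxA", "pat_BxA",
        ],
    )

    inter_rows = []
    for row in sig[sig.gene_id == ""].to_dict("records"):
        d = by_scaffold.get(row["scaffold"])
        nearest, dist, side = "", np.nan, ""
        if d is not None and len(d):
            starts = d["start"].to_numpy()
            ends = d["end"].to_numpy()
            pos = row["pos"]
            dists = np.where(pos < starts, starts - pos, pos - ends + 1)
            i = int(np.argmin(dists))
            nearest = d["gene_id"].iloc[i]
            dist = int(dists[i])
            strand = d["strand"].iloc[i]
            before = pos < starts[i]
            side = "upstream" if before == (strand == "+") else "downstream"
        inter_rows.append(
            {
                "scaffold": row["scaffold"],
                "pos": row["pos"],
                "class": f"intergenic_{row['class']}_like",
                "nearest_gene": nearest,
                "distance": dist,
                "side": side,
            }
        )
    intergenic = pd.DataFrame(
        inter_rows, columns=["scaffold", "pos", "class", "nearest_gene", "distance", "side"]
    )
    return gene_calls, intergenic


def scatter_export(loci: pd.DataFrame) -> pd.DataFrame:
    """log2 maternal-vs-paternal pooled counts for a dosage scatter plot."""
    return pd.DataFrame(
        {
            "scaffold": loci["scaffold"],
            "pos": loci["pos"],
            "log2_mat": np.log2(loci["mat_AxB"] + loci["mat_BxA"] + 1),
            "log2_pat": np.log2(loci["pat_AxB"] + loci["pat_BxA"] + 1),
            "class": loci.get("class", ""),
        }
    )


def write_results(path, loci: pd.DataFrame) -> None:
    out = loci.copy()
    out["pos_1based"] = out["pos"] + 1
    cols = [
        "scaffold", "pos_1based", "class", "completeness",
        "p1_mat", "p2_mat", "p1_pat", "p2_pat",
        "joint_P_mat", "joint_P_pat", "fdr_mat", "fdr_pat",
        "mat_frac_AxB", "mat_frac_BxA", "n_AxB", "n_BxA",
    ]
    out[[c for c in cols if c in out.columns]].to_csv(path, sep="\t", index=False)
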