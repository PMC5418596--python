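"""RPKM differential expression with Fisher's exact test.

Per-locus expression is quantified as reads per kilobase per million
mapped reads (RPKM).  Differential expression between mutant and WT is
assessed per replicate pair with a two-sided Fisher's exact test on the
2x2 table (locus reads vs rest-of-library reads in each genotype),
BH-adjusted across loci within the pair.  A locus is called up if
log2(mutant RPKM / WT RPKM) > 2 and FDR < 0.01 (down symmetrically with
< -2), and the final call requires the same call in every replicate pair.
A pseudocount (default one read, added to both genotypes before RPKM
conversion) protects the log2 ratio against zero denominators; it is never
used in the Fisher test.

The module also provides the genome-overview helpers: log2 expression
ratios in non-overlapping 100-kb windows, and a one-sample proportion
z-test for enrichment of a locus set in the pericentromeric-heterochromatin
compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import benjamini_hochberg, fisher_exact_two_sided, proportion_ztest_two_sided

__all__ = [
    "compute_rpkm",
    "de_test",
    "call_differential",
    "windowed_log2_track",
    "compartment_enrichment",
    "EnrichmentResult",
    "DifferentialExpression",
    "DifferentialExpressionResults",
]


def compute_rpkm(count, length_bp, total_mapped):
    """Reads per kilobase of locus per million mapped reads.

    RPKM = count / (length_bp / 1000) / (total_mapped / 1e6).  Vectorized.
    """
    count = np.asarray(count, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    total_mapped = np.asarray(total_mapped, dtype=float)
    if np.any(length_bp < 1):
        raise ValueError("locus length must be >= 1 bp")
    if np.any(total_mapped < 1):
        raise ValueError("total mapped reads must be >= 1")
    out = count / (length_bp / 1e3) / (total_mapped / 1e6)
    return float(out) if out.ndim == 0 else out


def de_test(count_mut: int, count_wt: int, total_mut: int, total_wt: int) -> float:
    """Two-sided Fisher's exact test of one locus against the rest of the
    library: table (count_mut, total_mut - count_mut; count_wt,
    total_wt - count_wt)."""
    if count_mut > total_mut or count_wt > total_wt:
        raise ValueError("locus count exceeds library total")
    return fisher_exact_two_sided(
        int(count_mut), int(total_mut) - int(count_mut),
        int(count_wt), int(total_wt) - int(count_wt),
    )


def call_differential(
    counts: pd.DataFrame,
    lengths: pd.Series,
    pairs,
    totals: pd.Series | None = None,
    log2_threshold: float = 2.0,
    fdr_max: float = 0.01,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-locus differential-expression calls with replicate intersection.

    Parameters
    ----------
    counts
        Loci x libraries integer read counts.
    lengths
        Locus lengths in bp (same index as ``counts``).
    pairs
        Sequence of (wt_column, mut_column) replicate pairs.
    totals
        Per-library total mapped reads; defaults to column sums.
    log2_threshold, fdr_max
        Both strict: up iff log2 ratio > threshold AND FDR < fdr_max.
    pseudocount
        Reads added to both genotypes before RPKM conversion, for the
        log2 ratio only.

    Returns a DataFrame with per-library RPKM, per-pair log2 ratio,
    p-value, FDR and call, and the ``final_call`` (identical in all pairs,
    else ``unchanged``).
    """
    if len(pairs) < 1:
        raise ValueError("at least one replicate pair is required")
    if totals is None:
        totals = counts.sum(axis=0)
    lengths = lengths.reindex(counts.index)
    out = pd.DataFrame(index=counts.index)
    for col in counts.columns:
        out[f"rpkm_{col}"] = compute_rpkm(counts[col], lengths, totals[col])

    calls = []
    for k, (wt_col, mut_col) in enumerate(pairs, start=1):
        cw = counts[wt_col].to_numpy(dtype=np.int64)
        cm = counts[mut_col].to_numpy(dtype=np.int64)
        tw, tm = int(totals[wt_col]), int(totals[mut_col])
        rpkm_wt = compute_rpkm(cw + pseudocount, lengths.to_numpy(), tw)
        rpkm_mut = compute_rpkm(cm + pseudocount, lengths.to_numpy(), tm)
        log2r = np.log2(rpkm_mut / rpkm_wt)
        pvals = np.array([de_test(m, w, tm, tw) for m, w in zip(cm, cw)])
        fdr = benjamini_hochberg(pvals)
        call = np.where(
            (log2r > log2_threshold) & (fdr < fdr_max), "up",
            np.where((log2r < -log2_threshold) & (fdr < fdr_max), "down", "unchanged"),
        )
        out[f"log2_pair{k}"] = log2r
        out[f"p_pair{k}"] = pvals
        out[f"fdr_pair{k}"] = fdr
        out[f"call_pair{k}"] = call
        calls.append(call)

    stacked = np.vstack(calls)
    agree = (stacked == stacked[0]).all(axis=0)
    out["final_call"] = np.where(agree, stacked[0], "unchanged")
    return out


def windowed_log2_track(
    loci: pd.DataFrame,
    rpkm_wt: pd.Series,
    rpkm_mut: pd.Series,
    chrom_sizes: dict,
    window_bp: int = 100_000,
) -> pd.DataFrame:
    """log2 ratio of mean RPKM in non-overlapping tiling windows.

    Windows tile each chromosome from position 1; a locus belongs to the
    window containing its midpoint.  Windows without loci, or with a zero
    mean in either genotype, get NaN.
    """
    loci = loci.copy()
    mid = (loci["start"] + loci["end"]) // 2
    rows = []
    for chrom, size in chrom_sizes.items():
        n_win = int(np.ceil(size / window_bp))
        sel = loci["chrom"] == chrom
        widx = ((mid[sel] - 1) // window_bp).to_numpy()
        mw = pd.Series(rpkm_wt[sel].to_numpy()).groupby(widx).mean()
        mm = pd.Series(rpkm_mut[sel].to_numpy()).groupby(widx).mean()
        for w in range(n_win):
            start = w * window_bp + 1
            end = min((w + 1) * window_bp, size)
            wt_mean = mw.get(w, np.nan)
            mut_mean = mm.get(w, np.nan)
            if not np.isfinite(wt_mean) or not np.isfinite(mut_mean) or wt_mean <= 0 or mut_mean <= 0:
                val = np.nan
            else:
                val = float(np.log2(mut_mean / wt_mean))
            rows.append((chrom, start, end, val))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "log2_ratio"])


@dataclass(frozen=True)
class EnrichmentResult:
    """Compartment-enrichment test outcome for a locus subset."""

    observed: int
    n: int
    background_observed: int
    background_n: int
    proportion: float
    background_proportion: float
    z_score: float
    p_value: float


def compartment_enrichment(
    subset,
    background,
    compartment: str = "pericentromeric_het",
) -> EnrichmentResult:
    """Test whether a locus subset is enriched in one genomic compartment.

    One-sample two-sided z-test of the subset's compartment proportion
    against the background proportion p0:
    z = (p_hat - p0) / sqrt(p0 (1 - p0) / n).
    """
    sub = _compartments(subset)
    bg = _compartments(background)
    n = len(sub)
    if n == 0:
        raise ValueError("subset is empty")
    obs = int((sub == compartment).sum())
    bg_obs = int((bg == compartment).sum())
    p0 = bg_obs / len(bg)
    z, p = proportion_ztest_two_sided(obs, n, p0)
    return EnrichmentResult(
        observed=obs, n=n, background_observed=bg_obs, background_n=len(bg),
        proportion=obs / n, background_proportion=p0, z_score=z, p_value=p,
    )


def _compartments(features) -> pd.Series:
    if isinstance(features, pd.DataFrame):
        return features["compartment"]
    if isinstance(features, pd.Series):
        return features
    return pd.Series([f.compartment for f in features])


class DifferentialExpression:
    """RNA-seq differential-expression model (Fisher exact on RPKM counts).

    Built from a loci x libraries count table, locus coordinates and a
    list of (WT, mutant) replicate-pair column names.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        loci: pd.DataFrame,
        pairs,
        *,
        totals: pd.Series | None = None,
        log2_threshold: float = 2.0,
        fdr_max: float = 0.01,
        pseudocount: float = 1.0,
    ):
        self.counts = counts
        self.loci = loci.reindex(counts.index)
        self.pairs = list(pairs)
        self.totals = counts.sum(axis=0) if totals is None else totals
        self.log2_threshold = log2_threshold
        self.fdr_max = fdr_max
        self.pseudocount = pseudocount

    @classmethod
    def from_count_table(cls, table: pd.DataFrame, pairs, **kwargs):
        """Build from a table carrying chrom/start/end plus count columns
        (the layout written by :func:`epidiff.io.write_count_table`)."""
        coord_cols = ["chrom", "start", "end"]
        loci = table[coord_cols].copy()
        counts = table.drop(columns=[c for c in coord_cols + ["compartment", "kind"]
                                     if c in table.columns])
        return cls(counts, loci, pairs, **kwargs)

    @property
    def lengths(self) -> pd.Series:
        return self.loci["end"] - self.loci["start"] + 1

    def fit(self) -> "DifferentialExpressionResults":
        table = call_differential(
            self.counts, self.lengths, self.pairs, self.totals,
            self.log2_threshold, self.fdr_max, self.pseudocount,
        )
        return DifferentialExpressionResults(self, table)


class DifferentialExpressionResults:
    """Fitted differential-expression results; ``table`` holds per-locus
    RPKM, per-pair statistics and the intersected final call."""

    def __init__(self, model: DifferentialExpression, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def upregulated(self) -> pd.Index:
        return self.table.index[self.table["final_call"] == "up"]

    @property
    def downregulated(self) -> pd.Index:
        return self.table.index[self.table["final_call"] == "down"]

    def windowed_log2(self, chrom_sizes: dict, window_bp: int = 100_000) -> pd.DataFrame:
        wt_cols = [f"rpkm_{w}" for w, _ in self.model.pairs]
        mut_cols = [f"rpkm_{m}" for _, m in self.model.pairs]
        loci = self.model.loci
        return windowed_log2_track(
            loci,
            self.table[wt_cols].mean(axis=1),
            self.table[mut_cols].mean(axis=1),
            chrom_sizes,
            window_bp,
        )

    def enrichment(self, features: pd.DataFrame, which: str = "up",
                   compartment: str = "pericentromeric_het") -> EnrichmentResult:
        ids = self.upregulated if which == "up" else self.downregulated
        feats = features.set_index("id") if "id" in features.columns else features
        return compartment_enrichment(
            feats.loc[feats.index.intersection(ids)], feats, compartment
        )

    def summary(self) -> str:
        n_up, n_down = len(self.upregulated), len(self.downregulated)
        lines = [
            "Differential expression summary",
            "=" * 40,
            f"loci tested: {len(self.table)}",
            f"replicate pairs: {len(self.model.pairs)}",
            f"up (all pairs): {n_up}",
            f"down (all pairs): {n_down}",
            f"unchanged: {len(self.table) - n_up - n_down}",
        ]
        return "\n".join(lines)
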