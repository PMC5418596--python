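"""Metaprofiles around genomic features and small-RNA normalization.

Methylation metaprofiles align stranded features at their 5' or 3' end and
average the methylation level in fixed-width bins (default 100 bp) from
3 kb upstream to 3 kb downstream; upstream of a minus-strand feature is
genomically downstream.  Bin values default to the coverage-weighted rate
(sum of methylated reads over sum of total reads across all contributing
cytosines), which is robust to low-coverage cytosines; per-cytosine-rate
averaging is available as an option.

Small-RNA counts are normalized to reads per million 18-26-nt mapping
reads within each library.  TE-scaled siRNA profiles use 1-nt flank bins
and a fixed number of proportional body bins, so TEs of any length share
one axis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CYTOSINE_CONTEXTS

__all__ = [
    "methylation_metaprofile",
    "normalize_srna",
    "scaled_te_profile",
    "plot_profile",
]


def _feature_rows(features):
    if isinstance(features, pd.DataFrame):
        return list(features.itertuples())
    return features


def methylation_metaprofile(
    cytosines: pd.DataFrame,
    features,
    flank: int = 3000,
    bin_width: int = 100,
    anchor: str = "5prime",
    contexts=CYTOSINE_CONTEXTS,
    weighted: bool = True,
) -> pd.DataFrame:
    """Average methylation around feature ends in fixed-width bins.

    Parameters
    ----------
    cytosines
        Per-cytosine table (chrom, pos, context, meth, unmeth).
    features
        Stranded features (DataFrame or GenomicFeature sequence).
    flank
        bp covered on each side of the anchor (must be divisible by
        ``bin_width``).
    anchor
        ``5prime`` or ``3prime`` feature end.
    weighted
        Coverage-weighted bin rate (default) versus the mean of
        per-cytosine rates.

    Returns a DataFrame with columns context, bin (index over
    2*flank/bin_width bins), offset_start (bp relative to the anchor),
    value and n_cytosines; bins without covered cytosines hold NaN.
    """
    if anchor not in ("5prime", "3prime"):
        raise ValueError(f"unknown anchor {anchor!r}")
    if flank % bin_width != 0:
        raise ValueError("flank must be divisible by bin_width")
    n_bins = 2 * flank // bin_width

    by_chrom = {
        chrom: sub.sort_values("pos", kind="mergesort")
        for chrom, sub in cytosines.groupby("chrom")
    }
    sum_m = {ctx: np.zeros(n_bins) for ctx in contexts}
    sum_t = {ctx: np.zeros(n_bins) for ctx in contexts}
    sum_r = {ctx: np.zeros(n_bins) for ctx in contexts}
    n_cov = {ctx: np.zeros(n_bins, dtype=np.int64) for ctx in contexts}

    for feat in _feature_rows(features):
        if feat.chrom not in by_chrom:
            continue
        minus = feat.strand == "-"
        if anchor == "5prime":
            anchor_pos = feat.end if minus else feat.start
        else:
            anchor_pos = feat.start if minus else feat.end
        sub = by_chrom[feat.chrom]
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [anchor_pos - flank, anchor_pos + flank + 1])
        if hi <= lo:
            continue
        window = sub.iloc[lo:hi]
        offset = window["pos"].to_numpy() - anchor_pos
        if minus:
            offset = -offset
        bins = (offset + flank) // bin_width
        inside = (bins >= 0) & (bins < n_bins)
        meth = window["meth"].to_numpy(dtype=float)
        tot = meth + window["unmeth"].to_numpy(dtype=float)
        covered = inside & (tot > 0)
        for ctx in contexts:
            sel = covered & (window["context"].to_numpy() == ctx)
            if not sel.any():
                continue
            b = bins[sel].astype(np.int64)
            np.add.at(sum_m[ctx], b, meth[sel])
            np.add.at(sum_t[ctx], b, tot[sel])
            np.add.at(sum_r[ctx], b, meth[sel] / tot[sel])
            np.add.at(n_cov[ctx], b, 1)

    rows = []
    for ctx in contexts:
        for b in range(n_bins):
            if n_cov[ctx][b] == 0:
                value = np.nan
            elif weighted:
                value = sum_m[ctx][b] / sum_t[ctx][b]
            else:
                value = sum_r[ctx][b] / n_cov[ctx][b]
            rows.append((ctx, b, b * bin_width - flank, value, int(n_cov[ctx][b])))
    return pd.DataFrame(
        rows, columns=["context", "bin", "offset_start", "value", "n_cytosines"]
    )


def normalize_srna(counts, total_18_26: float):
    """Scale raw small-RNA counts to reads per million 18-26-nt mapping
    reads of the library."""
    if total_18_26 <= 0:
        raise ValueError("library has no 18-26-nt mapping reads")
    counts = np.asarray(counts, dtype=float)
    out = counts * 1e6 / float(total_18_26)
    return float(out) if out.ndim == 0 else out


def scaled_te_profile(
    coverage: dict,
    te_features,
    flank: int = 2000,
    body_bins: int = 2000,
) -> pd.DataFrame:
    """Length-scaled coverage metaprofile over TEs.

    ``coverage`` maps chromosome -> per-bp array (index 0 is position 1).
    Flanks use 1-nt bins; each body position j of a TE of length L maps to
    bin floor(j / L * body_bins), capped at body_bins - 1, so TEs shorter
    than ``body_bins`` leave some body bins uncovered (fractional
    mapping).  Orientation is strand-aware.  Per bin, each TE contributes
    the mean coverage of its positions mapping there; the profile value is
    the mean over contributing TEs.

    Returns a DataFrame with columns bin (0 .. 2*flank + body_bins - 1),
    region (upstream/body/downstream), value, n_te.
    """
    total_bins = 2 * flank + body_bins
    acc = np.zeros(total_bins)
    n_te = np.zeros(total_bins, dtype=np.int64)

    for feat in _feature_rows(te_features):
        if feat.chrom not in coverage:
            continue
        cov = coverage[feat.chrom]
        length = feat.end - feat.start + 1
        minus = feat.strand == "-"

        per_te = np.full(total_bins, np.nan)
        # upstream flank (1-nt bins), oriented 5'->3'
        up = _flank_values(cov, feat.start - flank, feat.start - 1)
        down = _flank_values(cov, feat.end + 1, feat.end + flank)
        if minus:
            up, down = down[::-1], up[::-1]
        per_te[:flank] = up
        per_te[flank + body_bins:] = down

        body = cov[feat.start - 1: feat.end].astype(float)
        if minus:
            body = body[::-1]
        j = np.arange(length)
        bins = np.minimum((j * body_bins) // length, body_bins - 1).astype(np.int64)
        sums = np.zeros(body_bins)
        cnts = np.zeros(body_bins)
        np.add.at(sums, bins, body)
        np.add.at(cnts, bins, 1)
        covered = cnts > 0
        per_te[flank:flank + body_bins][covered] = sums[covered] / cnts[covered]

        have = np.isfinite(per_te)
        acc[have] += per_te[have]
        n_te[have] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(n_te > 0, acc / np.where(n_te > 0, n_te, 1), np.nan)
    region = np.array(
        ["upstream"] * flank + ["body"] * body_bins + ["downstream"] * flank
    )
    return pd.DataFrame(
        {"bin": np.arange(total_bins), "region": region, "value": value, "n_te": n_te}
    )


def _flank_values(cov: np.ndarray, start: int, end: int) -> np.ndarray:
    """Per-bp coverage over [start, end] (1-based); positions beyond the
    chromosome are NaN (flanks are never truncated, just undefined)."""
    out = np.full(end - start + 1, np.nan)
    lo = max(start, 1)
    hi = min(end, len(cov))
    if hi >= lo:
        out[lo - start: hi - start + 1] = cov[lo - 1: hi]
    return out


def plot_profile(profile: pd.DataFrame, x: str = "bin", y: str = "value",
                 hue: str | None = None, ax=None):
    """Minimal line-plot helper for profile tables."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if hue is not None:
        for key, sub in profile.groupby(hue):
            ax.plot(sub[x], sub[y], label=str(key))
        ax.legend()
    else:
        ax.plot(profile[x], profile[y])
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    return ax
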