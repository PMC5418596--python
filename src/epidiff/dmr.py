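"""Differential-methylation calling between two genotypes.

The procedure compares a mutant methylome with its wild-type (WT) control,
per cytosine sequence context (CG, CHG, CHH):

1. Within each sequencing library, the methylated and unmethylated read
   counts are smoothed independently along each (chromosome, context)
   cytosine track with an 11-point Savitzky–Golay quadratic filter, then
   the smoothed counts of a genotype's libraries are summed position-wise.
2. At every cytosine with non-zero smoothed coverage in both genotypes, a
   two-sided Fisher's exact test on the rounded smoothed counts identifies
   differentially methylated cytosines (DMCs): p <= 0.1 and an absolute
   smoothed-rate difference (mutant - WT) strictly above 0.1.  Positive
   differences are hyper-DMCs, negative ones hypo-DMCs.
3. Same-type DMCs are merged into candidate regions when consecutive DMCs
   lie within a context-specific distance (CG 160 bp, CHG 240 bp, CHH
   70 bp) and no opposite-type DMC falls strictly between them.
4. Each candidate region is re-tested: the smoothed counts are averaged
   over all context cytosines inside the region, rounded, and submitted to
   Fisher's exact test; p-values are BH-adjusted within each context.
5. Regions with >= 5 DMCs, length >= 50 bp, FDR <= 0.05 and an absolute
   region rate difference >= 0.40 (CG) / 0.20 (CHG, CHH) are reported as
   differentially methylated regions (DMRs).

`DifferentialMethylation` packages the pipeline statsmodels-style: build
the model from per-library cytosine tables, call :meth:`fit`, and inspect
the returned results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CYTOSINE_CONTEXTS
from .smoothing import SmoothingParams, savitzky_golay_smooth
from .stats import benjamini_hochberg, fisher_exact_two_sided, round_counts

__all__ = [
    "SmoothedTrack",
    "DmcParams",
    "MergeParams",
    "DmrFilterParams",
    "smooth_genotype",
    "call_dmcs",
    "merge_dmcs",
    "test_region",
    "filter_dmrs",
    "map_dmrs_to_features",
    "overlap_summary",
    "DifferentialMethylation",
    "DifferentialMethylationResults",
]

DMC_COLUMNS = ["chrom", "pos", "context", "type", "p_value", "rate_wt", "rate_mut", "diff"]
REGION_COLUMNS = [
    "chrom", "start", "end", "context", "type", "n_dmcs",
    "rate_wt", "rate_mut", "diff", "p_value",
]


@dataclass
class SmoothedTrack:
    """Genotype-level smoothed counts along one (chromosome, context) track.

    Positions are strictly increasing; ``meth``/``unmeth`` are the sums of
    the per-library smoothed counts (non-negative reals).
    """

    genotype: str
    chrom: str
    context: str
    pos: np.ndarray
    meth: np.ndarray
    unmeth: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.meth = np.asarray(self.meth, dtype=float)
        self.unmeth = np.asarray(self.unmeth, dtype=float)
        if not (len(self.pos) == len(self.meth) == len(self.unmeth)):
            raise ValueError("pos/meth/unmeth length mismatch")
        if len(self.pos) > 1 and not np.all(np.diff(self.pos) > 0):
            raise ValueError("track positions must be strictly increasing")

    @property
    def rate(self) -> np.ndarray:
        """Smoothed methylation rate; NaN where smoothed coverage is zero."""
        total = self.meth + self.unmeth
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.meth / np.where(total > 0, total, 1.0), np.nan)


@dataclass(frozen=True)
class DmcParams:
    """Per-cytosine test thresholds: p-value ceiling (inclusive) and the
    minimum absolute mutant-WT rate difference (exclusive)."""

    p_max: float = 0.1
    min_abs_diff: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError("p_max must lie in (0, 1]")
        if not 0.0 <= self.min_abs_diff < 1.0:
            raise ValueError("min_abs_diff must lie in [0, 1)")


@dataclass(frozen=True)
class MergeParams:
    """Maximum merge distance (bp) between same-type DMCs, per context."""

    max_gap: dict = field(
        default_factory=lambda: {"CG": 160, "CHG": 240, "CHH": 70}
    )

    def __post_init__(self) -> None:
        for ctx, gap in self.max_gap.items():
            if gap < 1:
                raise ValueError(f"max_gap[{ctx}] must be >= 1")


@dataclass(frozen=True)
class DmrFilterParams:
    """Region-level acceptance thresholds."""

    min_dmcs: int = 5
    min_length_bp: int = 50
    fdr_max: float = 0.05
    min_abs_diff: dict = field(
        default_factory=lambda: {"CG": 0.40, "CHG": 0.20, "CHH": 0.20}
    )

    def __post_init__(self) -> None:
        if self.min_dmcs < 1 or self.min_length_bp < 1:
            raise ValueError("min_dmcs and min_length_bp must be positive")
        if not 0.0 < self.fdr_max <= 1.0:
            raise ValueError("fdr_max must lie in (0, 1]")


def _track_keys(libraries) -> set:
    keys = set()
    for lib in libraries:
        keys.update(map(tuple, lib[["chrom", "context"]].drop_duplicates().to_numpy()))
    return keys


def smooth_genotype(
    libraries,
    params: SmoothingParams | None = None,
    genotype: str = "",
    scaffold: dict | None = None,
    pool_libraries: bool = False,
) -> dict:
    """Smooth each library's counts and combine them into genotype tracks.

    Parameters
    ----------
    libraries
        Per-library cytosine tables (DataFrames with chrom, pos, context,
        meth, unmeth), each sorted by position within (chrom, context).
    params
        Smoothing window/degree.
    scaffold
        Optional mapping (chrom, context) -> sorted position array to use
        as the common track scaffold (e.g. the union across genotypes so
        that WT and mutant tracks align position-wise).  Positions present
        in a library but absent from the scaffold are an error.
    pool_libraries
        If True, sum raw counts across libraries before smoothing instead
        of smoothing each library independently and summing afterwards.

    Returns
    -------
    dict mapping (chrom, context) -> :class:`SmoothedTrack`.  Positions
    missing from a library contribute zero counts for that library.
    """
    if not libraries:
        raise ValueError("at least one library is required")
    if params is None:
        params = SmoothingParams()
    chrom_sets = [set(lib["chrom"].unique()) for lib in libraries]
    if len(set(map(frozenset, chrom_sets))) > 1:
        warnings.warn(
            f"genotype {genotype!r}: libraries cover different chromosome sets; "
            "using their union",
            stacklevel=2,
        )

    per_lib = [
        {
            key: sub.sort_values("pos", kind="mergesort")
            for key, sub in lib.groupby(["chrom", "context"], sort=False)
        }
        for lib in libraries
    ]
    keys = _track_keys(libraries)
    if scaffold is not None:
        keys |= set(scaffold)

    tracks = {}
    for key in sorted(keys):
        if scaffold is not None and key in scaffold:
            pos = np.asarray(scaffold[key], dtype=np.int64)
        else:
            pos = np.unique(
                np.concatenate(
                    [g[key]["pos"].to_numpy() for g in per_lib if key in g]
                    or [np.empty(0, dtype=np.int64)]
                )
            )
        n = len(pos)
        raw_m = np.zeros((len(per_lib), n))
        raw_u = np.zeros((len(per_lib), n))
        for k, g in enumerate(per_lib):
            if key not in g:
                continue
            sub = g[key]
            idx = np.searchsorted(pos, sub["pos"].to_numpy())
            if np.any(idx >= n) or np.any(pos[idx] != sub["pos"].to_numpy()):
                raise ValueError(f"library positions missing from scaffold for {key}")
            raw_m[k, idx] = sub["meth"].to_numpy()
            raw_u[k, idx] = sub["unmeth"].to_numpy()
        if n == 0:
            tracks[key] = SmoothedTrack(genotype, key[0], key[1],
                                        pos, np.empty(0), np.empty(0))
            continue
        if pool_libraries:
            meth = savitzky_golay_smooth(raw_m.sum(axis=0), params)
            unmeth = savitzky_golay_smooth(raw_u.sum(axis=0), params)
        else:
            meth = np.zeros(n)
            unmeth = np.zeros(n)
            for k in range(len(per_lib)):
                meth += savitzky_golay_smooth(raw_m[k], params)
                unmeth += savitzky_golay_smooth(raw_u[k], params)
        tracks[key] = SmoothedTrack(genotype, key[0], key[1], pos, meth, unmeth)
    return tracks


def call_dmcs(
    wt: SmoothedTrack, mut: SmoothedTrack, params: DmcParams | None = None
) -> pd.DataFrame:
    """Call differentially methylated cytosines on one aligned track pair.

    Cytosines with zero smoothed coverage in either genotype are skipped.
    A DMC requires p <= ``p_max`` on the rounded smoothed counts AND an
    absolute unrounded-rate difference strictly above ``min_abs_diff``;
    the sign of the difference assigns hyper (mutant gain) or hypo.
    """
    if params is None:
        params = DmcParams()
    if (wt.chrom, wt.context) != (mut.chrom, mut.context):
        raise ValueError("tracks must cover the same (chromosome, context)")

    pos, iw, im = np.intersect1d(wt.pos, mut.pos, return_indices=True)
    wm, wu = wt.meth[iw], wt.unmeth[iw]
    mm, mu = mut.meth[im], mut.unmeth[im]
    tw, tm = wm + wu, mm + mu
    defined = (tw > 0) & (tm > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_wt = np.where(defined, wm / np.where(tw > 0, tw, 1.0), np.nan)
        rate_mut = np.where(defined, mm / np.where(tm > 0, tm, 1.0), np.nan)
    diff = rate_mut - rate_wt
    cand = defined & (np.abs(diff) > params.min_abs_diff)

    rows = []
    rm, ru = round_counts(mm), round_counts(mu)
    rwm, rwu = round_counts(wm), round_counts(wu)
    for i in np.flatnonzero(cand):
        p = fisher_exact_two_sided(int(rm[i]), int(ru[i]), int(rwm[i]), int(rwu[i]))
        if p <= params.p_max:
            rows.append(
                (wt.chrom, int(pos[i]), wt.context,
                 "hyper" if diff[i] > 0 else "hypo",
                 p, rate_wt[i], rate_mut[i], diff[i])
            )
    return pd.DataFrame(rows, columns=DMC_COLUMNS)


def merge_dmcs(
    dmcs: pd.DataFrame, context: str, params: MergeParams | None = None
) -> pd.DataFrame:
    """Chain same-type DMCs into candidate regions.

    Consecutive same-type DMCs merge when their distance is at most the
    context's ``max_gap`` and no opposite-type DMC lies strictly between
    them; chaining is transitive.  Every DMC belongs to exactly one
    candidate region (singletons included; the region filters remove them
    later).  Input must be position-sorted and single-chromosome.
    """
    if params is None:
        params = MergeParams()
    if context not in params.max_gap:
        raise ValueError(f"no max_gap configured for context {context!r}")
    gap = params.max_gap[context]
    if dmcs.empty:
        return pd.DataFrame(columns=REGION_COLUMNS[:6])
    if dmcs["chrom"].nunique() > 1:
        raise ValueError("merge_dmcs operates on a single chromosome")
    if (dmcs["context"] != context).any():
        raise ValueError("DMC context does not match the requested context")
    positions = dmcs["pos"].to_numpy()
    if not np.all(np.diff(positions) > 0):
        raise ValueError("DMCs must be sorted by strictly increasing position")

    chrom = dmcs["chrom"].iloc[0]
    types = dmcs["type"].to_numpy()
    regions = []
    start = end = int(positions[0])
    cur_type = types[0]
    count = 1
    # a single sorted pass: any opposite-type DMC appears between two
    # same-type DMCs in iteration order and closes the open chain
    for pos, typ in zip(positions[1:], types[1:]):
        pos = int(pos)
        if typ == cur_type and pos - end <= gap:
            end = pos
            count += 1
        else:
            regions.append((chrom, start, end, context, cur_type, count))
            start = end = pos
            cur_type = typ
            count = 1
    regions.append((chrom, start, end, context, cur_type, count))
    return pd.DataFrame(regions, columns=REGION_COLUMNS[:6])


def test_region(
    start: int, end: int, wt: SmoothedTrack, mut: SmoothedTrack
) -> dict:
    """Region-level Fisher's exact test on averaged smoothed counts.

    For each genotype the smoothed methylated and unmethylated counts are
    averaged over all cytosines of the region's context within
    [start, end] (zero-coverage cytosines contribute zeros), each average
    is rounded, and the rounded 2x2 table is tested.  The region rates and
    their difference use the unrounded averages.  A region whose rounded
    counts are all zero returns p = 1.
    """
    sel_w = slice(*np.searchsorted(wt.pos, [start, end + 1]))
    sel_m = slice(*np.searchsorted(mut.pos, [start, end + 1]))
    if sel_w.stop - sel_w.start == 0 or sel_m.stop - sel_m.start == 0:
        raise ValueError("region contains no cytosines of its context")
    wm = float(np.mean(wt.meth[sel_w]))
    wu = float(np.mean(wt.unmeth[sel_w]))
    mm = float(np.mean(mut.meth[sel_m]))
    mu = float(np.mean(mut.unmeth[sel_m]))
    table = [int(round_counts(v)) for v in (mm, mu, wm, wu)]
    p = 1.0 if sum(table) == 0 else fisher_exact_two_sided(*table)
    rate_wt = wm / (wm + wu) if wm + wu > 0 else np.nan
    rate_mut = mm / (mm + mu) if mm + mu > 0 else np.nan
    return {
        "p_value": p,
        "rate_wt": rate_wt,
        "rate_mut": rate_mut,
        "diff": rate_mut - rate_wt,
    }


def filter_dmrs(
    candidates: pd.DataFrame, params: DmrFilterParams | None = None
) -> pd.DataFrame:
    """Apply the DMR acceptance filters to FDR-annotated candidate regions.

    Keeps regions with >= ``min_dmcs`` member DMCs, length >=
    ``min_length_bp``, FDR <= ``fdr_max`` and an absolute region rate
    difference at least the context-specific threshold.
    """
    if params is None:
        params = DmrFilterParams()
    if candidates.empty:
        return candidates.copy()
    length = candidates["end"] - candidates["start"] + 1
    thresh = candidates["context"].map(params.min_abs_diff)
    keep = (
        (candidates["n_dmcs"] >= params.min_dmcs)
        & (length >= params.min_length_bp)
        & (candidates["fdr"] <= params.fdr_max)
        & (candidates["diff"].abs() >= thresh)
    )
    return candidates[keep.fillna(False)].reset_index(drop=True)


def map_dmrs_to_features(dmrs: pd.DataFrame, features) -> pd.DataFrame:
    """Map DMRs to features they overlap by at least one nucleotide.

    Intervals are 1-based inclusive; DMR [s1, e1] overlaps feature
    [s2, e2] iff max(s1, s2) <= min(e1, e2).  A DMR may map to several
    features.  Returns a DataFrame with columns dmr_index (positional
    index into ``dmrs``) and feature_id.
    """
    feats = _as_feature_frame(features)
    pairs = []
    for chrom, fsub in feats.groupby("chrom"):
        dsub = dmrs[dmrs["chrom"] == chrom]
        if dsub.empty:
            continue
        ds = dsub["start"].to_numpy()[:, None]
        de = dsub["end"].to_numpy()[:, None]
        fs = fsub["start"].to_numpy()[None, :]
        fe = fsub["end"].to_numpy()[None, :]
        hit = np.maximum(ds, fs) <= np.minimum(de, fe)
        di, fi = np.nonzero(hit)
        for i, j in zip(di, fi):
            pairs.append((dsub.index[i], fsub["id"].iloc[j]))
    return pd.DataFrame(pairs, columns=["dmr_index", "feature_id"])


def overlap_summary(hypo_dmrs_by_context: dict, upregulated_features) -> pd.DataFrame:
    """Per-context Venn counts between hypo-DMRs and upregulated loci.

    A feature counts as overlapped when at least one hypo-DMR of the
    context maps to it (one-nucleotide overlap rule).
    """
    feats = _as_feature_frame(upregulated_features)
    rows = []
    for context, dmrs in hypo_dmrs_by_context.items():
        overlapped = (
            set(map_dmrs_to_features(dmrs, feats)["feature_id"])
            if len(dmrs) else set()
        )
        rows.append((context, len(dmrs), len(feats), len(overlapped)))
    return pd.DataFrame(
        rows, columns=["context", "n_dmrs", "n_upregulated", "n_overlap"]
    )


def _as_feature_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    from .io import features_to_frame

    return features_to_frame(features)


class DifferentialMethylation:
    """Whole-methylome differential-methylation model.

    Parameters
    ----------
    wt_libraries, mut_libraries
        Per-library cytosine tables for the control and mutant genotypes.
    smoothing, dmc, merge, filters
        Parameter blocks; defaults reproduce the standard procedure.
    contexts
        Cytosine contexts to analyse (default all three).
    pool_libraries
        Combine replicate libraries by pooling raw counts before smoothing
        instead of smoothing each library first (default False).
    """

    def __init__(
        self,
        wt_libraries,
        mut_libraries,
        *,
        smoothing: SmoothingParams | None = None,
        dmc: DmcParams | None = None,
        merge: MergeParams | None = None,
        filters: DmrFilterParams | None = None,
        contexts=CYTOSINE_CONTEXTS,
        pool_libraries: bool = False,
    ):
        self.wt_libraries = list(wt_libraries)
        self.mut_libraries = list(mut_libraries)
        self.smoothing = smoothing or SmoothingParams()
        self.dmc = dmc or DmcParams()
        self.merge = merge or MergeParams()
        self.filters = filters or DmrFilterParams()
        self.contexts = tuple(contexts)
        self.pool_libraries = pool_libraries

    def fit(self) -> "DifferentialMethylationResults":
        """Run smoothing, DMC calling, merging, region testing and
        filtering; returns the results object."""
        scaffold = {}
        for lib in self.wt_libraries + self.mut_libraries:
            for key, sub in lib.groupby(["chrom", "context"], sort=False):
                prev = scaffold.get(key)
                cur = sub["pos"].to_numpy()
                scaffold[key] = cur if prev is None else np.union1d(prev, cur)
        scaffold = {k: v for k, v in scaffold.items() if k[1] in self.contexts}

        wt_tracks = smooth_genotype(
            self.wt_libraries, self.smoothing, "wt", scaffold, self.pool_libraries
        )
        mut_tracks = smooth_genotype(
            self.mut_libraries, self.smoothing, "mut", scaffold, self.pool_libraries
        )

        dmc_frames, candidates_by_ctx = [], {}
        for context in self.contexts:
            ctx_candidates = []
            for key in sorted(k for k in scaffold if k[1] == context):
                wt_t, mut_t = wt_tracks[key], mut_tracks[key]
                dmcs = call_dmcs(wt_t, mut_t, self.dmc)
                if dmcs.empty:
                    continue
                dmc_frames.append(dmcs)
                regions = merge_dmcs(dmcs, context, self.merge)
                stats_rows = [
                    test_region(int(r.start), int(r.end), wt_t, mut_t)
                    for r in regions.itertuples()
                ]
                ctx_candidates.append(
                    pd.concat([regions, pd.DataFrame(stats_rows)], axis=1)
                )
            if ctx_candidates:
                ctx_df = pd.concat(ctx_candidates, ignore_index=True)
                # BH across all candidate regions of this context
                ctx_df["fdr"] = benjamini_hochberg(ctx_df["p_value"].to_numpy())
            else:
                ctx_df = pd.DataFrame(columns=REGION_COLUMNS + ["fdr"])
            candidates_by_ctx[context] = ctx_df

        dmcs = (
            pd.concat(dmc_frames, ignore_index=True)
            if dmc_frames
            else pd.DataFrame(columns=DMC_COLUMNS)
        )
        candidates = pd.concat(candidates_by_ctx.values(), ignore_index=True)
        dmrs = filter_dmrs(candidates, self.filters)
        return DifferentialMethylationResults(self, wt_tracks, mut_tracks, dmcs,
                                              candidates, dmrs)


class DifferentialMethylationResults:
    """Fitted differential-methylation results.

    Attributes
    ----------
    dmcs : DataFrame of differential cytosines.
    candidates : DataFrame of merged candidate regions with p-values/FDR.
    dmrs : DataFrame of accepted DMRs.
    wt_tracks, mut_tracks : the genotype-level smoothed tracks.
    """

    def __init__(self, model, wt_tracks, mut_tracks, dmcs, candidates, dmrs):
        self.model = model
        self.wt_tracks = wt_tracks
        self.mut_tracks = mut_tracks
        self.dmcs = dmcs
        self.candidates = candidates
        self.dmrs = dmrs

    def hypo_dmrs_by_context(self) -> dict:
        return {
            ctx: self.dmrs[(self.dmrs["context"] == ctx) & (self.dmrs["type"] == "hypo")]
            for ctx in self.model.contexts
        }

    def map_to_features(self, features) -> pd.DataFrame:
        return map_dmrs_to_features(self.dmrs, features)

    def overlap_summary(self, upregulated_features) -> pd.DataFrame:
        return overlap_summary(self.hypo_dmrs_by_context(), upregulated_features)

    def summary(self) -> str:
        lines = ["Differential methylation summary", "=" * 40]
        lines.append(f"{'context':<8}{'type':<7}{'DMCs':>8}{'DMRs':>8}{'mean len':>10}")
        for ctx in self.model.contexts:
            for typ in ("hyper", "hypo"):
                nd = int(((self.dmcs["context"] == ctx) & (self.dmcs["type"] == typ)).sum())
                sub = self.dmrs[(self.dmrs["context"] == ctx) & (self.dmrs["type"] == typ)]
                mean_len = (
                    float((sub["end"] - sub["start"] + 1).mean()) if len(sub) else 0.0
                )
                lines.append(f"{ctx:<8}{typ:<7}{nd:>8}{len(sub):>8}{mean_len:>10.1f}")
        lines.append(f"total candidate regions: {len(self.candidates)}")
        lines.append(f"total DMRs: {len(self.dmrs)}")
        return "\n".join(lines)
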