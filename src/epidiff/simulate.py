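"""Seeded synthetic genomes, methylomes, RNA-seq and siRNA counts.

The generator emulates the statistical structure the analysis assumes in a
plant genome at desk scale: chromosomes with a central pericentromeric
heterochromatin compartment where TEs are densely packed and DNA
methylation is high in all three cytosine contexts, euchromatic arms
dominated by protein-coding genes, two replicate sequencing libraries per
genotype, beta-binomially overdispersed bisulfite counts, negative-
binomial RNA-seq counts, and multinomial small-RNA size classes with 24-nt
siRNAs concentrated on heterochromatic TEs.  Every generator is
bit-reproducible given its seed: a single global seed fans out to fixed
per-component child seeds so adding a generator does not shift existing
streams.  Ground-truth tables (injected DMR intervals, injected
differentially expressed loci) are emitted alongside the data so recovery
and null behaviour can be scored without further bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CYTOSINE_CONTEXTS

__all__ = [
    "GenomeSpec",
    "Genome",
    "MethylomeSpec",
    "InjectedDmr",
    "make_genome",
    "simulate_methylome",
    "simulate_expression",
    "simulate_srna",
    "srna_coverage",
    "preset_null",
    "preset_dmr_recovery",
    "preset_de_recovery",
    "score_dmr_calls",
    "score_de_calls",
]

# fixed component ids for seed fan-out
_COMP_GENOME = 1
_COMP_METH = 2
_COMP_EXPR = 3
_COMP_SRNA = 4


def _rng(seed: int, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(key)))


@dataclass(frozen=True)
class GenomeSpec:
    """Desk-scale genome layout.

    Defaults: 2 chromosomes of 1 Mb with the central 40% as
    pericentromeric heterochromatin, TEs four times denser in
    heterochromatin than euchromatin, genes with the reverse bias, and
    per-bp cytosine densities CG 0.04, CHG 0.03, CHH 0.08 (CHH sites far
    outnumber the symmetric contexts, as in real plant genomes).
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    pericentromere_fraction: float = 0.4
    n_pcgs: int = 400
    n_tes: int = 400
    te_het_eu_ratio: float = 4.0
    pcg_het_eu_ratio: float = 0.25
    pcg_length: tuple = (800, 3000)
    te_length: tuple = (300, 3000)
    cytosine_density: dict = field(
        default_factory=lambda: {"CG": 0.04, "CHG": 0.03, "CHH": 0.08}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pericentromere_fraction < 1.0:
            raise ValueError("pericentromere_fraction must lie in (0, 1)")


@dataclass
class Genome:
    """Feature annotation plus cytosine position map for a synthetic genome."""

    chrom_sizes: dict
    pericentromeres: dict
    features: pd.DataFrame
    cytosines: dict  # chrom -> DataFrame(pos, strand, context) sorted by pos

    def compartment_of(self, chrom: str, pos) -> np.ndarray:
        s, e = self.pericentromeres[chrom]
        pos = np.asarray(pos)
        return np.where((pos >= s) & (pos <= e), "pericentromeric_het", "euchromatin")


def _place_nonoverlapping(rng, lo: int, hi: int, lengths: np.ndarray) -> np.ndarray:
    """Sorted non-overlapping start positions for intervals of the given
    lengths inside [lo, hi]; raises if they cannot fit."""
    k = len(lengths)
    if k == 0:
        return np.empty(0, dtype=np.int64)
    space = hi - lo + 1
    slack = space - int(lengths.sum())
    if slack < 0:
        raise ValueError(
            f"cannot place {k} features totalling {lengths.sum()} bp in {space} bp"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=k))
    starts = lo + cuts + np.concatenate(([0], np.cumsum(lengths[:-1])))
    return starts.astype(np.int64)


def _assign_with_capacity(rng, lengths, capacities, probs) -> np.ndarray:
    """Assign each feature to a compartment interval with the given
    probabilities, spilling overloaded intervals into whichever interval
    has the most free space; raises if the features cannot fit at all."""
    if lengths.sum() > sum(capacities):
        raise ValueError(
            f"cannot place features totalling {lengths.sum()} bp in "
            f"{sum(capacities)} bp"
        )
    assign = rng.choice(len(capacities), size=len(lengths), p=probs / probs.sum())
    loads = np.array([lengths[assign == b].sum() for b in range(len(capacities))])
    caps = np.asarray(capacities)
    for i in rng.permutation(len(lengths)):
        b = assign[i]
        if loads[b] <= caps[b]:
            continue
        free = caps - loads
        free[b] = -1
        target = int(np.argmax(free))
        if free[target] < lengths[i]:
            raise ValueError("cannot rebalance features into compartments")
        loads[b] -= lengths[i]
        loads[target] += lengths[i]
        assign[i] = target
    if np.any(loads > caps):
        raise ValueError("cannot rebalance features into compartments")
    return assign


def make_genome(spec: GenomeSpec) -> Genome:
    """Generate chromosome layout, features and cytosine positions.

    Deterministic given ``spec`` (including its seed).  TEs are enriched in
    the pericentromeric compartment per the het:eu density ratio; features
    never overlap within a class.
    """
    rng = _rng(spec.seed, _COMP_GENOME)
    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    chrom_sizes = {c: spec.chrom_length for c in chroms}
    half = spec.pericentromere_fraction / 2.0
    pericentromeres = {
        c: (
            int(spec.chrom_length * (0.5 - half)) + 1,
            int(spec.chrom_length * (0.5 + half)),
        )
        for c in chroms
    }

    feature_rows = []
    for kind, n_total, ratio, length_range in (
        ("PCG", spec.n_pcgs, spec.pcg_het_eu_ratio, spec.pcg_length),
        ("TE", spec.n_tes, spec.te_het_eu_ratio, spec.te_length),
    ):
        if n_total == 0:
            continue
        per_chrom = np.full(spec.n_chroms, n_total // spec.n_chroms)
        per_chrom[: n_total % spec.n_chroms] += 1
        counter = 0
        for c, n_c in zip(chroms, per_chrom):
            het_lo, het_hi = pericentromeres[c]
            l_het = het_hi - het_lo + 1
            l_eu = chrom_sizes[c] - l_het
            p_het = ratio * l_het / (ratio * l_het + l_eu)
            left_len = het_lo - 1
            p_left = (1 - p_het) * left_len / l_eu
            # intervals: het, eu left arm, eu right arm
            bins = [
                ("pericentromeric_het", het_lo, het_hi),
                ("euchromatin", 1, het_lo - 1),
                ("euchromatin", het_hi + 1, chrom_sizes[c]),
            ]
            probs = np.array([p_het, p_left, 1 - p_het - p_left])
            lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_c)
            assign = _assign_with_capacity(
                rng, lengths, [hi - lo + 1 for _, lo, hi in bins], probs
            )
            for b, (compartment, lo, hi) in enumerate(bins):
                sub = lengths[assign == b]
                starts = _place_nonoverlapping(rng, lo, hi, sub)
                for s, ln in zip(starts, sub):
                    counter += 1
                    feature_rows.append(
                        (
                            f"{kind}_{c}_{counter:05d}", c, int(s), int(s + ln - 1),
                            "+" if rng.random() < 0.5 else "-", kind, compartment,
                        )
                    )
    features = pd.DataFrame(
        feature_rows,
        columns=["id", "chrom", "start", "end", "strand", "kind", "compartment"],
    ).sort_values(["chrom", "start"], ignore_index=True)

    cytosines = {}
    densities = spec.cytosine_density
    for c in chroms:
        size = chrom_sizes[c]
        counts = {ctx: int(round(densities.get(ctx, 0.0) * size)) for ctx in CYTOSINE_CONTEXTS}
        total = sum(counts.values())
        if total > size:
            raise ValueError("cytosine densities exceed one site per bp")
        all_pos = rng.choice(size, size=total, replace=False) + 1
        offset = 0
        frames = []
        for ctx in CYTOSINE_CONTEXTS:
            k = counts[ctx]
            pos = np.sort(all_pos[offset: offset + k])
            offset += k
            frames.append(
                pd.DataFrame(
                    {
                        "pos": pos,
                        "strand": np.where(rng.random(k) < 0.5, "+", "-"),
                        "context": ctx,
                    }
                )
            )
        cytosines[c] = (
            pd.concat(frames, ignore_index=True)
            .sort_values("pos", kind="mergesort", ignore_index=True)
        )
    return Genome(chrom_sizes, pericentromeres, features, cytosines)


@dataclass(frozen=True)
class InjectedDmr:
    """Ground-truth differential interval forced into one genotype."""

    chrom: str
    start: int
    end: int
    context: str
    rate: float


@dataclass(frozen=True)
class MethylomeSpec:
    """Bisulfite-count generative parameters.

    Base methylation rates per context and compartment default to dense
    heterochromatic methylation (CG 0.85, CHG 0.55, CHH 0.15) against a
    lightly methylated euchromatin (CG 0.20, CHG 0.05, CHH 0.03).
    Coverage is Poisson with the given mean; methylated counts are
    beta-binomial with the given overdispersion (rho = 0 reduces to
    binomial).  Two replicate libraries per genotype by default.
    """

    base_rates: dict = field(
        default_factory=lambda: {
            "CG": {"pericentromeric_het": 0.85, "euchromatin": 0.20},
            "CHG": {"pericentromeric_het": 0.55, "euchromatin": 0.05},
            "CHH": {"pericentromeric_het": 0.15, "euchromatin": 0.03},
        }
    )
    overdispersion: float = 0.05
    mean_coverage: float = 20.0
    n_libraries: int = 2
    injections: tuple = ()

    def __post_init__(self) -> None:
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be non-negative")
        if not 0.0 <= self.overdispersion < 1.0:
            raise ValueError("overdispersion must lie in [0, 1)")


def simulate_methylome(
    genome: Genome, spec: MethylomeSpec, genotype: str, seed: int = 0
):
    """Simulate per-library cytosine count tables for one genotype.

    Returns ``(libraries, truth)``: a list of ``n_libraries`` cytosine
    DataFrames (chrom, pos, strand, context, meth, unmeth) and the truth
    table of injected intervals (with hyper/hypo type relative to the base
    rate at each interval).
    """
    import zlib

    gkey = zlib.crc32(genotype.encode())
    truth_rows = []
    per_chrom_rates = {}
    for chrom, cyt in genome.cytosines.items():
        pos = cyt["pos"].to_numpy()
        comp = genome.compartment_of(chrom, pos)
        rate = np.empty(len(pos))
        for ctx in CYTOSINE_CONTEXTS:
            for compartment, r in spec.base_rates[ctx].items():
                sel = (cyt["context"].to_numpy() == ctx) & (comp == compartment)
                rate[sel] = r
        for inj in spec.injections:
            if inj.chrom != chrom:
                continue
            sel = (
                (cyt["context"].to_numpy() == inj.context)
                & (pos >= inj.start)
                & (pos <= inj.end)
            )
            rate[sel] = inj.rate
        per_chrom_rates[chrom] = rate
    for inj in spec.injections:
        mid = (inj.start + inj.end) // 2
        compartment = str(genome.compartment_of(inj.chrom, [mid])[0])
        base = spec.base_rates[inj.context][compartment]
        truth_rows.append(
            (
                inj.chrom, inj.start, inj.end, inj.context, inj.rate, base,
                "hypo" if inj.rate < base else "hyper",
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "start", "end", "context", "target_rate", "base_rate", "type"],
    )

    libraries = []
    rho = spec.overdispersion
    for lib in range(spec.n_libraries):
        rng = _rng(seed, _COMP_METH, gkey, lib)
        frames = []
        for chrom, cyt in genome.cytosines.items():
            rate = per_chrom_rates[chrom]
            n = len(rate)
            cov = rng.poisson(spec.mean_coverage, size=n)
            if rho > 0:
                scale = (1.0 - rho) / rho
                a = np.clip(rate * scale, 1e-12, None)
                b = np.clip((1.0 - rate) * scale, 1e-12, None)
                p = rng.beta(a, b)
                p[rate <= 0.0] = 0.0
                p[rate >= 1.0] = 1.0
            else:
                p = rate
            meth = rng.binomial(cov, p)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": cyt["pos"].to_numpy(),
                        "strand": cyt["strand"].to_numpy(),
                        "context": cyt["context"].to_numpy(),
                        "meth": meth,
                        "unmeth": cov - meth,
                    }
                )
            )
        libraries.append(pd.concat(frames, ignore_index=True))
    return libraries, truth


def simulate_expression(
    genome: Genome,
    de_loci=(),
    baseline_mean: float = 50.0,
    dispersion: float = 0.05,
    n_pairs: int = 2,
    seed: int = 0,
    baseline_override: dict | None = None,
    background_reads: int = 1_000_000,
):
    """Simulate an RNA-seq count table over the genome's features.

    Counts are negative-binomial around a per-locus baseline (gamma-
    distributed across loci with the given mean); mutant libraries scale
    the baseline of each injected locus by its fold change.  The default
    dispersion (0.05) represents replicate libraries of isogenic plant
    material.  ``n_pairs`` replicate libraries are drawn per genotype.
    ``background_reads`` is added to every library's total mapped reads:
    it stands for the bulk of a real library that maps outside the
    desk-scale locus set, so that totals are not dominated by the assayed
    loci themselves.  Returns ``(table, truth, totals)`` where ``table``
    carries locus coordinates and the count columns wt_1..wt_n,
    mut_1..mut_n, ``truth`` lists each locus's baseline and fold, and
    ``totals`` holds per-library total mapped reads.
    """
    folds = dict(de_loci)
    if any(f <= 0 for f in folds.values()):
        raise ValueError("fold changes must be positive")
    rng = _rng(seed, _COMP_EXPR)
    loci = genome.features.set_index("id")
    n = len(loci)
    baseline = rng.gamma(shape=2.0, scale=baseline_mean / 2.0, size=n)
    if baseline_override:
        for locus, lam in baseline_override.items():
            baseline[loci.index.get_loc(locus)] = lam
    fold = np.array([folds.get(locus, 1.0) for locus in loci.index])

    def _draw(rng, mean):
        if dispersion < 1e-9:
            return rng.poisson(mean)
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mean))

    table = loci[["chrom", "start", "end", "compartment", "kind"]].copy()
    count_cols = []
    for k in range(1, n_pairs + 1):
        table[f"wt_{k}"] = _draw(rng, baseline)
        table[f"mut_{k}"] = _draw(rng, baseline * fold)
        count_cols += [f"wt_{k}", f"mut_{k}"]
    truth = pd.DataFrame(
        {"baseline": baseline, "fold": fold}, index=loci.index
    )
    totals = table[count_cols].sum(axis=0) + int(background_reads)
    return table, truth, totals


@dataclass
class SrnaSim:
    """Synthetic small-RNA dataset: per-library read-length totals
    (18-26 nt) and per-locus counts for the 21- and 24-nt classes."""

    length_totals: pd.DataFrame  # index: read length 18..26; columns: libraries
    locus_counts: dict  # (size_class, library) -> pd.Series per locus
    intensities: pd.DataFrame  # truth: per-locus relative intensity per class


def simulate_srna(
    genome: Genome,
    class_fractions: dict | None = None,
    library_size: int = 1_000_000,
    n_libraries: int = 2,
    intensity: dict | None = None,
    seed: int = 0,
) -> SrnaSim:
    """Simulate size-classed small-RNA counts.

    Library totals over read lengths 18-26 nt are multinomial with the
    given 21-nt/24-nt fractions (the remainder spread evenly over the
    other lengths).  Within a size class, per-locus counts are multinomial
    with weights proportional to locus length times a kind/compartment
    intensity; by default 24-nt siRNAs concentrate on heterochromatic TEs.
    """
    fractions = dict(class_fractions or {"21": 0.15, "24": 0.55})
    if sum(fractions.values()) > 1.0 + 1e-9:
        raise ValueError("class fractions must sum to at most 1")
    intensity = intensity or {
        "24": {("TE", "pericentromeric_het"): 1.0, ("TE", "euchromatin"): 0.3,
               ("PCG", "pericentromeric_het"): 0.05, ("PCG", "euchromatin"): 0.02},
        "21": {("TE", "pericentromeric_het"): 0.5, ("TE", "euchromatin"): 0.4,
               ("PCG", "pericentromeric_het"): 0.2, ("PCG", "euchromatin"): 0.2},
    }
    lengths_nt = list(range(18, 27))
    other = [l for l in lengths_nt if str(l) not in fractions]
    p_other = max(0.0, 1.0 - sum(fractions.values())) / len(other)
    probs = [fractions.get(str(l), p_other) for l in lengths_nt]

    loci = genome.features.set_index("id")
    locus_len = (loci["end"] - loci["start"] + 1).to_numpy(dtype=float)
    weight_by_class = {}
    for cls in ("21", "24"):
        imap = intensity[cls]
        w = np.array(
            [
                imap.get((k, c), 0.0)
                for k, c in zip(loci["kind"], loci["compartment"])
            ]
        ) * locus_len
        weight_by_class[cls] = w

    length_totals = pd.DataFrame(index=pd.Index(lengths_nt, name="length"))
    locus_counts = {}
    for lib in range(1, n_libraries + 1):
        rng = _rng(seed, _COMP_SRNA, lib)
        totals = rng.multinomial(library_size, probs)
        col = f"lib_{lib}"
        length_totals[col] = totals
        for cls in ("21", "24"):
            total_cls = int(totals[lengths_nt.index(int(cls))])
            w = weight_by_class[cls]
            if w.sum() <= 0:
                counts = np.zeros(len(loci), dtype=np.int64)
            else:
                counts = rng.multinomial(total_cls, w / w.sum())
            locus_counts[(cls, col)] = pd.Series(counts, index=loci.index)
    intensities = pd.DataFrame(
        {cls: weight_by_class[cls] / locus_len for cls in ("21", "24")},
        index=loci.index,
    )
    return SrnaSim(length_totals, locus_counts, intensities)


def srna_coverage(genome: Genome, counts: pd.Series) -> dict:
    """Spread per-locus counts uniformly over each locus to a per-bp
    coverage track (chrom -> float array, index 0 = position 1)."""
    cov = {c: np.zeros(size) for c, size in genome.chrom_sizes.items()}
    feats = genome.features.set_index("id")
    for locus, count in counts.items():
        if count == 0:
            continue
        row = feats.loc[locus]
        length = row.end - row.start + 1
        cov[row.chrom][row.start - 1: row.end] += count / length
    return cov


# ---------------------------------------------------------------------------
# presets: the standard study conditions used by the CLI and the tests


def preset_null(seed: int, n_chroms: int = 1, chrom_length: int = 1_000_000,
                mean_coverage: float = 20.0):
    """Two genotypes simulated from identical generative parameters
    (no injected differences): the negative control for DMR calling."""
    gspec = GenomeSpec(n_chroms=n_chroms, chrom_length=chrom_length,
                       n_pcgs=200 * n_chroms, n_tes=200 * n_chroms, seed=seed)
    genome = make_genome(gspec)
    mspec = MethylomeSpec(mean_coverage=mean_coverage)
    wt, _ = simulate_methylome(genome, mspec, "wt", seed)
    mut, _ = simulate_methylome(genome, mspec, "mut", seed)
    truth = pd.DataFrame(
        columns=["chrom", "start", "end", "context", "target_rate", "base_rate", "type"]
    )
    return {"genome": genome, "wt": wt, "mut": mut, "truth": truth}


def preset_dmr_recovery(
    seed: int,
    n_dmrs: int = 30,
    context: str = "CG",
    target_rate: float = 0.10,
    length_range: tuple = (300, 800),
    mean_coverage: float = 20.0,
    n_chroms: int = 1,
    chrom_length: int = 1_000_000,
):
    """Hypo-methylated intervals injected into the mutant's heterochromatin
    (CG 0.85 -> 0.10 by default): the positive control for DMR calling."""
    gspec = GenomeSpec(n_chroms=n_chroms, chrom_length=chrom_length,
                       n_pcgs=200 * n_chroms, n_tes=200 * n_chroms, seed=seed)
    genome = make_genome(gspec)
    rng = _rng(seed, 90)
    per_chrom = np.full(n_chroms, n_dmrs // n_chroms)
    per_chrom[: n_dmrs % n_chroms] += 1
    injections = []
    for chrom, k in zip(genome.chrom_sizes, per_chrom):
        het_lo, het_hi = genome.pericentromeres[chrom]
        lengths = rng.integers(length_range[0], length_range[1] + 1, size=int(k))
        # pad each interval so neighbouring injections cannot chain together
        pad = 2000
        starts = _place_nonoverlapping(rng, het_lo, het_hi, lengths + pad) + pad // 2
        for s, ln in zip(starts, lengths):
            injections.append(InjectedDmr(chrom, int(s), int(s + ln - 1), context, target_rate))
    base_spec = MethylomeSpec(mean_coverage=mean_coverage)
    mut_spec = MethylomeSpec(mean_coverage=mean_coverage, injections=tuple(injections))
    wt, _ = simulate_methylome(genome, base_spec, "wt", seed)
    mut, truth = simulate_methylome(genome, mut_spec, "mut", seed)
    return {"genome": genome, "wt": wt, "mut": mut, "truth": truth}


def preset_de_recovery(
    seed: int,
    n_up: int = 30,
    fold: float = 8.0,
    baseline: float = 50.0,
    n_pairs: int = 2,
):
    """Loci upregulated ``fold``-times in the mutant, preferentially in
    pericentromeric heterochromatin: the positive control for DE calling."""
    gspec = GenomeSpec(seed=seed)
    genome = make_genome(gspec)
    rng = _rng(seed, 91)
    feats = genome.features
    het = feats[feats["compartment"] == "pericentromeric_het"]["id"].to_numpy()
    eu = feats[feats["compartment"] == "euchromatin"]["id"].to_numpy()
    n_het = min(len(het), int(round(n_up * 0.8)))
    chosen = list(rng.choice(het, size=n_het, replace=False))
    chosen += list(rng.choice(eu, size=n_up - n_het, replace=False))
    de_loci = [(locus, fold) for locus in chosen]
    overrides = {locus: baseline for locus in chosen}
    table, truth, totals = simulate_expression(
        genome, de_loci, baseline_mean=baseline, n_pairs=n_pairs, seed=seed,
        baseline_override=overrides,
    )
    return {"genome": genome, "table": table, "truth": truth, "totals": totals,
            "pairs": [(f"wt_{k}", f"mut_{k}") for k in range(1, n_pairs + 1)]}


# ---------------------------------------------------------------------------
# truth scoring


def score_dmr_calls(dmrs: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Recall/precision/boundary accuracy of called DMRs against injected
    intervals (same context and type, >= 1 nt overlap)."""
    n_true = len(truth)
    recovered = 0
    boundary_errors = []
    called_true = np.zeros(len(dmrs), dtype=bool)
    for t in truth.itertuples():
        sub = dmrs[
            (dmrs["chrom"] == t.chrom)
            & (dmrs["context"] == t.context)
            & (dmrs["type"] == t.type)
        ]
        hit = (sub["start"] <= t.end) & (sub["end"] >= t.start)
        if hit.any():
            recovered += 1
            called_true[[dmrs.index.get_loc(i) for i in sub.index[hit]]] = True
            merged_start = int(sub["start"][hit].min())
            merged_end = int(sub["end"][hit].max())
            boundary_errors.append(abs(merged_start - t.start))
            boundary_errors.append(abs(merged_end - t.end))
    recall = recovered / n_true if n_true else float("nan")
    precision = called_true.mean() if len(dmrs) else float("nan")
    return {
        "n_true": n_true,
        "n_called": len(dmrs),
        "recall": recall,
        "precision": float(precision),
        "mean_boundary_error_bp": float(np.mean(boundary_errors)) if boundary_errors else float("nan"),
        "max_boundary_error_bp": float(np.max(boundary_errors)) if boundary_errors else float("nan"),
    }


def score_de_calls(table: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Recall of injected upregulated loci and count of spurious calls."""
    injected = truth.index[truth["fold"] > 1.0]
    called_up = set(table.index[table["final_call"] == "up"])
    tp = sum(1 for locus in injected if locus in called_up)
    recall = tp / len(injected) if len(injected) else float("nan")
    false_calls = len(
        set(table.index[table["final_call"] != "unchanged"]) - set(injected)
    )
    return {
        "n_injected": int(len(injected)),
        "n_called_up": len(called_up),
        "recall": recall,
        "n_false_calls": false_calls,
    }
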