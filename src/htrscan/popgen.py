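"""Within-species population genomics: VCF hard filtering, diversity statistics
with coalescent null intervals, linkage disequilibrium, SNP pruning, and
mating-type classification.

Diversity definitions. For n haploid strains over a reference of length L:

* pi — the average number of pairwise nucleotide differences per site,
  computed pairwise-complete at each site and scaled by L;
* theta_W — Watterson's estimator S / (a1 * L) with a1 = sum_{i<n} 1/i;
* Tajima's D — the normalized difference (pi_total - S/a1) / sqrt(Var), with
  the standard b/c/e constants. Because clonal fungal populations violate the
  equilibrium assumptions behind the textbook critical values, the null 95%
  interval is obtained by fixed-S coalescent resampling: neutral genealogies
  are simulated for the observed n, S mutations are dropped on branches in
  proportion to branch length, and D is recomputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FilterThresholds",
    "VariantTable",
    "DiversityStats",
    "filter_vcf",
    "diversity",
    "tajima_d",
    "tajima_d_null_interval",
    "ld_decay",
    "ld_prune",
    "mating_type",
]

MISSING = -1


@dataclass(frozen=True)
class FilterThresholds:
    """GATK-style hard filters for haploid SNP calls.

    The two rank-sum bounds follow the GATK convention of negative cutoffs
    (a strongly negative rank sum means the alternative allele is supported
    by worse-quality or more clipped reads).
    """

    qd_min: float = 2.0
    mq_min: float = 40.0
    fs_max: float = 60.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0
    max_missing: float = 0.10


@dataclass
class VariantTable:
    """Haploid biallelic SNP matrix: genotypes[site, strain] in {0, 1, -1}."""

    genotypes: np.ndarray
    positions: np.ndarray  # 1-based, as in VCF
    contigs: np.ndarray
    samples: list[str]
    genome_length: int
    info: pd.DataFrame | None = None

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def take(self, idx: np.ndarray) -> "VariantTable":
        return VariantTable(
            genotypes=self.genotypes[idx],
            positions=self.positions[idx],
            contigs=self.contigs[idx],
            samples=self.samples,
            genome_length=self.genome_length,
            info=self.info.iloc[idx].reset_index(drop=True) if self.info is not None else None,
        )


class PloidyError(ValueError):
    pass


def filter_vcf(
    path: str | Path,
    thresholds: FilterThresholds = FilterThresholds(),
    *,
    genome_length: int | None = None,
) -> tuple[VariantTable, dict[str, int]]:
    """Read a haploid VCF and apply the hard filters.

    Removes indels, non-biallelic sites, and sites failing any threshold
    (QD, MQ, FS, MQRankSum, ReadPosRankSum, missingness). Returns the filtered
    table and a tally of removals per filter. Diploid genotypes raise
    :class:`PloidyError`. ``genome_length`` defaults to the sum of contig
    lengths declared in the VCF header.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if genome_length is None:
        genome_length = sum(c.length or 0 for c in vf.header.contigs.values())
        if genome_length == 0:
            raise ValueError("genome_length not given and no contig lengths in header")

    tallies = {
        "indel": 0, "non_biallelic": 0, "QD": 0, "MQ": 0, "FS": 0,
        "MQRankSum": 0, "ReadPosRankSum": 0, "missing": 0, "retained": 0,
    }
    geno_rows, pos_rows, contig_rows, info_rows = [], [], [], []
    info_keys = ("QD", "MQ", "FS", "MQRankSum", "ReadPosRankSum")
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            tallies["non_biallelic"] += 1
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            tallies["indel"] += 1
            continue
        # keys absent from the header count as missing (no filter applied)
        declared = vf.header.info
        info = {k: (rec.info.get(k) if k in declared else None) for k in info_keys}
        if info["QD"] is not None and info["QD"] < thresholds.qd_min:
            tallies["QD"] += 1
            continue
        if info["MQ"] is not None and info["MQ"] < thresholds.mq_min:
            tallies["MQ"] += 1
            continue
        if info["FS"] is not None and info["FS"] > thresholds.fs_max:
            tallies["FS"] += 1
            continue
        if info["MQRankSum"] is not None and info["MQRankSum"] < thresholds.mq_rank_sum_min:
            tallies["MQRankSum"] += 1
            continue
        if (
            info["ReadPosRankSum"] is not None
            and info["ReadPosRankSum"] < thresholds.read_pos_rank_sum_min
        ):
            tallies["ReadPosRankSum"] += 1
            continue
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s]["GT"]
            if len(gt) != 1:
                raise PloidyError(
                    f"{rec.chrom}:{rec.pos} sample {s} has ploidy {len(gt)}; "
                    "haploid calls required"
                )
            if gt[0] is not None:
                row[i] = gt[0]
        if np.mean(row == MISSING) > thresholds.max_missing:
            tallies["missing"] += 1
            continue
        tallies["retained"] += 1
        geno_rows.append(row)
        pos_rows.append(rec.pos)
        contig_rows.append(rec.chrom)
        info_rows.append({k: (float(v) if v is not None else np.nan) for k, v in info.items()})

    geno = np.array(geno_rows, dtype=np.int8) if geno_rows else np.zeros((0, len(samples)), np.int8)
    vt = VariantTable(
        genotypes=geno,
        positions=np.array(pos_rows, dtype=int),
        contigs=np.array(contig_rows, dtype=object),
        samples=samples,
        genome_length=int(genome_length),
        info=pd.DataFrame(info_rows) if info_rows else None,
    )
    return vt, tallies


def variant_table_from_matrix(
    genotypes: np.ndarray,
    positions: np.ndarray,
    genome_length: int,
    *,
    contig: str = "chr1",
    samples: Sequence[str] | None = None,
) -> VariantTable:
    """Wrap an in-memory (sites x strains) 0/1/-1 matrix as a VariantTable."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n = genotypes.shape[1]
    return VariantTable(
        genotypes=genotypes,
        positions=np.asarray(positions, dtype=int),
        contigs=np.full(genotypes.shape[0], contig, dtype=object),
        samples=list(samples) if samples is not None else [f"s{i}" for i in range(n)],
        genome_length=int(genome_length),
    )


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


@dataclass
class DiversityStats:
    pi: float                 # per site
    theta_w: float            # per site
    S: int
    tajima_d: float           # NaN when S == 0
    d_null_ci: tuple[float, float] | None
    n: int
    pi_se: float | None = None
    theta_w_se: float | None = None


def _site_components(genotypes: np.ndarray) -> tuple[float, int]:
    """(total pairwise-difference sum, segregating site count), missing-aware."""
    g = genotypes
    n1 = (g == 1).sum(axis=1)
    n0 = (g == 0).sum(axis=1)
    m = n0 + n1
    seg = (n0 > 0) & (n1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_site = np.where(m > 1, 2.0 * n0 * n1 / (m * (m - 1.0)), 0.0)
    return float(per_site.sum()), int(seg.sum())


def _tajima_constants(n: int) -> tuple[float, float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    return a1, c1 / a1, c2 / (a1**2 + a2)


def tajima_d(pi_total: float, S: int, n: int) -> float:
    """Tajima's D from the total pairwise-difference sum, S, and sample size."""
    if S == 0:
        return float("nan")
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:  # degenerate at n <= 3, where the variance constants vanish
        return float("nan")
    return (pi_total - S / a1) / math.sqrt(var)


class TajimaDNullBank:
    """Fixed-S null distribution of Tajima's D from reusable genealogies.

    ``n_sims`` neutral single-tree coalescent genealogies for n haploid
    samples are simulated once; for any segregating-site count S, S mutations
    are dropped on each genealogy's branches (multinomially, proportional to
    branch length) and D is recomputed, giving the conditional null
    distribution of D given (n, S). Reusing the genealogies makes interval
    computation for many S values cheap (one multinomial draw per genealogy).
    """

    def __init__(self, n: int, *, n_sims: int = 10_000, seed: int = 0) -> None:
        import msprime
        import tskit

        if n < 4:
            raise ValueError("Tajima's D requires n >= 4")
        self.n = n
        self.n_sims = n_sims
        self._rng = np.random.default_rng(seed)
        reps = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=1.0,
            num_replicates=n_sims, random_seed=max(1, seed % (2**31 - 1)) or 1,
        )
        self._branch_p: list[np.ndarray] = []
        self._weights: list[np.ndarray] = []
        denom = n * (n - 1.0)
        for ts in reps:
            tree = ts.first()
            nodes = [u for u in tree.nodes() if tree.parent(u) != tskit.NULL]
            bl = np.array([tree.branch_length(u) for u in nodes])
            below = np.array([tree.num_samples(u) for u in nodes])
            self._branch_p.append(bl / bl.sum())
            self._weights.append(2.0 * below * (self.n - below) / denom)
        self._cache: dict[int, np.ndarray] = {}

    def draws(self, S: int) -> np.ndarray:
        """Null D replicates conditioned on S segregating sites."""
        if S <= 0:
            raise ValueError("null distribution undefined for S <= 0")
        if S not in self._cache:
            ds = np.empty(self.n_sims)
            for i, (p, w) in enumerate(zip(self._branch_p, self._weights)):
                counts = self._rng.multinomial(S, p)
                ds[i] = tajima_d(float(counts @ w), S, self.n)
            self._cache[S] = ds
        return self._cache[S]

    def interval(self, S: int, alpha: float = 0.05) -> tuple[float, float]:
        lo, hi = np.quantile(self.draws(S), [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)


def tajima_d_null_interval(
    n: int,
    S: int,
    *,
    n_sims: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, np.ndarray]:
    """95% null interval for Tajima's D by fixed-S coalescent resampling.

    Convenience wrapper over :class:`TajimaDNullBank` for a single (n, S).
    Returns (lo, hi, replicates).
    """
    if S == 0:
        raise ValueError("null interval undefined for S = 0")
    bank = TajimaDNullBank(n, n_sims=n_sims, seed=seed)
    ds = bank.draws(S)
    lo, hi = bank.interval(S, alpha)
    return lo, hi, ds


def diversity(
    vt: VariantTable,
    *,
    null_sims: int = 10_000,
    seed: int = 0,
    jackknife_block: int | None = 100_000,
    compute_null: bool = True,
) -> DiversityStats:
    """pi, Watterson's theta, Tajima's D and its fixed-S null interval.

    Standard errors for pi and theta_W come from a block jackknife over
    ``jackknife_block``-bp windows (skipped when None or too few blocks).
    """
    if vt.n_samples < 2:
        raise ValueError("need at least 2 strains")
    L = vt.genome_length
    pi_total, S = _site_components(vt.genotypes)
    a1, _, _ = _tajima_constants(vt.n_samples)
    stats = DiversityStats(
        pi=pi_total / L,
        theta_w=S / (a1 * L),
        S=S,
        tajima_d=tajima_d(pi_total, S, vt.n_samples),
        d_null_ci=None,
        n=vt.n_samples,
    )
    if compute_null and S > 0:
        lo, hi, _ = tajima_d_null_interval(vt.n_samples, S, n_sims=null_sims, seed=seed)
        stats.d_null_ci = (lo, hi)
    if jackknife_block and S > 0:
        stats.pi_se, stats.theta_w_se = _jackknife_se(vt, jackknife_block, a1)
    return stats


def _jackknife_se(vt: VariantTable, block: int, a1: float) -> tuple[float, float]:
    """Delete-one-block jackknife over fixed genomic windows."""
    keys = [(c, p // block) for c, p in zip(vt.contigs, vt.positions)]
    blocks = sorted(set(keys))
    B = len(blocks)
    n_blocks_genome = max(B, math.ceil(vt.genome_length / block))
    if B < 2:
        return float("nan"), float("nan")
    pi_tot, S = _site_components(vt.genotypes)
    Lb = vt.genome_length / n_blocks_genome  # average block span
    pis, ths = [], []
    for b in blocks:
        idx = np.array([k != b for k in keys])
        pt, sb = _site_components(vt.genotypes[idx])
        Lm = vt.genome_length - Lb
        pis.append(pt / Lm)
        ths.append(sb / (a1 * Lm))
    pis, ths = np.array(pis), np.array(ths)
    fac = (B - 1.0) / B
    return (
        float(np.sqrt(fac * np.sum((pis - pis.mean()) ** 2))),
        float(np.sqrt(fac * np.sum((ths - ths.mean()) ** 2))),
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def _maf_mask(g: np.ndarray, maf_min: float, min_count: int = 1) -> np.ndarray:
    n1 = (g == 1).sum(axis=1)
    n0 = (g == 0).sum(axis=1)
    m = n0 + n1
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.minimum(n0, n1) / np.maximum(m, 1)
    return (np.minimum(n0, n1) >= min_count) & (maf >= maf_min) & (m > 0)


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared allelic correlation between two haploid sites, pairwise-complete."""
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x, y = a[ok].astype(float), b[ok].astype(float)
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_decay(
    vt: VariantTable,
    *,
    window: int = 15_000,
    maf_min: float = 0.2,
    bin_size: int = 500,
) -> pd.DataFrame:
    """Mean r^2 between site pairs within ``window`` bp, binned by distance.

    Sites below the minor-allele-frequency cutoff are excluded. Returns a
    DataFrame (distance_bin, mean_r2, n_pairs); empty with a warning when no
    qualifying pairs exist.
    """
    import warnings

    keep = _maf_mask(vt.genotypes, maf_min)
    sub = vt.take(np.flatnonzero(keep))
    dists, r2s = [], []
    for contig in np.unique(sub.contigs):
        idx = np.flatnonzero(sub.contigs == contig)
        pos = sub.positions[idx]
        order = np.argsort(pos)
        idx, pos = idx[order], pos[order]
        for i in range(idx.size):
            j = i + 1
            while j < idx.size and pos[j] - pos[i] <= window:
                r = _r2(sub.genotypes[idx[i]], sub.genotypes[idx[j]])
                if not math.isnan(r):
                    dists.append(pos[j] - pos[i])
                    r2s.append(r)
                j += 1
    if not dists:
        warnings.warn("no qualifying site pairs for LD decay")
        return pd.DataFrame(columns=["distance_bin", "mean_r2", "n_pairs"])
    df = pd.DataFrame({"distance": dists, "r2": r2s})
    df["distance_bin"] = (df["distance"] // bin_size) * bin_size + bin_size // 2
    out = (
        df.groupby("distance_bin")["r2"]
        .agg(mean_r2="mean", n_pairs="size")
        .reset_index()
    )
    return out


def ld_prune(
    vt: VariantTable,
    *,
    r2_max: float = 0.2,
    window: int = 1000,
    maf_min: float = 0.05,
    min_minor_count: int = 2,
) -> VariantTable:
    """Greedy left-to-right LD pruning.

    The MAF filter (minor allele in at least ``min_minor_count`` strains and
    frequency >= ``maf_min``) is applied first; then, scanning each contig in
    position order, a site is dropped if its r^2 with any already-retained
    site within ``window`` bp upstream is >= ``r2_max``. The output is a fixed
    point: pruning it again changes nothing.
    """
    keep = _maf_mask(vt.genotypes, maf_min, min_count=min_minor_count)
    sub = vt.take(np.flatnonzero(keep))
    retained: list[int] = []
    for contig in pd.unique(sub.contigs):
        idx = np.flatnonzero(sub.contigs == contig)
        idx = idx[np.argsort(sub.positions[idx])]
        kept_here: list[int] = []
        for i in idx:
            ok = True
            for j in reversed(kept_here):
                if sub.positions[i] - sub.positions[j] > window:
                    break
                r = _r2(sub.genotypes[i], sub.genotypes[j])
                if not math.isnan(r) and r >= r2_max:
                    ok = False
                    break
            if ok:
                kept_here.append(i)
        retained.extend(kept_here)
    out = sub.take(np.array(sorted(retained), dtype=int))
    # retained pairwise r^2 within the window must all be below the cutoff
    for contig in pd.unique(out.contigs):
        idx = np.flatnonzero(out.contigs == contig)
        pos = out.positions[idx]
        for a in range(idx.size):
            for b in range(a + 1, idx.size):
                if pos[b] - pos[a] > window:
                    break
                r = _r2(out.genotypes[idx[a]], out.genotypes[idx[b]])
                assert math.isnan(r) or r < r2_max
    return out


# ---------------------------------------------------------------------------
# mating type
# ---------------------------------------------------------------------------


def _six_frame_peptides(seq: str) -> list[str]:
    from Bio.Seq import Seq

    s = Seq(seq)
    frames = []
    for strand_seq in (s, s.reverse_complement()):
        for off in range(3):
            sub = strand_seq[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(sub.translate()))
    return frames


def _peptide_kmers(pep: str, k: int) -> set[str]:
    return {
        pep[i : i + k]
        for i in range(len(pep) - k + 1)
        if "*" not in pep[i : i + k] and "X" not in pep[i : i + k]
    }


def mating_type(
    assembly: str | Mapping[str, str],
    references: Mapping[str, str],
    *,
    k: int = 8,
    min_score: float = 0.3,
) -> tuple[str, dict[str, float]]:
    """Classify a genome's mating-type idiomorph by translated similarity.

    Each reference idiomorph is translated (it is an ORF) and its peptide
    k-mers are searched in the six-frame translation of the assembly; the
    score per idiomorph is the fraction of its peptide k-mers found. The call
    is the idiomorph with score >= ``min_score``; "both" (an anomaly in
    heterothallic fungi) when both exceed it, "none" when neither does.

    Returns (call, scores).
    """
    if not references:
        raise ValueError("reference idiomorph sequences required")
    if isinstance(assembly, str):
        contigs = {"contig": assembly}
    else:
        contigs = dict(assembly)
    genome_kmers: set[str] = set()
    for seq in contigs.values():
        for pep in _six_frame_peptides(seq):
            genome_kmers |= _peptide_kmers(pep, k)
    scores = {}
    for name, ref in references.items():
        from Bio.Seq import Seq

        pep = str(Seq(ref[: len(ref) - len(ref) % 3]).translate())
        kmers = _peptide_kmers(pep, k)
        scores[name] = len(kmers & genome_kmers) / max(1, len(kmers))
    hits = [name for name, sc in scores.items() if sc >= min_score]
    if len(hits) == 0:
        call = "none"
    elif len(hits) == 1:
        call = hits[0]
    else:
        call = "both"
    return call, scores


def mating_type_summary(calls: Mapping[str, str]) -> pd.DataFrame:
    """Per-idiomorph strain counts from a strain -> call mapping."""
    return (
        pd.Series(calls, name="call")
        .value_counts()
        .rename_axis("mating_type")
        .reset_index(name="n_strains")
    )
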