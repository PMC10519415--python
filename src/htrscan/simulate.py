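"""Synthetic genome panels with known ground truth.

Generates the data regime the rest of the package analyses: two (or more)
fungal-like species separated by ~10-15% background divergence, each holding
several clonal strains, with near-identical horizontally transferred regions
(HTRs) planted at species-specific loci, transposable-element (TE) annotations
that may overlap HTR termini, within-species SNPs at a target diversity, two
mating-type idiomorphs, and per-gene McDonald-Kreitman count data drawn from
the same Poisson log-linear model the selection module fits.

Genome composition is i.i.d. nucleotides with configurable GC content;
divergence and polymorphism are applied as per-site substitutions (no indels),
which keeps every planted coordinate exact. All outputs are deterministic
functions of (seed, config).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "HTRSpec",
    "SimulationConfig",
    "TruthTable",
    "simulate_panel",
    "simulate_variants",
    "simulate_mk_counts",
    "write_panel",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    """Configuration violates an invariant; the message names the field."""


@dataclass(frozen=True)
class HTRSpec:
    """One horizontally transferred region to plant.

    ``identity`` is the fraction of identical sites between the donor copy and
    each recipient copy (e.g. 0.995). ``recipients`` lists species indices that
    receive a copy; ``te_at_edges`` plants a TE interval overlapping each
    terminus of every planted copy.
    """

    length: int
    identity: float = 0.995
    recipients: tuple[int, ...] = (0, 1)
    te_at_edges: bool = False


@dataclass(frozen=True)
class SelectionSpec:
    """Per-gene-class composition for MK count simulation."""

    n_positive: int = 0
    n_negative: int = 0
    effect: float = 1.5  # log-scale effect on the gene selection effect


@dataclass
class SimulationConfig:
    seed: int = 0
    n_species: int = 2
    background_divergence: float = 0.12
    genome_length: int = 200_000
    n_strains_per_species: int = 3
    theta: float = 0.002
    htr_specs: tuple[HTRSpec, ...] = ()
    te_density: float = 0.05
    n_genes: int = 50
    gc_content: float = 0.48
    mat1_1_strains: tuple[str, ...] = ()  # strain ids carrying MAT1-1; rest MAT1-2

    def validate(self) -> None:
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        if not (0.0 <= self.background_divergence < 0.75):
            raise ConfigError("background_divergence must lie in [0, 0.75)")
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be positive")
        if self.n_strains_per_species < 1:
            raise ConfigError("n_strains_per_species must be >= 1")
        if self.theta < 0:
            raise ConfigError("theta must be >= 0")
        if not (0.0 <= self.te_density < 1.0):
            raise ConfigError("te_density must lie in [0, 1)")
        for i, h in enumerate(self.htr_specs):
            if h.length <= 0:
                raise ConfigError(f"htr_specs[{i}].length must be positive")
            if h.length >= self.genome_length / 4:
                raise ConfigError(
                    f"htr_specs[{i}].length must be below genome_length/4"
                )
            if not (0.0 < h.identity <= 1.0):
                raise ConfigError(f"htr_specs[{i}].identity must lie in (0, 1]")
            if any(r >= self.n_species or r < 0 for r in h.recipients):
                raise ConfigError(f"htr_specs[{i}].recipients out of range")


@dataclass
class TruthTable:
    """Ground truth of a simulated panel (coordinates 0-based half-open)."""

    planted_htrs: dict[str, list[tuple[int, int, int]]]  # strain -> [(start, end, htr_idx)]
    planted_theta: float
    planted_mating_type: dict[str, str]
    planted_selection: dict[str, str] = field(default_factory=dict)

    def validate_against(self, genome_lengths: dict[str, int]) -> None:
        for strain, ivs in self.planted_htrs.items():
            ivs = sorted(ivs)
            for (s, e, _), nxt in zip(ivs, ivs[1:] + [None]):
                if not (0 <= s < e <= genome_lengths[strain]):
                    raise ValueError(f"truth interval [{s},{e}) outside {strain}")
                if nxt is not None and nxt[0] < e:
                    raise ValueError(f"overlapping truth intervals in {strain}")


# ---------------------------------------------------------------------------
# genome panel
# ---------------------------------------------------------------------------


def _random_genome(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _substitute(rng: np.random.Generator, seq: np.ndarray, n_sub: int) -> np.ndarray:
    """Substitute exactly n_sub distinct sites to a different base."""
    out = seq.copy()
    if n_sub == 0:
        return out
    sites = rng.choice(seq.size, size=min(n_sub, seq.size), replace=False)
    out[sites] = (out[sites] + rng.integers(1, 4, size=sites.size)) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


# mating-type idiomorph cassettes: short protein-coding-like marker sequences.
# MAT1-1 carries an alpha-box-like ORF, MAT1-2 an HMG-box-like ORF; here they
# are simply two fixed, unrelated ORFs long enough for translated matching.
def reference_idiomorphs(length: int = 900, seed: int = 777) -> dict[str, str]:
    rng = np.random.default_rng(seed)
    out = {}
    for name in ("MAT1-1", "MAT1-2"):
        n_codons = length // 3
        # codons avoiding stops (indices of TAA=48? simpler: draw, then fix stops)
        seq = _random_genome(rng, n_codons * 3, 0.5)
        s = _to_str(seq)
        codons = [s[i : i + 3] for i in range(0, len(s), 3)]
        codons = ["ATG"] + [c if c not in ("TAA", "TAG", "TGA") else "TGG" for c in codons[1:]]
        out[name] = "".join(codons)
    return out


def simulate_panel(
    config: SimulationConfig,
    outdir: str | Path | None = None,
) -> tuple[dict[str, str], dict[str, list[tuple[int, int, str]]], TruthTable]:
    """Simulate a genome panel with planted HTRs, TEs, genes and mating types.

    Returns ``(assemblies, annotations, truth)`` where ``assemblies`` maps
    strain id -> sequence, and ``annotations`` maps strain id -> list of
    (start, end, feature_type) with feature_type in {"TE", "gene"}. Strain ids
    are ``sp{i}_s{j}``; strain j=0 of each species is the conventional
    reference. If ``outdir`` is given, FASTA/GFF3/BED/TSV files are written.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.genome_length

    # ancestral genome of species 0; others accumulate fixed differences
    species_refs = [_random_genome(rng, L, config.gc_content)]
    for _ in range(1, config.n_species):
        n_sub = int(round(config.background_divergence * L))
        species_refs.append(_substitute(rng, species_refs[0], n_sub))

    # choose non-overlapping insertion loci per species (species-specific loci)
    htr_loci: list[dict[int, int]] = []  # per spec index: species -> start
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(config.n_species)]
    donor_segments: list[np.ndarray] = []
    for h in config.htr_specs:
        donor_segments.append(_random_genome(rng, h.length, config.gc_content))
        loci: dict[int, int] = {}
        for sp in h.recipients:
            for _attempt in range(1000):
                start = int(rng.integers(0, L - h.length))
                if all(
                    start + h.length <= s or start >= e
                    for s, e in occupied[sp]
                ):
                    occupied[sp].append((start, start + h.length))
                    loci[sp] = start
                    break
            else:  # pragma: no cover - only for absurdly dense configs
                raise ConfigError("htr_specs: could not place HTRs without overlap")
        htr_loci.append(loci)

    # plant HTR copies into species references (replacement keeps length fixed)
    for h, seg, loci in zip(config.htr_specs, donor_segments, htr_loci):
        for sp, start in loci.items():
            n_sub = int(round((1.0 - h.identity) * h.length))
            copy = _substitute(rng, seg, n_sub)
            species_refs[sp][start : start + h.length] = copy

    # strains: per-strain substitutions at rate theta/2 relative to species ref
    # (two strains then differ at ~theta per site), sparing planted HTRs so the
    # configured donor identity is preserved exactly.
    assemblies: dict[str, str] = {}
    truth_htrs: dict[str, list[tuple[int, int, int]]] = {}
    mating: dict[str, str] = {}
    annotations: dict[str, list[tuple[int, int, str]]] = {}
    idiomorphs = reference_idiomorphs()

    for sp in range(config.n_species):
        htr_mask = np.zeros(L, dtype=bool)
        sp_truth = []
        for idx, loci in enumerate(htr_loci):
            if sp in loci:
                s = loci[sp]
                e = s + config.htr_specs[idx].length
                htr_mask[s:e] = True
                sp_truth.append((s, e, idx))
        free_sites = np.flatnonzero(~htr_mask)

        # shared annotations per species (TEs + genes), same coords for all strains
        feats = _simulate_features(rng, config, sp_truth)

        for j in range(config.n_strains_per_species):
            strain = f"sp{sp}_s{j}"
            seq = species_refs[sp].copy()
            if j > 0 and config.theta > 0 and free_sites.size:
                n_sub = rng.poisson(config.theta / 2 * free_sites.size)
                if n_sub:
                    sites = rng.choice(free_sites, size=min(n_sub, free_sites.size), replace=False)
                    seq[sites] = (seq[sites] + rng.integers(1, 4, size=sites.size)) % 4
            s = _to_str(seq)
            mt = "MAT1-1" if strain in config.mat1_1_strains else "MAT1-2"
            s = s + idiomorphs[mt]  # idiomorph cassette appended after the core genome
            assemblies[strain] = s
            truth_htrs[strain] = list(sp_truth)
            mating[strain] = mt
            annotations[strain] = list(feats)

    truth = TruthTable(
        planted_htrs=truth_htrs,
        planted_theta=config.theta,
        planted_mating_type=mating,
    )
    truth.validate_against({k: len(v) for k, v in assemblies.items()})
    if outdir is not None:
        write_panel(Path(outdir), assemblies, annotations, truth)
    return assemblies, annotations, truth


def _simulate_features(
    rng: np.random.Generator,
    config: SimulationConfig,
    sp_truth: list[tuple[int, int, int]],
) -> list[tuple[int, int, str]]:
    """TE and gene interval annotations for one species."""
    L = config.genome_length
    feats: list[tuple[int, int, str]] = []
    # TEs: fixed-size elements until the density target is met
    te_len = 2000
    n_te = int(config.te_density * L / te_len)
    for _ in range(n_te):
        s = int(rng.integers(0, L - te_len))
        feats.append((s, s + te_len, "TE"))
    # TE at HTR edges where requested: one element straddling each terminus
    for s, e, idx in sp_truth:
        if config.htr_specs[idx].te_at_edges:
            half = te_len // 2
            feats.append((max(0, s - half), s + half, "TE"))
            feats.append((e - half, min(L, e + half), "TE"))
    # genes: uniform 1.5-kbp intervals
    gene_len = 1500
    for g in range(config.n_genes):
        s = int(rng.integers(0, L - gene_len))
        feats.append((s, s + gene_len, "gene"))
    feats.sort()
    return feats


def write_panel(
    outdir: Path,
    assemblies: dict[str, str],
    annotations: dict[str, list[tuple[int, int, str]]],
    truth: TruthTable,
) -> list[Path]:
    """Write FASTA per strain, GFF3 annotations, BED truth intervals, TSV truth."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for strain, seq in sorted(assemblies.items()):
        p = outdir / f"{strain}.fasta"
        SeqIO.write([SeqRecord(Seq(seq), id=f"{strain}_contig1", description="")], p, "fasta")
        written.append(p)
    gff = outdir / "annotations.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for strain in sorted(annotations):
            for s, e, kind in annotations[strain]:
                feat = "transposable_element" if kind == "TE" else "gene"
                # GFF3 is 1-based inclusive
                fh.write(
                    f"{strain}_contig1\thtrscan_sim\t{feat}\t{s + 1}\t{e}\t.\t+\t.\tID={feat}_{s}\n"
                )
    written.append(gff)
    bed = outdir / "truth_htrs.bed"
    with open(bed, "w") as fh:
        for strain in sorted(truth.planted_htrs):
            for s, e, idx in sorted(truth.planted_htrs[strain]):
                fh.write(f"{strain}_contig1\t{s}\t{e}\thtr{idx}\n")
    written.append(bed)
    tsv = outdir / "truth.tsv"
    with open(tsv, "w") as fh:
        fh.write("strain\tmating_type\ttheta\n")
        for strain in sorted(truth.planted_mating_type):
            fh.write(f"{strain}\t{truth.planted_mating_type[strain]}\t{truth.planted_theta}\n")
    written.append(tsv)
    return written


# ---------------------------------------------------------------------------
# within-species variants (VCF)
# ---------------------------------------------------------------------------


def simulate_variants(
    config: SimulationConfig,
    out_vcf: str | Path | None = None,
    *,
    method: Literal["coalescent", "fixed_s", "clonal"] = "coalescent",
    contig: str = "chr1",
    fail_fraction: float = 0.0,
) -> tuple["np.ndarray", np.ndarray, "pd.DataFrame"]:
    """Simulate haploid within-species SNPs at the configured theta.

    Returns ``(genotypes, positions, info)``: a (sites x strains) 0/1 matrix,
    1-based positions, and per-site INFO metrics (QD, MQ, FS, MQRankSum,
    ReadPosRankSum). ``method``:

    - ``coalescent`` — msprime neutral coalescent (theta = 2*N*mu per site);
    - ``fixed_s`` — exactly E[S] = theta*a1*L segregating sites placed
      uniformly, derived-allele counts drawn from the neutral SFS;
    - ``clonal`` — two clonal lineages split half/half, all SNPs fixed
      between lineages (no within-lineage diversity), giving r^2 = 1 at all
      distances.

    A ``fail_fraction`` > 0 makes that fraction of sites fail one hard filter
    (for exercising VCF filtering). If ``out_vcf`` is given, a haploid VCF 4.2
    is written.
    """
    import pandas as pd

    config.validate()
    n = config.n_strains_per_species
    if n < 2:
        raise ConfigError("n_strains_per_species must be >= 2 for variant simulation")
    L = config.genome_length
    rng = np.random.default_rng(config.seed)

    if config.theta == 0 and method != "clonal":
        geno = np.zeros((0, n), dtype=np.int8)
        pos = np.zeros(0, dtype=int)
    elif method == "coalescent":
        import msprime

        N = 1000.0
        mu = config.theta / (2 * N)  # haploid coalescent: E[pi] = 2*N*mu per site
        ts = msprime.sim_ancestry(
            samples=n,
            ploidy=1,
            population_size=N,
            sequence_length=L,
            recombination_rate=mu,  # comparable recombination and mutation rates
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        mts = msprime.sim_mutations(
            ts,
            rate=mu,
            random_seed=int(rng.integers(1, 2**31 - 1)),
            model=msprime.BinaryMutationModel(),
        )
        geno = mts.genotype_matrix().astype(np.int8)
        pos = np.array([int(s.position) + 1 for s in mts.sites()])
        # collapse duplicate integer positions (rare at these densities)
        keep = np.concatenate([[True], np.diff(pos) > 0])
        geno, pos = geno[keep], pos[keep]
    elif method == "fixed_s":
        a1 = sum(1.0 / i for i in range(1, n))
        S = int(round(config.theta * a1 * L))
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=min(S, L), replace=False))
        # neutral SFS: P(derived count = i) propto 1/i
        counts = np.arange(1, n)
        probs = (1.0 / counts) / np.sum(1.0 / counts)
        geno = np.zeros((pos.size, n), dtype=np.int8)
        for row in range(pos.size):
            c = rng.choice(counts, p=probs)
            geno[row, rng.choice(n, size=c, replace=False)] = 1
    elif method == "clonal":
        S = max(1, int(round(config.theta * L))) if config.theta > 0 else 200
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=min(S, L), replace=False))
        lineage = np.zeros(n, dtype=np.int8)
        lineage[n // 2 :] = 1
        geno = np.tile(lineage, (pos.size, 1))
    else:
        raise ValueError(f"unknown method {method!r}")

    m = pos.size
    info = pd.DataFrame(
        {
            "QD": rng.uniform(5, 30, m),
            "MQ": rng.uniform(50, 60, m),
            "FS": rng.uniform(0, 10, m),
            "MQRankSum": rng.normal(0, 1, m),
            "ReadPosRankSum": rng.normal(0, 1, m),
        }
    )
    if fail_fraction > 0 and m:
        bad = rng.random(m) < fail_fraction
        which = rng.integers(0, 3, m)
        info.loc[bad & (which == 0), "QD"] = 1.0
        info.loc[bad & (which == 1), "MQ"] = 30.0
        info.loc[bad & (which == 2), "FS"] = 80.0

    if out_vcf is not None:
        _write_vcf(Path(out_vcf), geno, pos, info, n, L, contig, config.seed)
    return geno, pos, info


def _write_vcf(
    path: Path,
    geno: np.ndarray,
    pos: np.ndarray,
    info,
    n: int,
    L: int,
    contig: str,
    seed: int,
) -> None:
    ref_alt = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    rng = np.random.default_rng(seed + 1)
    choice = rng.integers(0, 4, pos.size)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={L}>\n")
        for k, desc in (
            ("QD", "Quality by depth"),
            ("MQ", "RMS mapping quality"),
            ("FS", "Fisher strand bias"),
            ("MQRankSum", "Mapping quality rank sum"),
            ("ReadPosRankSum", "Read position rank sum"),
        ):
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{desc}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"s{i}" for i in range(n))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for row in range(pos.size):
            ref, alt = ref_alt[choice[row]]
            inf = ";".join(f"{k}={info.iloc[row][k]:.3f}" for k in info.columns)
            gts = "\t".join(str(int(g)) for g in geno[row])
            fh.write(f"{contig}\t{pos[row]}\t.\t{ref}\t{alt}\t100\tPASS\t{inf}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# MK count data
# ---------------------------------------------------------------------------

# fixed effects of the generating Poisson log-linear model (log scale); chosen
# to give realistic per-gene MK tables (PS ~ 5-15, DS ~ 25-60 for typical genes)
MK_MODEL_DEFAULTS = {
    "beta0": math.log(0.02),    # per-synonymous-site polymorphism rate
    "beta_r": math.log(0.6),    # average replacement deficit (background constraint)
    "beta_d": math.log(4.0),    # divergence/polymorphism ratio
    "beta_rd": 0.0,
    "sigma_u": 0.3,             # gene mutation-rate spread
    "sigma_s": 0.05,            # jitter on neutral selection effects (true value 0)
    "sigma_d": 0.2,             # gene-level divergence spread
}


def simulate_mk_counts(
    selection_spec: SelectionSpec,
    n_genes: int,
    seed: int,
    *,
    model: dict | None = None,
):
    """Draw per-gene (PS, PR, DS, DR) counts and site counts from the
    hierarchical Poisson log-linear model used for selection inference.

    Genes are assigned classes (positive / negative / neutral); positive genes
    get selection effect +effect, negative genes -effect, neutral genes draw
    from N(0, sigma_s). Returns a pandas DataFrame with columns
    gene_id, PS, PR, DS, DR, Lsyn, Lrep, true_class, true_selection_effect.
    """
    import pandas as pd

    if selection_spec.n_positive + selection_spec.n_negative > n_genes:
        raise ConfigError("selection_spec: planted classes exceed n_genes")
    if not math.isfinite(selection_spec.effect):
        raise ConfigError("selection_spec.effect must be finite")
    p = dict(MK_MODEL_DEFAULTS)
    if model:
        p.update(model)
    rng = np.random.default_rng(seed)

    classes = np.array(
        ["positive"] * selection_spec.n_positive
        + ["negative"] * selection_spec.n_negative
        + ["neutral"] * (n_genes - selection_spec.n_positive - selection_spec.n_negative)
    )
    rng.shuffle(classes)

    n_codons = rng.integers(200, 601, n_genes)
    lsyn = 0.75 * n_codons  # ~25% of positions synonymous under NG86-like counting
    lrep = 2.25 * n_codons
    u = rng.normal(0, p["sigma_u"], n_genes)
    d = rng.normal(0, p["sigma_d"], n_genes)
    s = rng.normal(0, p["sigma_s"], n_genes)
    s[classes == "positive"] = selection_spec.effect
    s[classes == "negative"] = -selection_spec.effect

    def mean(lsites, R, D):
        return np.exp(
            np.log(lsites)
            + p["beta0"]
            + p["beta_r"] * R
            + p["beta_d"] * D
            + p["beta_rd"] * R * D
            + u
            + s * R
            + d * D
        )

    mu_ps, mu_pr = mean(lsyn, 0, 0), mean(lrep, 1, 0)
    mu_ds, mu_dr = mean(lsyn, 0, 1), mean(lrep, 1, 1)
    if not np.all(mu_ps + mu_pr + mu_ds + mu_dr > 0):
        raise ConfigError("selection_spec/model: zero expected counts")
    df = pd.DataFrame(
        {
            "gene_id": [f"g{i:04d}" for i in range(n_genes)],
            "PS": rng.poisson(mu_ps),
            "PR": rng.poisson(mu_pr),
            "DS": rng.poisson(mu_ds),
            "DR": rng.poisson(mu_dr),
            "Lsyn": lsyn,
            "Lrep": lrep,
            "true_class": classes,
            "true_selection_effect": s,
        }
    )
    return df
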