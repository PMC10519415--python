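"""End-to-end orchestration: simulate -> match -> calibrate -> detect -> mask ->
scan -> popgen -> selection, with a manifest of every output file.

Configuration is a single YAML file; every numeric threshold used anywhere in
the pipeline is a named key with its default (identity 98%, length 7000 bp,
control min-match 1000 bp, post-mask minimum 500 bp, plot-merge minimum
35 kbp, LD window 15,000 bp with MAF 0.2, pruning r^2 0.2 in 1 kbp with MAF
0.05, MCMC 25,000/10,000/4). Reruns with the same config and seed reproduce
byte-identical outputs; the manifest records a sha256 per file so this is
checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align, htr, panel, popgen, selection, simulate

log = logging.getLogger("htrscan")

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "htrscan_out",
    "stages": {
        "simulate": True, "detect": True, "scan": True,
        "popgen": True, "selection": True,
    },
    "simulate": {
        "n_species": 2,
        "background_divergence": 0.12,
        "genome_length": 200_000,
        "n_strains_per_species": 5,
        "theta": 0.002,
        "te_density": 0.05,
        "n_genes": 50,
        "htrs": [
            {"length": 20_000, "identity": 0.995, "te_at_edges": True},
            {"length": 12_000, "identity": 0.99, "te_at_edges": False},
        ],
        "mk": {"n_genes": 200, "n_positive": 20, "n_negative": 20, "effect": 1.5},
    },
    "thresholds": {
        "identity": 98.0,
        "min_length": 7000,
        "control_min_match": 1000,
        "min_unmasked": 500,
        "min_merged": 35_000,
        "extremity_window": 1000,
    },
    "matcher": {"k": 15, "min_block": 1000, "max_gap": 1000},
    "popgen": {
        "ld_window": 15_000,
        "ld_maf": 0.2,
        "prune_r2": 0.2,
        "prune_window": 1000,
        "prune_maf": 0.05,
        "null_sims": 2000,
    },
    "selection": {"iterations": 25_000, "burn_in": 10_000, "thin": 4},
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    raw: dict
    path: Path | None = None

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls(raw=_deep_merge(DEFAULTS, user), path=Path(path))

    @classmethod
    def default(cls, **overrides) -> "RunConfig":
        return cls(raw=_deep_merge(DEFAULTS, overrides))

    def __getitem__(self, key):
        return self.raw[key]

    def validate(self) -> None:
        for key in ("genomes", "annotations", "vcfs", "trees"):
            p = self.raw.get("paths", {}).get(key)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured path does not exist: {key}={p}")

    def config_hash(self) -> str:
        # outdir is excluded: the same analysis into two directories is the
        # same analysis, and output hashes must agree between such runs
        hashed = {k: v for k, v in self.raw.items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(hashed, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _deep_merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> Path:
    with open(path, "w") as fh:
        fh.write(f"# htrscan seed={cfg['seed']} config={cfg.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages in dependency order; return the manifest.

    The manifest maps relative output path -> sha256 and is itself written to
    ``<outdir>/manifest.json``. A stage failure propagates after the partial
    manifest is written.
    """
    config.validate()
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict[str, str] = {}
    written: list[Path] = []

    def record(paths):
        for p in np.atleast_1d(paths):
            p = Path(p)
            manifest[str(p.relative_to(outdir))] = _sha256(p)
            written.append(p)

    try:
        stages = config["stages"]
        sim_cfg = config["simulate"]
        htr_specs = tuple(
            simulate.HTRSpec(
                length=h["length"],
                identity=h.get("identity", 0.995),
                recipients=tuple(h.get("recipients", (0, 1))),
                te_at_edges=h.get("te_at_edges", False),
            )
            for h in sim_cfg["htrs"]
        )
        scfg = simulate.SimulationConfig(
            seed=seed,
            n_species=sim_cfg["n_species"],
            background_divergence=sim_cfg["background_divergence"],
            genome_length=sim_cfg["genome_length"],
            n_strains_per_species=sim_cfg["n_strains_per_species"],
            theta=sim_cfg["theta"],
            htr_specs=htr_specs,
            te_density=sim_cfg["te_density"],
            n_genes=sim_cfg["n_genes"],
        )

        assemblies = annotations = truth = None
        if stages.get("simulate", True):
            log.info("stage simulate: %d species x %d strains, L=%d",
                     scfg.n_species, scfg.n_strains_per_species, scfg.genome_length)
            paneldir = outdir / "panel"
            assemblies, annotations, truth = simulate.simulate_panel(scfg, outdir=paneldir)
            record(sorted(paneldir.iterdir()))
            vcf = outdir / "species0.vcf"
            simulate.simulate_variants(scfg, out_vcf=vcf)
            record(vcf)
            mk_df = simulate.simulate_mk_counts(
                simulate.SelectionSpec(
                    n_positive=sim_cfg["mk"]["n_positive"],
                    n_negative=sim_cfg["mk"]["n_negative"],
                    effect=sim_cfg["mk"]["effect"],
                ),
                sim_cfg["mk"]["n_genes"],
                seed,
            )
            record(_write_tsv(mk_df, outdir / "mk_counts.tsv", config))

        consensus_list = []
        if stages.get("detect", True):
            if assemblies is None:
                raise ConfigError("detect stage requires the simulate stage in this run mode")
            thr_cfg = config["thresholds"]
            thresholds = htr.ThresholdSet(
                identity_threshold=thr_cfg["identity"],
                length_threshold=thr_cfg["min_length"],
            )
            ref_a, ref_b = "sp0_s0", "sp1_s0"
            strains_a = sorted(s for s in assemblies if s.startswith("sp0_"))
            strains_b = sorted(s for s in assemblies if s.startswith("sp1_"))
            pairs = [(a, b) for a in strains_a for b in strains_b]
            mk = config["matcher"]
            pair_matches = align.match_all_pairs(assemblies, pairs, **mk)
            lift = {
                s: align.anchor_match(assemblies[s], assemblies[ref],
                                      query_name=s, target_name=ref, **mk)
                for ref, grp in ((ref_a, strains_a), (ref_b, strains_b))
                for s in grp if s != ref
            }
            n_matches = sum(len(v) for v in pair_matches.values())
            candidates = htr.detect_candidates(
                pair_matches, thresholds,
                reference_a=ref_a, reference_b=ref_b, lift_to_reference=lift,
            )
            log.info("stage detect: %d matches in -> %d candidates out",
                     n_matches, len(candidates))
            cand_df = pd.DataFrame(
                {
                    "id": c.id,
                    "ref_a_start": c.species_a_interval[2],
                    "ref_a_end": c.species_a_interval[3],
                    "length": c.length,
                    "mean_identity": c.mean_identity,
                    "supporting_pairs": c.supporting_pairs,
                }
                for c in candidates
            )
            record(_write_tsv(cand_df, outdir / "candidates.tsv", config))

            te = [(s, e) for s, e, kind in annotations[ref_a] if kind == "TE"]
            consensus_list = htr.mask_and_filter(
                candidates, te, thr_cfg["min_unmasked"],
                reference_sequence=assemblies[ref_a],
                contig_length=len(assemblies[ref_a]),
            )
            log.info("stage mask: %d candidates in -> %d retained (min unmasked %d bp)",
                     len(candidates), len(consensus_list), thr_cfg["min_unmasked"])
            cons_df = pd.DataFrame(
                {
                    "id": c.id, "start": c.interval[2], "end": c.interval[3],
                    "length": c.length, "unmasked_length": c.unmasked_length,
                    "te_fraction": c.te_fraction, "mean_identity": c.mean_identity,
                }
                for c in consensus_list
            )
            record(_write_tsv(cons_df, outdir / "consensus_htrs.tsv", config))
            ext = htr.extremity_te_report(consensus_list, te, thr_cfg["extremity_window"])
            record(_write_tsv(ext, outdir / "extremities.tsv", config))
            with open(outdir / "consensus_htrs.fasta", "w") as fh:
                for c in consensus_list:
                    if c.sequence:
                        fh.write(f">{c.id}\n{c.sequence}\n")
            record(outdir / "consensus_htrs.fasta")

        if stages.get("scan", True) and consensus_list:
            pan = {sid: {f"{sid}_contig1": seq} for sid, seq in assemblies.items()}
            cons = {c.id: c.sequence for c in consensus_list if c.sequence}
            matrix = panel.panel_matrix(pan, cons, matcher_kwargs=config["matcher"])
            log.info("stage scan: %d genomes x %d HTRs", len(pan), len(cons))
            record(_write_tsv(matrix, outdir / "presence_matrix.tsv", config))

        if stages.get("popgen", True):
            vcf = outdir / "species0.vcf"
            vt, tallies = popgen.filter_vcf(vcf)
            log.info("stage popgen: VCF filter tallies %s", tallies)
            pg = config["popgen"]
            div = popgen.diversity(vt, null_sims=pg["null_sims"], seed=seed)
            div_df = pd.DataFrame(
                [
                    {
                        "pi": div.pi, "theta_w": div.theta_w, "S": div.S,
                        "tajima_d": div.tajima_d,
                        "d_null_lo": div.d_null_ci[0] if div.d_null_ci else np.nan,
                        "d_null_hi": div.d_null_ci[1] if div.d_null_ci else np.nan,
                        "n": div.n, "pi_se": div.pi_se, "theta_w_se": div.theta_w_se,
                    }
                ]
            )
            record(_write_tsv(div_df, outdir / "diversity.tsv", config))
            ld = popgen.ld_decay(vt, window=pg["ld_window"], maf_min=pg["ld_maf"])
            record(_write_tsv(ld, outdir / "ld_decay.tsv", config))
            pruned = popgen.ld_prune(
                vt, r2_max=pg["prune_r2"], window=pg["prune_window"],
                maf_min=pg["prune_maf"],
            )
            log.info("stage popgen: %d sites -> %d after pruning", vt.n_sites, pruned.n_sites)
            pruned_df = pd.DataFrame(
                {"contig": pruned.contigs, "position": pruned.positions}
            )
            record(_write_tsv(pruned_df, outdir / "pruned_sites.tsv", config))
            refs = simulate.reference_idiomorphs()
            calls = {
                sid: popgen.mating_type(seq, refs)[0]
                for sid, seq in (assemblies or {}).items()
            }
            if calls:
                record(_write_tsv(
                    pd.DataFrame(sorted(calls.items()), columns=["strain", "mating_type"]),
                    outdir / "mating_types.tsv", config,
                ))

        if stages.get("selection", True):
            mk_df = pd.read_csv(outdir / "mk_counts.tsv", sep="\t", comment="#")
            sel = config["selection"]
            calls, diag = selection.snipre_fit(
                mk_df,
                iterations=sel["iterations"], burn_in=sel["burn_in"],
                thin=sel["thin"], seed=seed,
            )
            log.info("stage selection: %d genes, classes %s",
                     len(calls),
                     pd.Series([c.classification for c in calls]).value_counts().to_dict())
            calls_df = pd.DataFrame(
                {
                    "gene_id": c.gene_id,
                    "selection_effect": c.selection_effect,
                    "ci_lo": c.ci95[0], "ci_hi": c.ci95[1],
                    "classification": c.classification,
                }
                for c in calls
            )
            record(_write_tsv(calls_df, outdir / "selection_calls.tsv", config))
    finally:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def summarize(outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Collect report tables from a completed run's output directory.

    Returns whichever of presence, diversity, selection-class and mating-type
    summaries the manifest's files allow; missing stages are noted with a
    warning rather than an error.
    """
    import warnings

    outdir = Path(outdir)
    out: dict[str, pd.DataFrame] = {}
    mapping = {
        "presence": "presence_matrix.tsv",
        "diversity": "diversity.tsv",
        "selection": "selection_calls.tsv",
        "mating_types": "mating_types.tsv",
    }
    for key, fname in mapping.items():
        p = outdir / fname
        if p.exists():
            out[key] = pd.read_csv(p, sep="\t", comment="#")
        else:
            warnings.warn(f"summary: {fname} absent; stage may have been disabled")
    if "presence" in out:
        wide = out["presence"].pivot_table(
            index="genome_id", columns="htr_id", values="fraction_present",
            observed=False,
        )
        out["presence_wide"] = wide
    if "selection" in out:
        out["selection_summary"] = (
            out["selection"]["classification"].value_counts().rename_axis("class").reset_index(name="n_genes")
        )
    return out
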