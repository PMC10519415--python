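"""Gene-level selection inference from polymorphism and divergence.

Per gene, a McDonald-Kreitman table is built from in-group and outgroup codon
alignments: synonymous and replacement (nonsynonymous) changes, each split
into polymorphic (segregating in the in-group) and fixed (in-group monomorphic,
outgroup consensus different). Synonymous/replacement site opportunities are
counted NG86-style (per-position fraction of synonymous one-step changes) and
averaged over sequences weighted by non-missing length.

Classification uses a hierarchical Bayesian Poisson log-linear model over all
genes: each of the four counts (PS, PR, DS, DR) is Poisson with

    log mean = log(site count) + b0 + bR*R + bD*D + bRD*R*D
               + u_g + s_g*R + d_g*D

where R/D indicate replacement and divergence cells, u_g is a gene-level
mutation-rate effect, d_g a gene-level divergence effect, and s_g the gene's
*selection effect* on replacement terms. Under neutrality replacement and
synonymous changes accumulate proportionally and s_g = 0; purifying selection
depresses replacement changes (s_g < 0) and positive selection elevates
replacement divergence (s_g > 0). A gene is called positive (negative) when
the 95% credible interval of s_g lies entirely above (below) zero. Fitting is
by Metropolis-within-Gibbs MCMC with weakly-informative normal priors on the
fixed effects and half-normal priors on the random-effect scales.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MKCounts",
    "SelectionCall",
    "mk_counts",
    "mk_fisher",
    "snipre_fit",
    "category_enrichment",
]

_STOPS = {"TAA", "TAG", "TGA"}
_CODON_CHARS = set("ACGT")


def _codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


_TRANSLATE = _codon_table()


def _is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and set(codon) <= _CODON_CHARS


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three one-step changes at ``pos`` that are synonymous."""
    aa = _TRANSLATE[codon]
    syn = 0
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if _TRANSLATE[alt] == aa:
            syn += 1
    return syn / 3.0


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, replacement) site counts of one codon, NG86-style."""
    lsyn = sum(_syn_fraction(codon, p) for p in range(3))
    return lsyn, 3.0 - lsyn


def codon_path_changes(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, replacement) change counts between two codons.

    All mutational paths changing one position at a time are enumerated;
    paths passing through a stop codon are excluded (unless all do), and
    counts are averaged over the remaining paths, so ties between pathways
    are split equally.
    """
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    path_counts = []
    for order in itertools.permutations(diff):
        cur = c1
        syn = rep = 0.0
        through_stop = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if _TRANSLATE[nxt] == "*" and nxt != c2:
                through_stop = True
            if _TRANSLATE[nxt] == _TRANSLATE[cur]:
                syn += 1
            else:
                rep += 1
            cur = nxt
        path_counts.append((syn, rep, through_stop))
    valid = [(s, r) for s, r, ts in path_counts if not ts] or [
        (s, r) for s, r, _ in path_counts
    ]
    syn = sum(s for s, _ in valid) / len(valid)
    rep = sum(r for _, r in valid) / len(valid)
    return syn, rep


@dataclass
class MKCounts:
    """Per-gene McDonald-Kreitman table with site-count opportunities."""

    gene_id: str
    PS: float
    PR: float
    DS: float
    DR: float
    Lsyn: float
    Lrep: float
    skipped_codons: int = 0

    def __post_init__(self) -> None:
        for f in ("PS", "PR", "DS", "DR", "Lsyn", "Lrep"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


def mk_counts(
    ingroup: Sequence[str],
    outgroup: Sequence[str],
    *,
    gene_id: str = "",
    warn_stop: bool = True,
) -> MKCounts:
    """Build the MK table for one gene from aligned coding sequences.

    ``ingroup`` and ``outgroup`` are aligned sequences of equal length
    divisible by 3. Codons containing gaps or ambiguity codes are skipped per
    sequence; a codon column needs >= 2 valid in-group codons and >= 1 valid
    outgroup codon to be scored. A column is polymorphic when the in-group
    segregates (outgroup state then ignored); fixed when the in-group is
    monomorphic and differs from the outgroup consensus.
    """
    if len(ingroup) < 2:
        raise ValueError("need >= 2 in-group sequences")
    if len(outgroup) < 1:
        raise ValueError("need >= 1 outgroup sequence")
    length = len(ingroup[0])
    if any(len(s) != length for s in list(ingroup) + list(outgroup)):
        raise ValueError("sequences must be aligned to equal length")
    if length % 3 != 0:
        raise ValueError("alignment length must be divisible by 3")

    seqs_in = [s.upper() for s in ingroup]
    seqs_out = [s.upper() for s in outgroup]
    PS = PR = DS = DR = 0.0
    skipped = 0
    # per-sequence site tallies for the weighted average
    per_seq_syn = np.zeros(len(seqs_in))
    per_seq_len = np.zeros(len(seqs_in))

    for cpos in range(0, length, 3):
        in_codons = []
        for si, s in enumerate(seqs_in):
            codon = s[cpos : cpos + 3]
            if not _is_valid_codon(codon):
                continue
            if _TRANSLATE[codon] == "*" and cpos < length - 3:
                if warn_stop:
                    warnings.warn(f"mid-sequence stop codon at {cpos} in {gene_id or 'gene'}")
                continue
            in_codons.append((si, codon))
        out_codons = [
            s[cpos : cpos + 3]
            for s in seqs_out
            if _is_valid_codon(s[cpos : cpos + 3]) and _TRANSLATE[s[cpos : cpos + 3]] != "*"
        ]
        if len(in_codons) < 2 or not out_codons:
            skipped += 1
            continue
        for si, codon in in_codons:
            lsyn, _ = codon_sites(codon)
            per_seq_syn[si] += lsyn
            per_seq_len[si] += 3.0

        counts: dict[str, int] = {}
        for _, c in in_codons:
            counts[c] = counts.get(c, 0) + 1
        variants = sorted(counts, key=lambda c: (-counts[c], c))
        if len(variants) > 1:
            major = variants[0]
            for minor in variants[1:]:
                syn, rep = codon_path_changes(major, minor)
                PS += syn
                PR += rep
        else:
            out_counts: dict[str, int] = {}
            for c in out_codons:
                out_counts[c] = out_counts.get(c, 0) + 1
            consensus = sorted(out_counts, key=lambda c: (-out_counts[c], c))[0]
            if consensus != variants[0]:
                syn, rep = codon_path_changes(variants[0], consensus)
                DS += syn
                DR += rep

    # weighted average of per-sequence site counts, weights = non-missing length
    w = per_seq_len
    if w.sum() > 0:
        lsyn = float(np.sum(per_seq_syn * w) / np.sum(w))
        lrep = float(np.sum((per_seq_len - per_seq_syn) * w) / np.sum(w))
    else:
        lsyn = lrep = 0.0
    return MKCounts(
        gene_id=gene_id, PS=PS, PR=PR, DS=DS, DR=DR,
        Lsyn=lsyn, Lrep=lrep, skipped_codons=skipped,
    )


def mk_fisher(mk: MKCounts, *, midp: bool = False) -> tuple[float, float]:
    """Neutrality index and two-sided exact conditional p for one MK table.

    NI = (PR/PS)/(DR/DS); NaN when any margin needed is zero. The exact test
    runs on the table rounded to integers. With ``midp`` the two-sided mid-p
    variant is returned: the exact conditional p is conservative because of
    the discreteness of the hypergeometric support, and the mid-p correction
    (half-weight on tables exactly as probable as the observed one) restores
    approximate uniformity under the null.
    """
    if mk.PS > 0 and mk.DS > 0 and mk.DR > 0:
        ni = (mk.PR / mk.PS) / (mk.DR / mk.DS)
    else:
        ni = float("nan")
    a, b = int(round(mk.PR)), int(round(mk.PS))
    c, d = int(round(mk.DR)), int(round(mk.DS))
    if not midp:
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
        return ni, p
    n1, n2, m = a + b, c + d, a + c
    lo, hi = max(0, m - n2), min(m, n1)
    support = np.arange(lo, hi + 1)
    probs = stats.hypergeom.pmf(support, n1 + n2, n1, m)
    p0 = stats.hypergeom.pmf(a, n1 + n2, n1, m)
    eq = np.abs(probs - p0) <= p0 * 1e-9
    p = float(probs[probs < p0 * (1 + 1e-9)].sum() - 0.5 * probs[eq].sum())
    return ni, min(max(p, 0.0), 1.0)


# ---------------------------------------------------------------------------
# hierarchical Bayesian Poisson log-linear fit
# ---------------------------------------------------------------------------


@dataclass
class SelectionCall:
    gene_id: str
    selection_effect: float  # posterior mean of s_g
    ci95: tuple[float, float]
    classification: str  # positive / negative / neutral
    converged: bool = True


_R = np.array([0.0, 1.0, 0.0, 1.0])  # PS, PR, DS, DR
_D = np.array([0.0, 0.0, 1.0, 1.0])


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential-scale-reduction statistic for one scalar chain."""
    half = x.size // 2
    chains = np.stack([x[:half], x[half : 2 * half]])
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W)) if W > 0 else float("nan")


def snipre_fit(
    tables: Sequence[MKCounts] | pd.DataFrame,
    *,
    iterations: int = 25_000,
    burn_in: int = 10_000,
    thin: int = 4,
    seed: int = 0,
    rhat_threshold: float = 1.1,
) -> tuple[list[SelectionCall], dict]:
    """Fit the hierarchical Poisson log-linear selection model by MCMC.

    Accepts MKCounts objects or a DataFrame with columns gene_id, PS, PR, DS,
    DR, Lsyn, Lrep. Runs ``iterations`` Metropolis-within-Gibbs sweeps,
    discards ``burn_in``, keeps every ``thin``-th draw, and classifies each
    gene by the 95% credible interval of its selection effect. Returns the
    calls and a diagnostics dict (posterior means of fixed effects and
    random-effect scales, split-chain R-hat per shared parameter, acceptance
    rates). Non-convergent parameters (R-hat above ``rhat_threshold``) set
    ``converged=False`` on every call and trigger a warning.
    """
    if isinstance(tables, pd.DataFrame):
        df = tables
        gene_ids = list(df["gene_id"])
        Y = df[["PS", "PR", "DS", "DR"]].to_numpy(float)
        lsyn = df["Lsyn"].to_numpy(float)
        lrep = df["Lrep"].to_numpy(float)
    else:
        gene_ids = [t.gene_id for t in tables]
        Y = np.array([[t.PS, t.PR, t.DS, t.DR] for t in tables], float)
        lsyn = np.array([t.Lsyn for t in tables], float)
        lrep = np.array([t.Lrep for t in tables], float)
    G = len(gene_ids)
    if G < 20:
        raise ValueError("need >= 20 genes for the hierarchical fit")
    if np.any(lsyn <= 0) or np.any(lrep <= 0):
        raise ValueError("site counts must be positive for every gene")
    Y = np.round(Y)

    off = np.empty((G, 4))
    off[:, 0] = off[:, 2] = np.log(lsyn)
    off[:, 1] = off[:, 3] = np.log(lrep)

    rng = np.random.default_rng(seed)
    X = np.stack([np.ones(4), _R, _D, _R * _D])  # (4 params, 4 cells)

    beta = np.zeros(4)
    # crude initialization from marginal rates
    beta[0] = math.log(max(Y[:, 0].mean() / np.exp(off[:, 0]).mean(), 1e-6))
    u = np.zeros(G)
    s = np.zeros(G)
    d = np.zeros(G)
    log_sig = np.log(np.array([0.3, 0.3, 0.3]))  # sigma_u, sigma_s, sigma_d

    def log_lam(beta, u, s, d):
        fixed = beta @ X  # (4,)
        return off + fixed[None, :] + u[:, None] + s[:, None] * _R[None, :] + d[:, None] * _D[None, :]

    def loglik_total(ll):
        return float(np.sum(Y * ll - np.exp(ll)))

    ll = log_lam(beta, u, s, d)
    cur_ll = loglik_total(ll)

    prop_beta = np.full(4, 0.05)
    prop_re = np.full(3, 0.2)  # u, s, d
    prop_sig = 0.1
    acc = {"beta": np.zeros(4), "re": np.zeros(3), "sig": np.zeros(3)}
    n_keep = (iterations - burn_in) // thin
    s_draws = np.empty((n_keep, G))
    shared_draws = {k: np.empty(n_keep) for k in
                    ("b0", "bR", "bD", "bRD", "sigma_u", "sigma_s", "sigma_d")}
    keep_i = 0

    beta_prior_sd = 5.0
    for it in range(iterations):
        # fixed effects, one at a time
        for j in range(4):
            prop = beta.copy()
            prop[j] += rng.normal(0, prop_beta[j])
            ll_new = log_lam(prop, u, s, d)
            new_ll = loglik_total(ll_new)
            dprior = (beta[j] ** 2 - prop[j] ** 2) / (2 * beta_prior_sd**2)
            if math.log(rng.random()) < new_ll - cur_ll + dprior:
                beta, ll, cur_ll = prop, ll_new, new_ll
                acc["beta"][j] += 1

        # gene-level random effects, vectorized per block
        sig = np.exp(log_sig)
        for which, (vec, mask, psd) in enumerate(
            (
                (u, np.ones(4), sig[0]),
                (s, _R, sig[1]),
                (d, _D, sig[2]),
            )
        ):
            eps = rng.normal(0, prop_re[which], G)
            ll_new = ll + eps[:, None] * mask[None, :]
            dll = np.sum(Y * (ll_new - ll) - (np.exp(ll_new) - np.exp(ll)), axis=1)
            dpr = (vec**2 - (vec + eps) ** 2) / (2 * psd**2)
            accept = np.log(rng.random(G)) < dll + dpr
            vec[accept] += eps[accept]
            ll[accept] = ll_new[accept]
            acc["re"][which] += accept.mean()
        cur_ll = loglik_total(ll)

        # random-effect scales: MH on log sigma, half-normal(1) prior on sigma
        for which, vec in enumerate((u, s, d)):
            cur = log_sig[which]
            prop = cur + rng.normal(0, prop_sig)
            def lp(lsig):
                sd = math.exp(lsig)
                return (
                    -G * lsig
                    - float(np.sum(vec**2)) / (2 * sd**2)
                    - sd**2 / 2.0  # half-normal(1) prior on sigma
                    + lsig  # Jacobian of the log transform
                )
            if math.log(rng.random()) < lp(prop) - lp(cur):
                log_sig[which] = prop
                acc["sig"][which] += 1

        # adapt proposal scales during burn-in
        if it < burn_in and (it + 1) % 200 == 0:
            win = it + 1
            for j in range(4):
                rate = acc["beta"][j] / win
                prop_beta[j] *= math.exp(0.5 * (rate - 0.3))
            for j in range(3):
                rate = acc["re"][j] / win
                prop_re[j] *= math.exp(0.5 * (rate - 0.3))

        if it >= burn_in and (it - burn_in) % thin == 0 and keep_i < n_keep:
            s_draws[keep_i] = s
            sig = np.exp(log_sig)
            for name, val in zip(
                ("b0", "bR", "bD", "bRD", "sigma_u", "sigma_s", "sigma_d"),
                (*beta, *sig),
            ):
                shared_draws[name][keep_i] = val
            keep_i += 1

    rhat = {k: _split_rhat(v) for k, v in shared_draws.items()}
    bad = [k for k, v in rhat.items() if not math.isnan(v) and v > rhat_threshold]
    converged = not bad
    if bad:
        warnings.warn(f"possible non-convergence (split R-hat > {rhat_threshold}): {bad}")

    lo = np.quantile(s_draws, 0.025, axis=0)
    hi = np.quantile(s_draws, 0.975, axis=0)
    mean = s_draws.mean(axis=0)
    calls = []
    for g in range(G):
        if lo[g] > 0:
            cls = "positive"
        elif hi[g] < 0:
            cls = "negative"
        else:
            cls = "neutral"
        calls.append(
            SelectionCall(
                gene_id=gene_ids[g],
                selection_effect=float(mean[g]),
                ci95=(float(lo[g]), float(hi[g])),
                classification=cls,
                converged=converged,
            )
        )
    diagnostics = {
        "posterior_means": {k: float(v.mean()) for k, v in shared_draws.items()},
        "rhat": rhat,
        "acceptance": {
            "beta": (acc["beta"] / iterations).tolist(),
            "random_effects": (acc["re"] / iterations).tolist(),
            "scales": (acc["sig"] / iterations).tolist(),
        },
        "n_samples": keep_i,
    }
    return calls, diagnostics


# ---------------------------------------------------------------------------
# functional-category enrichment
# ---------------------------------------------------------------------------


def category_enrichment(
    selected_genes: Sequence[str] | Mapping[str, str],
    categories: Mapping[str, str],
    universe: Sequence[str] | None = None,
    *,
    target_class: str = "positive",
) -> pd.DataFrame:
    """Fisher exact tests of category membership versus the selected gene set.

    ``selected_genes`` is either a plain gene set (e.g. genes inside HTRs) or
    a gene -> classification mapping from :func:`snipre_fit`, in which case
    genes whose class equals ``target_class`` form the selected set.
    ``categories`` maps gene -> COG category; the universe defaults to all
    categorized genes. Categories with no gene in the universe are omitted.
    Reports raw p and Benjamini-Hochberg q per category.
    """
    if not categories:
        raise ValueError("empty category map")
    if isinstance(selected_genes, Mapping):
        selected = {g for g, c in selected_genes.items() if c == target_class}
    else:
        selected = set(selected_genes)
    if universe is None:
        universe = list(categories)
    universe = [g for g in universe if g in categories]
    if not any(g in selected for g in universe):
        raise ValueError("category map covers no selected gene")
    rows = []
    for cat in sorted(set(categories[g] for g in universe)):
        in_cat = {g for g in universe if categories[g] == cat}
        a = len(in_cat & selected)
        b = len(selected) - a
        c = len(in_cat) - a
        dd = len(universe) - a - b - c
        res = stats.fisher_exact([[a, b], [c, dd]])
        rows.append({"category": cat, "selected_in": a, "selected_out": b,
                     "rest_in": c, "rest_out": dd,
                     "odds_ratio": float(res.statistic), "p": float(res.pvalue)})
    df = pd.DataFrame(rows)
    df["q"] = stats.false_discovery_control(df["p"].to_numpy())
    return df.sort_values("p").reset_index(drop=True)
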