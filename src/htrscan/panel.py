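"""Presence/identity scanning of consensus HTRs across a genome panel.

Each consensus HTR is aligned against every panel assembly; matches are kept
only if they (1) cover the entire HTR, (2) cover an entire contig of the
assembly with at least 1 kbp of matched bases, or (3) are larger than 10 kbp
and sit at the edge of a larger contig, with at most two such edge matches per
HTR. These rules discard spurious partial hits (mostly repeats) while keeping
genuine copies that assembly fragmentation has split across contigs.

Presence is the fraction of the HTR covered by the union of kept matches;
identity is matched bases over that union. Positions covered by more than one
kept match can optionally be treated as ambiguous and excluded from both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import MatchBlock, anchor_match

__all__ = [
    "PresenceRecord",
    "keep_matches",
    "presence_identity",
    "panel_matrix",
    "genome_size_regression",
]

RULE_FULL_HTR = "full_htr"
RULE_FULL_CONTIG = "full_contig"
RULE_CONTIG_EDGE = "contig_edge"


@dataclass
class PresenceRecord:
    genome_id: str
    htr_id: str
    fraction_present: float
    identity: float | None  # percent over matched bases; None when fraction = 0
    kept_matches: int
    rules_used: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_present <= 1.0):
            raise ValueError("fraction_present must lie in [0, 1]")
        if self.identity is not None and not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity must lie in [0, 100]")


def keep_matches(
    matches: Sequence[MatchBlock],
    htr_length: int,
    contig_lengths: Mapping[str, int],
    *,
    cover_fraction: float = 0.95,
    edge_min_block: int = 10_000,
    edge_distance: int = 1000,
    contig_min_matched: int = 1000,
    max_edge_matches: int = 2,
) -> list[tuple[MatchBlock, str]]:
    """Apply the three match-keeping rules to matches of one HTR (query) against
    one genome (target). Returns (match, rule) pairs.

    "Entire" HTR/contig coverage means >= ``cover_fraction`` of its span
    (alignment ends are often trimmed); "edge" means the match starts or ends
    within ``edge_distance`` bp of a contig terminus, on a contig longer than
    the HTR; at most ``max_edge_matches`` (the longest) edge matches count.
    """
    kept: list[tuple[MatchBlock, str]] = []
    edge_pool: list[MatchBlock] = []
    for m in matches:
        if m.target_name not in contig_lengths:
            raise KeyError(f"match references unknown contig {m.target_name!r}")
        clen = contig_lengths[m.target_name]
        if m.query_span >= cover_fraction * htr_length:
            kept.append((m, RULE_FULL_HTR))
        elif m.target_span >= cover_fraction * clen and m.matched_bases >= contig_min_matched:
            kept.append((m, RULE_FULL_CONTIG))
        elif (
            m.block_length > edge_min_block
            and clen > htr_length
            and (m.target_start <= edge_distance or m.target_end >= clen - edge_distance)
        ):
            edge_pool.append(m)
    edge_pool.sort(key=lambda m: (-m.block_length, m.query_start))
    kept.extend((m, RULE_CONTIG_EDGE) for m in edge_pool[:max_edge_matches])
    kept.sort(key=lambda t: (t[0].query_start, t[0].target_start))
    return kept


def presence_identity(
    kept: Sequence[tuple[MatchBlock, str]],
    htr_length: int,
    *,
    genome_id: str = "",
    htr_id: str = "",
    exclude_ambiguous: bool = False,
) -> PresenceRecord:
    """Fraction of the HTR covered by kept matches, and identity over the
    covered union. Overlapping match portions are counted once, attributed to
    the higher-identity match; with ``exclude_ambiguous`` they are instead
    excluded from both numerator and denominator.
    """
    if not kept:
        return PresenceRecord(genome_id, htr_id, 0.0, None, 0, ())
    # breakpoint sweep over HTR (query) coordinates
    edges = sorted({0, htr_length} | {m.query_start for m, _ in kept} | {m.query_end for m, _ in kept})
    union = 0
    matched = 0.0
    for s, e in zip(edges, edges[1:]):
        covering = [m for m, _ in kept if m.query_start <= s and m.query_end >= e]
        if not covering:
            continue
        if exclude_ambiguous and len(covering) > 1:
            continue
        union += e - s
        best = max(covering, key=lambda m: m.identity)
        matched += (e - s) * best.identity / 100.0
    if union == 0:
        return PresenceRecord(genome_id, htr_id, 0.0, None, len(kept), tuple(r for _, r in kept))
    return PresenceRecord(
        genome_id=genome_id,
        htr_id=htr_id,
        fraction_present=union / htr_length,
        identity=100.0 * matched / union,
        kept_matches=len(kept),
        rules_used=tuple(r for _, r in kept),
    )


def panel_matrix(
    panel: Mapping[str, Mapping[str, str]],
    consensus: Mapping[str, str],
    *,
    tree_path: str | None = None,
    matcher_kwargs: dict | None = None,
    exclude_ambiguous: bool = False,
) -> pd.DataFrame:
    """Scan every consensus HTR against every panel genome.

    ``panel`` maps genome id -> {contig name -> sequence}; ``consensus`` maps
    HTR id -> sequence. Returns a long-form DataFrame (genome_id, htr_id,
    fraction_present, identity, kept_matches). Genomes are ordered by the leaf
    order of ``tree_path`` (Newick) when given; leaf names must match genome
    ids exactly.
    """
    order = list(panel)
    if tree_path is not None:
        from Bio import Phylo

        tree = Phylo.read(tree_path, "newick")
        leaves = [t.name for t in tree.get_terminals()]
        missing = sorted(set(leaves) ^ set(panel))
        if missing:
            raise ValueError(f"tree leaves and genome ids differ: {missing}")
        order = leaves

    kw = dict(min_block=1000)
    kw.update(matcher_kwargs or {})
    rows = []
    for gid in order:
        contigs = panel[gid]
        clens = {name: len(seq) for name, seq in contigs.items()}
        for hid, hseq in consensus.items():
            matches: list[MatchBlock] = []
            for cname, cseq in contigs.items():
                matches.extend(
                    anchor_match(hseq, cseq, query_name=hid, target_name=cname, **kw)
                )
            kept = keep_matches(matches, len(hseq), clens)
            rec = presence_identity(
                kept, len(hseq), genome_id=gid, htr_id=hid,
                exclude_ambiguous=exclude_ambiguous,
            )
            rows.append(
                {
                    "genome_id": gid,
                    "htr_id": hid,
                    "fraction_present": rec.fraction_present,
                    "identity": rec.identity,
                    "kept_matches": rec.kept_matches,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["genome_id"] = pd.Categorical(df["genome_id"], categories=order, ordered=True)
    return df


def shared_htr_length(matrix: pd.DataFrame, htr_lengths: Mapping[str, int],
                      genome_species: Mapping[str, str],
                      presence_min: float = 0.5) -> pd.DataFrame:
    """Cumulative length of HTRs shared by each species pair (an HTR counts as
    present in a species when any strain shows fraction >= ``presence_min``)."""
    present: dict[str, set[str]] = {}
    for _, row in matrix.iterrows():
        if row["fraction_present"] >= presence_min:
            present.setdefault(genome_species[str(row["genome_id"])], set()).add(row["htr_id"])
    species = sorted(present)
    rows = []
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            shared = present[a] & present[b]
            rows.append(
                {
                    "species_a": a,
                    "species_b": b,
                    "n_shared": len(shared),
                    "total_length": sum(htr_lengths[h] for h in shared),
                }
            )
    return pd.DataFrame(rows)


def genome_size_regression(
    total_htr_length: Sequence[float],
    genome_sizes: Sequence[float],
) -> tuple[float, float, float]:
    """OLS of genome size on total kept-HTR length per genome.

    Returns (slope, intercept, adjusted R^2) with
    adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - 2).
    """
    x = np.asarray(total_htr_length, dtype=float)
    y = np.asarray(genome_sizes, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 genomes")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in predictor")
    from scipy import stats

    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(res.slope), float(res.intercept), float(adj)
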