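"""Horizontally transferred region (HTR) detection between two focal species.

The method proceeds in four stages:

1. **Calibration** — thresholds are derived from a control comparison between
   non-focal sister species, where any long, highly similar region must be
   vertical: the identity threshold is the floor of the highest control
   identity among matches of at least ``min_match`` bp, and the length
   threshold is the second-longest such near-identical control match rounded
   up to the nearest 100 bp. The rationale is that similarity/length
   combinations beyond anything seen between ordinary sister species cannot
   plausibly arise by vertical descent.
2. **Detection** — inter-species matches passing both thresholds are projected
   onto each species' reference strain and single-linkage merged into
   candidates.
3. **Masking** — transposable-element intervals are subtracted; candidates
   whose unmasked residue falls below 500 bp are discarded (repeats alone can
   produce spurious high-identity matches).
4. **Characterization** — TE context of each candidate extremity, and a
   coarser overlap-merge used for genome-wide plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import MatchBlock

__all__ = [
    "ThresholdSet",
    "HTRCandidate",
    "HTRConsensus",
    "calibrate_thresholds",
    "detect_candidates",
    "mask_and_filter",
    "extremity_te_report",
    "merge_for_plotting",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdSet:
    """Identity/length thresholds with the control values that produced them."""

    identity_threshold: float  # percent
    length_threshold: int  # bp
    max_control_identity: float | None = None
    longest_control_match: int | None = None
    second_longest_control_match: int | None = None
    underpowered: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.identity_threshold <= 100):
            raise ValueError("identity_threshold must lie in (0, 100]")
        if self.length_threshold <= 0:
            raise ValueError("length_threshold must be positive")


@dataclass
class HTRCandidate:
    """A merged inter-species candidate region, on reference coordinates."""

    id: str
    species_a_interval: tuple[str, str, int, int]  # (strain, contig, start, end)
    species_b_interval: tuple[str, str, int, int]
    length: int
    mean_identity: float
    supporting_pairs: int


@dataclass
class HTRConsensus:
    """A TE-masked candidate with its representative (reference) sequence."""

    id: str
    interval: tuple[str, str, int, int]
    length: int
    te_masked_intervals: list[tuple[int, int]]  # relative to HTR start, half-open
    unmasked_length: int
    te_fraction: float
    mean_identity: float
    sequence: str | None = None
    member_genes: list[str] = field(default_factory=list)


def calibrate_thresholds(
    control_matches: Sequence[MatchBlock],
    min_match: int = 1000,
) -> ThresholdSet:
    """Derive (identity, length) thresholds from a control species comparison.

    ``identity_threshold`` = floor of the maximum identity among control
    matches of length >= ``min_match``. Among control matches at or above that
    identity, ``length_threshold`` = the second-longest length rounded up to
    the nearest 100 bp (longest if fewer than two qualify, flagged
    ``underpowered``).
    """
    long_enough = [m for m in control_matches if m.block_length >= min_match]
    if not long_enough:
        raise CalibrationError(
            f"no control matches of length >= {min_match} bp; "
            "supply a larger control match set"
        )
    max_ident = max(m.identity for m in long_enough)
    ident_thr = float(math.floor(max_ident))
    near = sorted(
        (m.block_length for m in long_enough if m.identity >= ident_thr),
        reverse=True,
    )
    underpowered = len(near) < 2
    ref_len = near[0] if underpowered else near[1]
    len_thr = int(math.ceil(ref_len / 100.0) * 100)
    return ThresholdSet(
        identity_threshold=ident_thr,
        length_threshold=len_thr,
        max_control_identity=max_ident,
        longest_control_match=near[0],
        second_longest_control_match=None if underpowered else near[1],
        underpowered=underpowered,
    )


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals (any overlap >= 1 bp merges)."""
    ivs = sorted(ivs)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _interval_union_length(ivs: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in _merge_intervals(ivs))


def _lift_interval(
    interval: tuple[int, int],
    lift_blocks: Sequence[MatchBlock],
) -> tuple[str, int, int] | None:
    """Lift a (start, end) interval on a non-reference strain onto the
    reference via the strain-vs-reference match blocks (gapless offset map).

    Returns (target_contig, start, end) of the overlapping portion, or None
    if no lift block covers at least half of the interval.
    """
    s, e = interval
    best = None
    best_cov = 0
    for b in lift_blocks:
        if b.strand != "+":
            continue
        cov = min(e, b.query_end) - max(s, b.query_start)
        if cov > best_cov:
            best_cov = cov
            best = b
    if best is None or best_cov < (e - s) / 2:
        return None
    off = best.target_start - best.query_start
    return (
        best.target_name,
        max(best.target_start, s + off),
        min(best.target_end, e + off),
    )


def detect_candidates(
    pair_matches: Mapping[tuple[str, str], Sequence[MatchBlock]],
    thresholds: ThresholdSet,
    *,
    reference_a: str,
    reference_b: str,
    lift_to_reference: Mapping[str, Sequence[MatchBlock]] | None = None,
) -> list[HTRCandidate]:
    """Detect candidate HTRs from inter-species strain-pair matches.

    ``pair_matches`` maps (strain_of_species_a, strain_of_species_b) to the
    match blocks between them, with the species-A strain as query. Matches
    passing both thresholds are projected onto the two reference strains
    (directly when the strain is the reference, otherwise lifted through
    ``lift_to_reference``, which maps a non-reference strain id to its match
    blocks against its own species' reference). Projected intervals are
    single-linkage merged (any overlap) on reference-A coordinates; candidate
    identity is the matched-bases-weighted mean over contributing matches.

    Unliftable matches are counted and excluded; the count is attached to the
    returned list as the attribute ``unlifted`` (informational).
    """
    if not reference_a or not reference_b:
        raise ValueError("both species must designate a reference strain")

    kept: list[tuple] = []  # (a_iv, b_iv, contig_a, contig_b, block, pair)
    unlifted = 0
    for (sa, sb), matches in pair_matches.items():
        for m in matches:
            if m.block_length < thresholds.length_threshold:
                continue
            if m.identity < thresholds.identity_threshold:
                continue
            a_iv: tuple[int, int] | None = (m.query_start, m.query_end)
            b_iv: tuple[int, int] | None = (m.target_start, m.target_end)
            contig_a, contig_b = m.query_name, m.target_name
            if sa != reference_a:
                lifted = _lift_interval(a_iv, (lift_to_reference or {}).get(sa, ()))
                a_iv, contig_a = ((lifted[1], lifted[2]), lifted[0]) if lifted else (None, "")
            if sb != reference_b:
                lifted = _lift_interval(b_iv, (lift_to_reference or {}).get(sb, ()))
                b_iv, contig_b = ((lifted[1], lifted[2]), lifted[0]) if lifted else (None, "")
            if a_iv is None or b_iv is None:
                unlifted += 1
                continue
            kept.append((a_iv, b_iv, contig_a, contig_b, m, (sa, sb)))

    # single-linkage merge of projected reference-A intervals
    kept.sort(key=lambda t: t[0])
    clusters: list[list] = []
    for item in kept:
        (s, e) = item[0]
        if clusters and s < max(iv[0][1] for iv in clusters[-1]):
            clusters[-1].append(item)
        else:
            clusters.append([item])

    candidates = []
    for members in clusters:
        a_s = min(iv[0][0] for iv in members)
        a_e = max(iv[0][1] for iv in members)
        b_s = min(iv[1][0] for iv in members)
        b_e = max(iv[1][1] for iv in members)
        w = sum(m.matched_bases for *_, m, _ in members)
        ident = sum(m.identity * m.matched_bases for *_, m, _ in members) / w
        pairs = {pair for *_, pair in members}
        contig_a = members[0][2]
        contig_b = members[0][3]
        candidates.append(
            HTRCandidate(
                id="",
                species_a_interval=(reference_a, contig_a, a_s, a_e),
                species_b_interval=(reference_b, contig_b, b_s, b_e),
                length=a_e - a_s,
                mean_identity=ident,
                supporting_pairs=len(pairs),
            )
        )

    # ids by descending length, ties by reference coordinate
    candidates.sort(key=lambda c: (-c.length, c.species_a_interval[2]))
    for i, c in enumerate(candidates, start=1):
        c.id = f"HTR{i}"
    return candidates


# ---------------------------------------------------------------------------
# TE masking
# ---------------------------------------------------------------------------


def mask_and_filter(
    candidates: Sequence[HTRCandidate],
    te_annotation: Sequence[tuple[int, int]],
    min_unmasked: int = 500,
    *,
    reference_sequence: str | None = None,
    contig_length: int | None = None,
    warn=None,
) -> list[HTRConsensus]:
    """Subtract TE intervals from candidates; drop those with < ``min_unmasked``
    bp left. TE intervals are on the same (reference-A) coordinate system as
    the candidates; intervals extending beyond the contig are clipped with a
    warning. The representative sequence is the reference strain's subsequence.
    """
    te = list(te_annotation)
    if contig_length is not None:
        clipped = []
        for s, e in te:
            if s < 0 or e > contig_length:
                if warn:
                    warn(f"TE interval [{s},{e}) outside contig; clipped")
                s, e = max(0, s), min(contig_length, e)
            if s < e:
                clipped.append((s, e))
        te = clipped
    te = _merge_intervals(te)

    out = []
    for c in candidates:
        strain, contig, s, e = c.species_a_interval
        local = [(max(ts, s) - s, min(te_, e) - s) for ts, te_ in te if ts < e and te_ > s]
        masked = _interval_union_length(local)
        unmasked = c.length - masked
        if unmasked < min_unmasked:
            continue
        out.append(
            HTRConsensus(
                id=c.id,
                interval=c.species_a_interval,
                length=c.length,
                te_masked_intervals=_merge_intervals(local),
                unmasked_length=unmasked,
                te_fraction=masked / c.length if c.length else 0.0,
                mean_identity=c.mean_identity,
                sequence=reference_sequence[s:e] if reference_sequence else None,
            )
        )
    return out


def extremity_te_report(
    consensus: Sequence[HTRConsensus],
    te_annotation: Sequence[tuple[int, int]],
    window: int = 1000,
):
    """TE context of each HTR extremity (two per HTR, on reference coords).

    Returns a pandas DataFrame with one row per extremity: whether the
    terminal base lies inside a TE, and the distance to the nearest TE
    (``inf`` when no TE exists on the contig); plus summary attributes
    ``frac_in_te`` and ``n_within_window`` in ``df.attrs``.
    """
    import pandas as pd

    te = _merge_intervals(te_annotation)
    rows = []
    for c in consensus:
        _, contig, s, e = c.interval
        for side, base in (("left", s), ("right", e - 1)):
            in_te = any(ts <= base < te_ for ts, te_ in te)
            if te:
                dist = min(
                    0 if ts <= base < te_ else min(abs(base - (te_ - 1)), abs(ts - base))
                    for ts, te_ in te
                )
            else:
                dist = math.inf
            rows.append(
                {
                    "htr_id": c.id,
                    "side": side,
                    "in_te": in_te,
                    "nearest_te_distance": dist,
                    "within_window": dist <= window,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df.attrs["frac_in_te"] = float(df["in_te"].mean())
        df.attrs["n_within_window"] = int(df["within_window"].sum())
    return df


def merge_for_plotting(
    consensus: Sequence[HTRConsensus],
    min_merged: int = 35_000,
) -> list[tuple[int, int]]:
    """Overlap-merge consensus HTR intervals, keep merged regions of at least
    ``min_merged`` bp (used as queries for genome-wide similarity plotting).
    """
    ivs = [(c.interval[2], c.interval[3]) for c in consensus]
    return [(s, e) for s, e in _merge_intervals(ivs) if e - s >= min_merged]
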