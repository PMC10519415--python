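"""Pairwise local-alignment matches: the PAF interface and a built-in anchor matcher.

All horizontal-transfer logic downstream consumes :class:`MatchBlock` objects, one
per local alignment between two sequences. Blocks can be read from standard PAF
(e.g. minimap2 ``-cx asm20`` output) or produced by :func:`anchor_match`, a
seed-and-extend k-mer matcher sufficient for assemblies whose differences are
substitutions rather than large rearrangements.

Coordinates are 0-based half-open on both query and target. Matches on the
reverse strand are normalized so target coordinates ascend; the strand flag is
retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["MatchBlock", "PafError", "read_paf", "write_paf", "anchor_match"]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PafError(ValueError):
    """Raised for malformed PAF input; carries the offending line number."""


@dataclass(frozen=True)
class MatchBlock:
    """One pairwise local-alignment match.

    ``identity`` is the percentage of matching bases over the block length —
    the number of matching bases divided by the aligned length, times 100.
    """

    query_name: str
    query_start: int
    query_end: int
    query_length: int
    target_name: str
    target_start: int
    target_end: int
    target_length: int
    strand: str
    matched_bases: int
    block_length: int

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_length):
            raise ValueError(
                f"query interval [{self.query_start}, {self.query_end}) invalid "
                f"for length {self.query_length}"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_length):
            raise ValueError(
                f"target interval [{self.target_start}, {self.target_end}) invalid "
                f"for length {self.target_length}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.matched_bases > self.block_length:
            raise ValueError("matched_bases exceeds block_length")
        if self.block_length <= 0:
            raise ValueError("block_length must be positive")

    @property
    def identity(self) -> float:
        """Percent identity: 100 * matched bases / block length."""
        return 100.0 * self.matched_bases / self.block_length

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    def swapped(self) -> "MatchBlock":
        """The same match with query and target roles exchanged."""
        return MatchBlock(
            query_name=self.target_name,
            query_start=self.target_start,
            query_end=self.target_end,
            query_length=self.target_length,
            target_name=self.query_name,
            target_start=self.query_start,
            target_end=self.query_end,
            target_length=self.query_length,
            strand=self.strand,
            matched_bases=self.matched_bases,
            block_length=self.block_length,
        )


def read_paf(path: str | Path) -> list[MatchBlock]:
    """Parse a PAF file into MatchBlocks (12 mandatory columns; tags ignored)."""
    blocks: list[MatchBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise PafError(
                    f"line {lineno}: expected >=12 tab-separated columns, got {len(fields)}"
                )
            try:
                blocks.append(
                    MatchBlock(
                        query_name=fields[0],
                        query_length=int(fields[1]),
                        query_start=int(fields[2]),
                        query_end=int(fields[3]),
                        strand=fields[4],
                        target_name=fields[5],
                        target_length=int(fields[6]),
                        target_start=int(fields[7]),
                        target_end=int(fields[8]),
                        matched_bases=int(fields[9]),
                        block_length=int(fields[10]),
                    )
                )
            except ValueError as exc:
                raise PafError(f"line {lineno}: {exc}") from exc
    return blocks


def write_paf(blocks: Iterable[MatchBlock], path: str | Path) -> None:
    """Write MatchBlocks as 12-column PAF (mapping quality column fixed at 60)."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        b.query_name,
                        b.query_length,
                        b.query_start,
                        b.query_end,
                        b.strand,
                        b.target_name,
                        b.target_length,
                        b.target_start,
                        b.target_end,
                        b.matched_bases,
                        b.block_length,
                        60,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Built-in seed-and-extend matcher
# ---------------------------------------------------------------------------


_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 integer code of every k-mer (Horner scheme) and a validity mask
    (False where the window contains a non-ACGT base)."""
    n = arr.size - k + 1
    codes = arr[:n].astype(np.int64)
    for j in range(1, k):
        codes = codes * 4 + arr[j : j + n]
    bad = np.concatenate([[0], np.cumsum(arr >= 4)])
    valid = (bad[k:] - bad[:-k]) == 0
    return codes, valid


def _shared_seeds(qarr: np.ndarray, tarr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All (query_pos, target_pos) pairs sharing an exact k-mer."""
    qcodes, qvalid = _kmer_codes(qarr, k)
    tcodes, tvalid = _kmer_codes(tarr, k)
    qpos = np.flatnonzero(qvalid)
    tpos = np.flatnonzero(tvalid)
    qc, tc = qcodes[qpos], tcodes[tpos]
    order = np.argsort(qc, kind="stable")
    qc_sorted, qpos_sorted = qc[order], qpos[order]
    left = np.searchsorted(qc_sorted, tc, side="left")
    right = np.searchsorted(qc_sorted, tc, side="right")
    counts = right - left
    hit = counts > 0
    starts, cnt, tp = left[hit], counts[hit], tpos[hit]
    total = int(cnt.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    base = np.repeat(np.cumsum(cnt) - cnt, cnt)
    idx = np.repeat(starts, cnt) + (np.arange(total) - base)
    return qpos_sorted[idx], np.repeat(tp, cnt)


def _chains_from_seeds(
    qp: np.ndarray, tp: np.ndarray, k: int, max_gap: int
) -> list[tuple[int, int, int, int]]:
    """Group co-diagonal seeds into chains; a gap > max_gap on the query
    starts a new chain. Returns (qstart, qend, tstart, tend)."""
    diag = qp - tp
    order = np.lexsort((qp, diag))
    dq, dd = qp[order], diag[order]
    breaks = np.flatnonzero((np.diff(dd) != 0) | (np.diff(dq) > max_gap)) + 1
    bounds = np.concatenate([[0], breaks, [dq.size]])
    chains = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        qs, qe = int(dq[s]), int(dq[e - 1]) + k
        d = int(dd[s])
        chains.append((qs, qe, qs - d, qe - d))
    return chains


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def anchor_match(
    query: str,
    target: str,
    *,
    k: int = 15,
    min_block: int = 1000,
    max_gap: int = 1000,
    query_name: str = "query",
    target_name: str = "target",
) -> list[MatchBlock]:
    """Seed-and-extend gapless matching between two sequences.

    Exact k-mers shared between query and target (both strands) are chained
    along diagonals; each chain becomes a block whose identity is computed by
    direct column comparison of the two induced substrings. Blocks shorter
    than ``min_block`` are suppressed. Overlapping blocks on the query are
    resolved by keeping the block with the most matched bases (ties broken by
    leftmost query coordinate).

    Suited to assemblies that differ by substitutions (no indel model); for
    divergent or rearranged genomes use an external aligner and feed its PAF
    through :func:`read_paf`.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    if k < 11:
        raise ValueError("k must be >= 11")
    if k > min(len(query), len(target)):
        raise ValueError("k exceeds a sequence length")

    query = query.upper()
    target = target.upper()
    qarr = _encode(query)

    raw_blocks: list[MatchBlock] = []
    for strand, tseq in (("+", target), ("-", revcomp(target))):
        tarr = _encode(tseq)
        qp, tp = _shared_seeds(qarr, tarr, k)
        if qp.size == 0:
            continue
        for qs, qe, ts, te in _chains_from_seeds(qp, tp, k, max_gap):
            if qe - qs < min_block:
                continue
            qwin, twin = qarr[qs:qe], tarr[ts:te]
            matched = int(np.sum((qwin == twin) & (qwin < 4)))
            if strand == "-":
                # map back to forward-strand target coordinates (ascending)
                ts, te = len(target) - te, len(target) - ts
            raw_blocks.append(
                MatchBlock(
                    query_name=query_name,
                    query_start=qs,
                    query_end=qe,
                    query_length=len(query),
                    target_name=target_name,
                    target_start=ts,
                    target_end=te,
                    target_length=len(target),
                    strand=strand,
                    matched_bases=matched,
                    block_length=qe - qs,
                )
            )

    # resolve query-overlapping candidates: most matched bases wins, leftmost on tie
    raw_blocks.sort(key=lambda b: (-b.matched_bases, b.query_start, b.target_start))
    kept: list[MatchBlock] = []
    for b in raw_blocks:
        shadowed = any(
            _overlap(b.query_start, b.query_end, o.query_start, o.query_end)
            > 0.5 * min(b.query_span, o.query_span)
            and _overlap(b.target_start, b.target_end, o.target_start, o.target_end)
            > 0.5 * min(b.target_span, o.target_span)
            for o in kept
        )
        if not shadowed:
            kept.append(b)
    kept.sort(key=lambda b: (b.query_start, b.target_start))
    return kept


def match_all_pairs(
    sequences: dict[str, str],
    pairs: Sequence[tuple[str, str]],
    *,
    k: int = 15,
    min_block: int = 1000,
    max_gap: int = 1000,
) -> dict[tuple[str, str], list[MatchBlock]]:
    """Run :func:`anchor_match` over the named sequence pairs."""
    out = {}
    for a, b in pairs:
        out[(a, b)] = anchor_match(
            sequences[a], sequences[b], k=k, min_block=min_block, max_gap=max_gap,
            query_name=a, target_name=b,
        )
    return out
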