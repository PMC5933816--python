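"""Sliding-window candidate extraction and domain-hit boundary estimation.

A genome is tiled with fixed-length overlapping windows. Windows carrying a
hit in their shared overlap region are merged (transitively) so an element
straddling window boundaries yields a single candidate. Each merged region
is then partitioned by strand, de-duplicated, and trimmed so a candidate
runs from the start of its first hit to the end of its last hit. Windows
without hits produce no candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from .config import RunConfig
from .errors import ConsistencyError
from .io import DomainHit, GenomeSequence

logger = logging.getLogger(__name__)

_STRAND_ORDER = {"+": 0, "-": 1}


@dataclass(frozen=True)
class WindowSpec:
    seq_id: str
    start: int
    end: int
    index: int


@dataclass(frozen=True)
class CandidateTE:
    """A genomic candidate: boundary-trimmed region carrying single-strand hits."""

    candidate_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    hits: tuple[DomainHit, ...]

    def __post_init__(self) -> None:
        if not self.hits:
            raise ConsistencyError(f"candidate {self.candidate_id} has no hits")
        strands = {h.strand for h in self.hits}
        if strands != {self.strand}:
            raise ConsistencyError(
                f"candidate {self.candidate_id} mixes strands {sorted(strands)}"
            )
        if self.start != min(h.start for h in self.hits) or self.end != max(
            h.end for h in self.hits
        ):
            raise ConsistencyError(
                f"candidate {self.candidate_id} boundaries not trimmed to its hits"
            )

    def oriented_hits(self) -> tuple[DomainHit, ...]:
        """Hits in element-local coordinates, 5'->3' on the element strand.

        For a minus-strand candidate the element is read right-to-left, so
        hit intervals are mirrored about the candidate; hit order and
        lengths are preserved in the element's own reading frame.
        """
        if self.strand == "+":
            local = [replace(h, start=h.start - self.start, end=h.end - self.start)
                     for h in self.hits]
        else:
            local = [replace(h, start=self.end - h.end, end=self.end - h.start)
                     for h in self.hits]
        return tuple(sorted(local, key=lambda h: (h.start, h.end, h.subject_id)))


def window_genome(genome: GenomeSequence, cfg: RunConfig) -> list[WindowSpec]:
    """Tile one sequence with overlapping windows (step = length - overlap)."""
    n = len(genome)
    if n == 0:
        return []
    windows: list[WindowSpec] = []
    start = 0
    index = 0
    while True:
        end = min(start + cfg.window_length, n)
        windows.append(WindowSpec(genome.seq_id, start, end, index))
        if end >= n:
            break
        start += cfg.window_step
        index += 1
    return windows


def _dedup_key(hit: DomainHit):
    return (hit.subject_id, hit.start, hit.end, hit.strand)


def build_candidates(
    windows: Sequence[WindowSpec],
    hits: Sequence[DomainHit],
    cfg: RunConfig,
) -> list[CandidateTE]:
    """Turn genome-coordinate hits plus the window tiling into candidates.

    Duplicate hits (the same genomic match reported from two overlapping
    windows) are collapsed; consecutive windows with a hit intersecting
    their shared overlap are merged transitively; each merged region yields
    one candidate per strand, trimmed to its first/last hit.
    """
    by_seq: dict[str, list[WindowSpec]] = {}
    for w in windows:
        by_seq.setdefault(w.seq_id, []).append(w)
    for seq_windows in by_seq.values():
        seq_windows.sort(key=lambda w: w.start)

    unique: dict[tuple, DomainHit] = {}
    for h in hits:
        unique.setdefault((h.source_seq,) + _dedup_key(h), h)
    deduped = list(unique.values())

    for h in deduped:
        if h.end - h.start >= cfg.window_overlap:
            logger.warning(
                "hit %s at %s:%d-%d is longer than the window overlap (%d nt); "
                "merging across windows may miss it",
                h.subject_id, h.source_seq, h.start + 1, h.end, cfg.window_overlap,
            )

    hits_per_window: dict[tuple[str, int], list[DomainHit]] = {}
    for h in deduped:
        seq_windows = by_seq.get(h.source_seq)
        if not seq_windows:
            raise ConsistencyError(
                f"hit {h.subject_id} on {h.source_seq!r} lies outside every window"
            )
        touched = [w for w in seq_windows if h.start < w.end and h.end > w.start]
        if not touched:
            raise ConsistencyError(
                f"hit {h.subject_id} at {h.source_seq}:{h.start + 1}-{h.end} "
                "lies outside every window"
            )
        for w in touched:
            hits_per_window.setdefault((w.seq_id, w.index), []).append(h)

    candidates: list[CandidateTE] = []
    for seq_id, seq_windows in sorted(by_seq.items()):
        occupied = [w for w in seq_windows if (seq_id, w.index) in hits_per_window]
        if not occupied:
            continue
        # transitively merge consecutive windows sharing a hit in their overlap
        groups: list[list[WindowSpec]] = [[occupied[0]]]
        for w in occupied[1:]:
            prev = groups[-1][-1]
            consecutive = w.index == prev.index + 1
            merged = False
            if consecutive:
                ov_start, ov_end = w.start, prev.end
                for h in hits_per_window[(seq_id, prev.index)]:
                    if h.start < ov_end and h.end > ov_start:
                        merged = True
                        break
            if merged:
                groups[-1].append(w)
            else:
                groups.append([w])

        for group in groups:
            group_hits: dict[tuple, DomainHit] = {}
            for w in group:
                for h in hits_per_window[(seq_id, w.index)]:
                    group_hits[_dedup_key(h)] = h
            per_strand: dict[str, list[DomainHit]] = {}
            for h in group_hits.values():
                per_strand.setdefault(h.strand, []).append(h)
            for strand in sorted(per_strand, key=_STRAND_ORDER.get):
                strand_hits = tuple(
                    sorted(per_strand[strand], key=lambda h: (h.start, h.end, h.subject_id))
                )
                start = min(h.start for h in strand_hits)
                end = max(h.end for h in strand_hits)
                wid = (
                    f"w{group[0].index}" if len(group) == 1
                    else f"w{group[0].index}-w{group[-1].index}"
                )
                candidate_id = f"{seq_id}:{wid}:{start + 1}-{end}:{strand}"
                candidates.append(
                    CandidateTE(candidate_id, seq_id, start, end, strand, strand_hits)
                )
    candidates.sort(key=lambda c: (c.seq_id, c.start, c.end, _STRAND_ORDER[c.strand]))
    return candidates
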