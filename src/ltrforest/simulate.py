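"""Synthetic genomes, hit tables and training corpora.

The simulator's contract is hit-level realism: per-superfamily domain
architectures (identity, order, length), log-uniform e-values, dropout and
spurious-hit noise, and genomic placement on both strands. Background
residues are i.i.d. uniform nucleotides; no sequence-level homology is
modelled, so no external domain scanner is needed anywhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .io import AnnotationRecord, DomainHit, GenomeSequence

_ALPHABET = np.array(list("ACGT"))

#: Spurious hits are always weak so learned e-value ceilings stay meaningful.
SPURIOUS_LOG10E_RANGE = (-3.0, 0.0)


@dataclass(frozen=True)
class DomainBlock:
    general: str
    subdomain: str
    length_range: tuple[int, int] = (150, 600)
    log10_evalue_range: tuple[float, float] = (-45.0, -8.0)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Generative model of one superfamily's domain architecture."""

    label: str
    blocks: tuple[DomainBlock, ...]
    gap_range: tuple[int, int] = (50, 300)
    minus_strand_prob: float = 0.0
    dropout: float = 0.0
    spurious_per_kb: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.minus_strand_prob <= 1.0:
            raise ConfigurationError("minus_strand_prob must lie in [0, 1]")
        if not 0.0 <= self.dropout <= 1.0:
            raise ConfigurationError("dropout must lie in [0, 1]")
        if self.spurious_per_kb < 0:
            raise ConfigurationError("spurious_per_kb must be non-negative")
        for lo, hi in [self.gap_range] + [b.length_range for b in self.blocks]:
            if lo <= 0 or hi < lo:
                raise ConfigurationError("ranges must be positive and ordered")


def default_specs(dropout: float = 0.0, spurious_per_kb: float = 0.0,
                  minus_strand_prob: float = 0.0) -> list[ArchitectureSpec]:
    """Three distinguishable architectures mirroring the Copia/Gypsy/Bel-Pao
    conventions: Copia places integrase before reverse transcriptase, the
    other two place it after, and each family carries its own key subdomains.
    """
    common = dict(dropout=dropout, spurious_per_kb=spurious_per_kb,
                  minus_strand_prob=minus_strand_prob)
    return [
        ArchitectureSpec(
            label="Copia",
            blocks=(
                DomainBlock("GAG", "Retrotrans_gag"),
                DomainBlock("AP", "retropepsin_like"),
                DomainBlock("Integrase", "rve"),
                DomainBlock("RT", "RT_LTR"),
                DomainBlock("RNase", "RNase_HI_RT_Ty1"),
            ),
            **common,
        ),
        ArchitectureSpec(
            label="Gypsy",
            blocks=(
                DomainBlock("GAG", "Retrotrans_gag"),
                DomainBlock("AP", "retropepsin_like_LTR_2"),
                DomainBlock("RT", "RT_LTR"),
                DomainBlock("RNase", "RNase_HI_RT_Ty3"),
                DomainBlock("Integrase", "rve"),
            ),
            **common,
        ),
        ArchitectureSpec(
            label="Bel-Pao",
            blocks=(
                DomainBlock("GAG", "Retrotran_gag_2"),
                DomainBlock("AP", "Peptidase_A17"),
                DomainBlock("RT", "RT_pepA17"),
                DomainBlock("RNase", "RNase_HI_like"),
                DomainBlock("Integrase", "rve"),
            ),
            **common,
        ),
    ]


def _random_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(_ALPHABET[rng.integers(0, 4, size=n)])


def _sample_element(
    spec: ArchitectureSpec, rng: np.random.Generator
) -> tuple[int, list[tuple[str, int, int, float]]]:
    """Element length plus local plus-strand hits (subdomain, start, end, evalue)."""
    pos = 0
    hits: list[tuple[str, int, int, float]] = []
    for block in spec.blocks:
        gap = int(rng.integers(spec.gap_range[0], spec.gap_range[1] + 1))
        length = int(rng.integers(block.length_range[0], block.length_range[1] + 1))
        start = pos + gap
        lo, hi = block.log10_evalue_range
        evalue = float(10.0 ** rng.uniform(lo, hi))
        if rng.random() >= spec.dropout:
            hits.append((block.subdomain, start, start + length, evalue))
        pos = start + length
    pos += int(rng.integers(spec.gap_range[0], spec.gap_range[1] + 1))
    return pos, hits


def _spurious_hits(
    spec: ArchitectureSpec,
    rng: np.random.Generator,
    span: int,
    vocabulary: Sequence[str],
) -> list[tuple[str, int, int, float]]:
    n = rng.poisson(spec.spurious_per_kb * span / 1000.0)
    out = []
    for _ in range(int(n)):
        sub = vocabulary[int(rng.integers(0, len(vocabulary)))]
        length = int(rng.integers(30, 120))
        start = int(rng.integers(0, max(1, span - length)))
        lo, hi = SPURIOUS_LOG10E_RANGE
        evalue = float(10.0 ** rng.uniform(lo, hi))
        out.append((sub, start, start + length, evalue))
    return out


_DEFAULT_VOCAB = (
    "RNase_HI_like", "DUF1759", "RVP_2", "RVT_3", "DNA_BRE_C", "gag_pre-integrase",
)


def simulate_training_corpus(
    specs: Sequence[ArchitectureSpec],
    n_per_class: int,
    seed: int,
) -> tuple[list[GenomeSequence], list[DomainHit], dict[str, str]]:
    """Labelled single-strand sequences with their hit table.

    Returns (sequences, hits in sequence-local coordinates, id -> label map).
    Deterministic under ``seed``.
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    if len(specs) < 2:
        raise ConfigurationError("need at least two architecture specs")
    rng = np.random.default_rng(seed)
    sequences: list[GenomeSequence] = []
    hits: list[DomainHit] = []
    labels: dict[str, str] = {}
    for spec in specs:
        for i in range(n_per_class):
            seq_id = f"{spec.label}_{i:05d}"
            span, local = _sample_element(spec, rng)
            local = local + _spurious_hits(spec, rng, span, _DEFAULT_VOCAB)
            sequences.append(GenomeSequence(seq_id, _random_residues(rng, span)))
            for sub, start, end, evalue in sorted(local):
                hits.append(DomainHit(sub, start, end, "+", evalue, seq_id))
            labels[seq_id] = spec.label
    return sequences, hits, labels


@dataclass(frozen=True)
class Insertion:
    """An explicit placement request: which architecture, where, which strand."""

    label: str
    start: int
    strand: str = "+"


def simulate_genome(
    specs: Sequence[ArchitectureSpec],
    n_insertions: int,
    genome_length: int,
    seed: int,
    seq_id: str = "chrSim",
    insertions: Optional[Sequence[Insertion]] = None,
) -> tuple[GenomeSequence, list[AnnotationRecord], list[DomainHit]]:
    """Background genome with planted elements, truth GFF3 records and hits.

    Placements are non-overlapping; pass ``insertions`` to pin elements at
    exact positions (e.g. straddling a window boundary). Hits are reported
    in genome coordinates with the element's strand.
    """
    rng = np.random.default_rng(seed)
    by_label = {s.label: s for s in specs}

    planned: list[tuple[ArchitectureSpec, Optional[int], str]] = []
    if insertions is not None:
        for ins in insertions:
            if ins.label not in by_label:
                raise ConfigurationError(f"no architecture spec for {ins.label!r}")
            planned.append((by_label[ins.label], ins.start, ins.strand))
    else:
        for k in range(n_insertions):
            spec = specs[int(rng.integers(0, len(specs)))]
            strand = "-" if rng.random() < spec.minus_strand_prob else "+"
            planned.append((spec, None, strand))

    elements = []
    for spec, start, strand in planned:
        span, local = _sample_element(spec, rng)
        elements.append([spec, start, strand, span, local])

    total_span = sum(e[3] for e in elements if e[1] is None)
    free = genome_length - sum(e[3] for e in elements)
    if free < 0 or any(
        e[1] is not None and e[1] + e[3] > genome_length for e in elements
    ):
        raise ConfigurationError(
            f"cannot place {len(elements)} elements (total span "
            f"{sum(e[3] for e in elements)}) in a genome of {genome_length} nt"
        )

    # place unpinned elements uniformly into the gaps left by pinned ones
    occupied = sorted(
        (e[1], e[1] + e[3]) for e in elements if e[1] is not None
    )
    for lo, hi in zip(occupied, occupied[1:]):
        if lo[1] > hi[0]:
            raise ConfigurationError("pinned insertions overlap")
    unpinned = [e for e in elements if e[1] is None]
    if unpinned:
        for attempt in range(1000):
            starts = sorted(
                int(rng.integers(0, genome_length - e[3] + 1)) for e in unpinned
            )
            trial = occupied + [
                (s, s + e[3]) for s, e in zip(starts, unpinned)
            ]
            trial.sort()
            if all(a[1] <= b[0] for a, b in zip(trial, trial[1:])):
                for s, e in zip(starts, unpinned):
                    e[1] = s
                break
        else:
            raise ConfigurationError(
                "could not place elements without overlap; genome too dense"
            )

    residues = _random_residues(rng, genome_length)
    annotations: list[AnnotationRecord] = []
    hits: list[DomainHit] = []
    elements.sort(key=lambda e: e[1])
    for i, (spec, start, strand, span, local) in enumerate(elements):
        annotations.append(
            AnnotationRecord(
                seq_id=seq_id, start=start, end=start + span, strand=strand,
                label=spec.label, annotation_id=f"true{i + 1}",
            )
        )
        for sub, l_start, l_end, evalue in local:
            if strand == "+":
                g_start, g_end = start + l_start, start + l_end
            else:
                g_start, g_end = start + span - l_end, start + span - l_start
            hits.append(DomainHit(sub, g_start, g_end, strand, evalue, seq_id))
    spurious_spec = specs[0]
    hits.extend(
        DomainHit(sub, s, e, "+", ev, seq_id)
        for sub, s, e, ev in _spurious_hits(
            spurious_spec, rng, genome_length, _DEFAULT_VOCAB
        )
    )
    hits.sort(key=lambda h: (h.start, h.end, h.subject_id))
    return GenomeSequence(seq_id, residues), annotations, hits
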