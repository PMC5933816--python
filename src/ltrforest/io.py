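"""External formats: FASTA, domain-hit tables, GFF3, and model files.

All in-memory coordinates are 0-based half-open. Every external format
(FASTA is coordinate-free; hit tables and GFF3 are 1-based inclusive)
is converted at this boundary and nowhere else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .config import RunConfig, SUPERFAMILIES
from .errors import FormatError, ModelVersionError, VocabularyError
from .relational import DomainHierarchy, RelationalTest

MODEL_FORMAT = "ltrforest-model"
MODEL_VERSION = 1

GFF_SOURCE = "ltrforest"
GFF_TYPE = "LTR_retrotransposon"


@dataclass(frozen=True)
class GenomeSequence:
    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise FormatError("sequence id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainHit:
    """One conserved-domain match; coordinates 0-based half-open on source_seq."""

    subject_id: str
    start: int
    end: int
    strand: str
    evalue: float
    source_seq: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(
                f"hit {self.subject_id}: end < start ({self.end} < {self.start})"
            )
        if self.evalue < 0:
            raise FormatError(f"hit {self.subject_id}: negative e-value")
        if self.strand not in ("+", "-"):
            raise FormatError(f"hit {self.subject_id}: strand must be + or -")


@dataclass(frozen=True)
class AnnotationRecord:
    """One reference annotation; coordinates 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str
    label: str
    annotation_id: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError("annotation end < start")
        if self.label not in SUPERFAMILIES:
            raise FormatError(f"unknown superfamily label {self.label!r}")


def read_fasta(path) -> list[GenomeSequence]:
    """Strict FASTA reader: rejects empty files, empty records, stray data.

    Hand-rolled deliberately so format errors can name the offending line.
    """
    path = Path(path)
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"{path}:{header_line}: record {header!r} has no residues")
        if header in seen:
            raise FormatError(f"{path}:{header_line}: duplicate sequence id {header!r}")
        seen.add(header)
        records.append(GenomeSequence(header, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before any FASTA header"
                    )
                bad = set(line.upper()) - set("ACGTN")
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: invalid residues {sorted(bad)}"
                    )
                chunks.append(line)
    flush()
    if not records:
        raise FormatError(f"{path}:1: empty FASTA file")
    return records


def write_fasta(sequences: Iterable[GenomeSequence], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.seq_id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i:i + width] + "\n")


# --- domain-hit tables -----------------------------------------------------

HIT_TABLE_COLUMNS = ("query_id", "subject_id", "q_start", "q_end", "strand", "evalue")


def read_domain_hits(path, hierarchy: DomainHierarchy) -> list[DomainHit]:
    """Read a tab-separated hit table (BLAST outfmt-6-like dialect).

    Columns: query_id, subject_id, q_start, q_end, strand, evalue with
    1-based inclusive coordinates. Rows with q_start > q_end are
    minus-strand matches reported with reversed coordinates: they are
    normalized to start <= end and forced to strand '-'.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(HIT_TABLE_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(HIT_TABLE_COLUMNS)} "
                    f"tab-separated columns, got {len(fields)}"
                )
            query_id, subject_id, s_start, s_end, strand, s_evalue = fields
            if subject_id not in hierarchy.parent:
                raise VocabularyError(
                    f"{path}:{lineno}: unknown subdomain identifier {subject_id!r}"
                )
            try:
                start = int(s_start)
                end = int(s_end)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            try:
                evalue = float(s_evalue)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric e-value {s_evalue!r}"
                ) from None
            if start > end:
                start, end = end, start
                strand = "-"
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            hits.append(
                DomainHit(
                    subject_id=subject_id,
                    start=start - 1,
                    end=end,
                    strand=strand,
                    evalue=evalue,
                    source_seq=query_id,
                )
            )
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.source_seq}\t{h.subject_id}\t{h.start + 1}\t{h.end}\t"
                f"{h.strand}\t{h.evalue:g}\n"
            )


def read_label_map(path) -> dict[str, str]:
    """Tab-separated sequence-id -> superfamily map."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'id<TAB>superfamily'")
            seq_id, label = fields
            if label not in SUPERFAMILIES:
                raise FormatError(f"{path}:{lineno}: unknown superfamily {label!r}")
            labels[seq_id] = label
    return labels


def write_label_map(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for seq_id, label in labels.items():
            fh.write(f"{seq_id}\t{label}\n")


# --- GFF3 ------------------------------------------------------------------

def _gff_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for part in raw.split(";"):
        part = part.strip()
        if part and "=" in part:
            key, value = part.split("=", 1)
            attrs[key] = value
    return attrs


def write_predictions_gff(preds: Sequence, path) -> None:
    """Write prediction records as sorted GFF3 (1-based inclusive)."""
    ordered = sorted(preds, key=lambda p: (p.seq_id, p.start, p.end, p.candidate_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in ordered:
            prob = max(p.probabilities.values())
            attrs = [f"ID={p.candidate_id}"]
            attrs.append(f"Superfamily={p.combined_label}")
            attrs.append(f"Probability={prob:.4f}")
            for family in SUPERFAMILIES:
                if family in p.probabilities:
                    attrs.append(f"P_{family.replace('-', '')}={p.probabilities[family]:.4f}")
            fh.write(
                f"{p.seq_id}\t{GFF_SOURCE}\t{GFF_TYPE}\t{p.start + 1}\t{p.end}\t"
                f"{prob:.4f}\t{p.strand}\t.\t{';'.join(attrs)}\n"
            )


def read_predictions_gff(path):
    """Re-read a predictions GFF3 into PredictionRecord objects."""
    from .classify import PredictionRecord

    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seq_id, _src, _type, start, end, _score, strand, _frame, attr_raw = fields
            attrs = _gff_attributes(attr_raw)
            probs = {}
            for family in SUPERFAMILIES:
                key = f"P_{family.replace('-', '')}"
                if key in attrs:
                    probs[family] = float(attrs[key])
            if not probs:
                probs = {attrs.get("Superfamily", "Copia"): float(attrs["Probability"])}
            records.append(
                PredictionRecord(
                    candidate_id=attrs.get("ID", f"pred{lineno}"),
                    seq_id=seq_id,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    probabilities=probs,
                    combined_label=attrs.get("Superfamily", "None"),
                )
            )
    return records


def write_annotations_gff(annotations: Iterable[AnnotationRecord], path) -> None:
    ordered = sorted(annotations, key=lambda a: (a.seq_id, a.start, a.end))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, a in enumerate(ordered):
            aid = a.annotation_id or f"ann{i + 1}"
            fh.write(
                f"{a.seq_id}\t{GFF_SOURCE}\t{GFF_TYPE}\t{a.start + 1}\t{a.end}\t.\t"
                f"{a.strand}\t.\tID={aid};Superfamily={a.label}\n"
            )


def read_annotations_gff(path) -> list[AnnotationRecord]:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seq_id, _src, _type, start, end, _score, strand, _frame, attr_raw = fields
            attrs = _gff_attributes(attr_raw)
            if "Superfamily" not in attrs:
                raise FormatError(f"{path}:{lineno}: missing Superfamily attribute")
            records.append(
                AnnotationRecord(
                    seq_id=seq_id,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand if strand in ("+", "-") else "+",
                    label=attrs["Superfamily"],
                    annotation_id=attrs.get("ID", f"ann{lineno}"),
                )
            )
    return records


# --- model files -----------------------------------------------------------

def _node_to_dict(node) -> dict:
    if node.is_leaf:
        return {"leaf": {"n": node.n_examples, "n_pos": node.n_positive}}
    return {
        "test": node.test.to_dict(),
        "yes": _node_to_dict(node.yes_child),
        "no": _node_to_dict(node.no_child),
    }


def _node_from_dict(d: dict):
    from .forest import TreeNode

    if "leaf" in d:
        return TreeNode.leaf(d["leaf"]["n"], d["leaf"]["n_pos"])
    return TreeNode.internal(
        RelationalTest.from_dict(d["test"]),
        _node_from_dict(d["yes"]),
        _node_from_dict(d["no"]),
    )


def save_model(forest, path) -> None:
    """Serialize a forest as versioned, human-readable JSON.

    Leaf probabilities are stored as integer counts so a round-trip is
    bit-for-bit exact.
    """
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "target": forest.target,
        "split_criterion": "information_gain",
        "aggregation": "mean_leaf_frequency",
        "enumeration": forest.enumeration,
        "rng_seed": forest.rng_seed,
        "config": forest.config.to_dict(),
        "trees": [_node_to_dict(t) for t in forest.trees],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path):
    from .forest import RelationalForest

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not a valid model file: {exc}") from None
    if payload.get("format") != MODEL_FORMAT:
        raise FormatError(f"{path}: not a {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_VERSION:
        raise ModelVersionError(
            f"{path}: model version {payload.get('version')!r} is not "
            f"supported (expected {MODEL_VERSION})"
        )
    return RelationalForest(
        trees=[_node_from_dict(t) for t in payload["trees"]],
        target=payload["target"],
        enumeration=payload["enumeration"],
        rng_seed=payload["rng_seed"],
        config=RunConfig.from_dict(payload["config"]),
    )
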