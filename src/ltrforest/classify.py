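"""Apply per-superfamily forests to candidates and combine the outputs."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .candidates import CandidateTE
from .config import KEY_DOMAINS, SUPERFAMILIES
from .errors import ConfigurationError
from .forest import RelationalForest, predict_proba
from .relational import DomainHierarchy

NONE_LABEL = "None"


@dataclass(frozen=True)
class PredictionRecord:
    candidate_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    probabilities: Mapping[str, float]
    combined_label: str = NONE_LABEL

    @property
    def max_probability(self) -> float:
        return max(self.probabilities.values())


@dataclass(frozen=True)
class _OrientedView:
    """Candidate hits in element orientation, as routed through the trees."""
    hits: tuple


def combine(probabilities: Mapping[str, float], none_threshold: float) -> str:
    """Argmax superfamily when its probability exceeds the threshold, else None.

    Exact ties are broken by the fixed order Copia < Gypsy < Bel-Pao.
    """
    if not probabilities:
        raise ConfigurationError("cannot combine an empty probability map")
    best_family = None
    best_p = -1.0
    for family in SUPERFAMILIES:
        if family in probabilities and probabilities[family] > best_p:
            best_family, best_p = family, probabilities[family]
    for family in probabilities:
        if family not in SUPERFAMILIES and probabilities[family] > best_p:
            best_family, best_p = family, probabilities[family]
    if best_p > none_threshold:
        return best_family
    return NONE_LABEL


def score_candidates(
    candidates: Sequence[CandidateTE],
    forests: Mapping[str, RelationalForest],
    hierarchy: DomainHierarchy,
    none_threshold: float = 0.5,
) -> list[PredictionRecord]:
    """One record per candidate with one probability per forest."""
    if not forests:
        raise ConfigurationError("at least one trained forest is required")
    records: list[PredictionRecord] = []
    for cand in candidates:
        view = _OrientedView(cand.oriented_hits())
        probs = {
            family: predict_proba(forest, view, hierarchy)
            for family, forest in forests.items()
        }
        records.append(
            PredictionRecord(
                candidate_id=cand.candidate_id,
                seq_id=cand.seq_id,
                start=cand.start,
                end=cand.end,
                strand=cand.strand,
                probabilities=probs,
                combined_label=combine(probs, none_threshold),
            )
        )
    return records


def baseline_predict(candidate: CandidateTE, target: str) -> bool:
    """Key-domain baseline: the target's key subdomain is present (any e-value)."""
    if target not in KEY_DOMAINS:
        raise ConfigurationError(f"unknown superfamily {target!r}")
    key = KEY_DOMAINS[target]
    return any(h.subject_id == key for h in candidate.hits)
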