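"""The relational feature language used at tree nodes.

A candidate element is a bag of conserved-domain hits (identity, interval,
e-value). Node tests are drawn from four families:

* ``OCCURS``        — some hit of a domain with e-value at or below a ceiling;
* ``OCCURS_LEN``    — as above, with a minimum or maximum hit-length bound;
* ``BEFORE``        — two qualifying hits whose start coordinates are ordered;
* ``COUNT``         — the number of hits under a general domain exceeds a
  threshold (no e-value ceiling).

Domains form a two-level hierarchy: 26 concrete subdomains grouped under 7
general domains. A test naming a general domain is satisfied by hits of any
of its subdomains. General domains with a single subdomain are extensionally
identical to that subdomain, so a duplicate-free enumeration names only the
subdomain in the OCCURS/OCCURS_LEN/BEFORE slots; COUNT tests exist only at
the general level and keep all 7 generals. Under the default grids this
yields 248 + 2976 + 7688 + 35 = 10947 distinct tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import RunConfig
from .errors import VocabularyError

OCCURS = "OCCURS"
OCCURS_LEN = "OCCURS_LEN"
BEFORE = "BEFORE"
COUNT = "COUNT"

_VARIANT_RANK = {OCCURS: 0, OCCURS_LEN: 1, BEFORE: 2, COUNT: 3}


class DomainHierarchy:
    """Two-level domain vocabulary: subdomains grouped under general domains."""

    def __init__(self, rows: Sequence[tuple[str, str, str]]):
        self.accession: dict[str, str] = {}
        self.parent: dict[str, str] = {}
        self._children: dict[str, list[str]] = {}
        for subdomain, accession, general in rows:
            if subdomain in self.parent:
                raise VocabularyError(f"duplicate subdomain {subdomain!r}")
            self.parent[subdomain] = general
            self.accession[subdomain] = accession
            self._children.setdefault(general, []).append(subdomain)
        self.subdomains: tuple[str, ...] = tuple(self.parent)
        self.generals: tuple[str, ...] = tuple(self._children)

    @classmethod
    def default(cls) -> "DomainHierarchy":
        text = (
            resources.files("ltrforest.data")
            .joinpath("domain_manifest.tsv")
            .read_text()
        )
        rows = []
        for line in text.splitlines()[1:]:
            if line.strip():
                sub, acc, gen = line.split("\t")
                rows.append((sub, acc, gen))
        return cls(rows)

    def children(self, general: str) -> tuple[str, ...]:
        return tuple(self._children[general])

    def is_general(self, domain: str) -> bool:
        return domain in self._children

    def resolve(self, domain: str) -> None:
        if domain not in self.parent and domain not in self._children:
            raise VocabularyError(f"unknown domain identifier {domain!r}")

    @property
    def effective_domains(self) -> tuple[str, ...]:
        """Subdomains plus generals with >= 2 subdomains, in manifest order.

        A general with a single subdomain matches exactly the same hits as
        that subdomain, so tests naming it are duplicates.
        """
        multi = [g for g in self.generals if len(self._children[g]) > 1]
        return self.subdomains + tuple(multi)


def subsumes(hierarchy: DomainHierarchy, query_domain: str, hit_subdomain: str) -> bool:
    """True iff a hit of ``hit_subdomain`` satisfies a test naming ``query_domain``."""
    hierarchy.resolve(query_domain)
    hierarchy.resolve(hit_subdomain)
    if query_domain == hit_subdomain:
        return True
    return hierarchy.parent.get(hit_subdomain) == query_domain


@dataclass(frozen=True, order=True)
class RelationalTest:
    """One candidate node test; comparison order is the canonical enumeration order."""

    variant_rank: int
    domain: str
    domain2: Optional[str] = None
    evalue_max: Optional[float] = None
    length_dir: Optional[str] = None  # "min" | "max"
    length_limit: Optional[int] = None
    count_threshold: Optional[int] = None

    @property
    def variant(self) -> str:
        for name, rank in _VARIANT_RANK.items():
            if rank == self.variant_rank:
                return name
        raise ValueError(self.variant_rank)

    def describe(self) -> str:
        v = self.variant
        if v == OCCURS:
            return f"occurs({self.domain}, e<={self.evalue_max:g})"
        if v == OCCURS_LEN:
            op = ">=" if self.length_dir == "min" else "<="
            return (
                f"occurs({self.domain}, e<={self.evalue_max:g}, "
                f"length{op}{self.length_limit})"
            )
        if v == BEFORE:
            return f"before({self.domain}, {self.domain2}, e<={self.evalue_max:g})"
        return f"count({self.domain}) > {self.count_threshold}"

    def to_dict(self) -> dict:
        d = {"variant": self.variant, "domain": self.domain}
        if self.domain2 is not None:
            d["domain2"] = self.domain2
        if self.evalue_max is not None:
            d["evalue_max"] = self.evalue_max
        if self.length_dir is not None:
            d["length_dir"] = self.length_dir
            d["length_limit"] = self.length_limit
        if self.count_threshold is not None:
            d["count_threshold"] = self.count_threshold
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RelationalTest":
        return cls(
            variant_rank=_VARIANT_RANK[d["variant"]],
            domain=d["domain"],
            domain2=d.get("domain2"),
            evalue_max=d.get("evalue_max"),
            length_dir=d.get("length_dir"),
            length_limit=d.get("length_limit"),
            count_threshold=d.get("count_threshold"),
        )


def enumeration_config(cfg: RunConfig) -> dict:
    """The frozen enumeration settings recorded in model files."""
    return {
        "evalue_grid": list(cfg.evalue_grid),
        "length_grid": list(cfg.length_grid),
        "count_grid": list(cfg.count_grid),
        "dedup_singleton_generals": True,
        "pairs": "ordered_with_self",
        "count_tests_use_evalue": False,
    }


def enumerate_tests(hierarchy: DomainHierarchy, cfg: RunConfig) -> list[RelationalTest]:
    """Enumerate the complete, duplicate-free test set in canonical order.

    Canonical order: variant family, then domain(s) in vocabulary order,
    then the grid values in ascending order.
    """
    domains = hierarchy.effective_domains
    tests: list[RelationalTest] = []
    for d in domains:
        for e in cfg.evalue_grid:
            tests.append(RelationalTest(_VARIANT_RANK[OCCURS], d, evalue_max=e))
    for d in domains:
        for e in cfg.evalue_grid:
            for direction in ("min", "max"):
                for limit in cfg.length_grid:
                    tests.append(
                        RelationalTest(
                            _VARIANT_RANK[OCCURS_LEN], d, evalue_max=e,
                            length_dir=direction, length_limit=limit,
                        )
                    )
    for d1, d2 in itertools.product(domains, domains):
        for e in cfg.evalue_grid:
            tests.append(
                RelationalTest(_VARIANT_RANK[BEFORE], d1, domain2=d2, evalue_max=e)
            )
    for g in hierarchy.generals:
        for k in cfg.count_grid:
            tests.append(RelationalTest(_VARIANT_RANK[COUNT], g, count_threshold=k))
    assert len(set(tests)) == len(tests), "duplicate tests in enumeration"
    return tests


def _hit_length(hit) -> int:
    # internal coordinates are 0-based half-open, so this equals the
    # 1-based inclusive length end - start + 1
    return hit.end - hit.start


def _qualifies(hierarchy, hit, domain: str, evalue_max: float) -> bool:
    return subsumes(hierarchy, domain, hit.subject_id) and hit.evalue <= evalue_max


def evaluate_test(candidate, test: RelationalTest, hierarchy: DomainHierarchy) -> bool:
    """Evaluate one test on a candidate-like object exposing oriented hits.

    ``candidate`` may be anything with a ``hits`` attribute (a sequence of
    domain hits on a single strand, already in element orientation).
    """
    hits = candidate.hits if hasattr(candidate, "hits") else candidate
    variant = test.variant
    if variant == OCCURS:
        return any(_qualifies(hierarchy, h, test.domain, test.evalue_max) for h in hits)
    if variant == OCCURS_LEN:
        for h in hits:
            if not _qualifies(hierarchy, h, test.domain, test.evalue_max):
                continue
            length = _hit_length(h)
            if test.length_dir == "min" and length >= test.length_limit:
                return True
            if test.length_dir == "max" and length <= test.length_limit:
                return True
        return False
    if variant == BEFORE:
        firsts = [h for h in hits if _qualifies(hierarchy, h, test.domain, test.evalue_max)]
        seconds = [h for h in hits if _qualifies(hierarchy, h, test.domain2, test.evalue_max)]
        return any(h1.start < h2.start for h1 in firsts for h2 in seconds)
    if variant == COUNT:
        n = sum(1 for h in hits if subsumes(hierarchy, test.domain, h.subject_id))
        return n > test.count_threshold
    raise ValueError(f"unknown test variant {variant!r}")


class FeatureMatrix:
    """Vectorized evaluation of the full test set over a fixed example set.

    Profiles each example once (minimum e-value per domain, per domain and
    length bound, per ordered domain pair, and hit counts per general), then
    answers any enumerated test by a table lookup. Semantics are identical
    to :func:`evaluate_test`; tree induction uses this path for speed.
    """

    def __init__(self, hierarchy: DomainHierarchy, cfg: RunConfig,
                 examples: Sequence) -> None:
        self.hierarchy = hierarchy
        self.cfg = cfg
        domains = hierarchy.effective_domains
        self._dom_idx = {d: i for i, d in enumerate(domains)}
        self._gen_idx = {g: i for i, g in enumerate(hierarchy.generals)}
        nd, ng = len(domains), len(hierarchy.generals)
        n = len(examples)
        L = len(cfg.length_grid)
        inf = np.inf
        self.min_ev = np.full((n, nd), inf)
        self.min_ev_len = np.full((n, nd, 2, L), inf)  # dir 0=min, 1=max
        self.pair_ev = np.full((n, nd, nd), inf)
        self.counts = np.zeros((n, ng), dtype=np.int64)
        limits = np.asarray(cfg.length_grid)
        for i, ex in enumerate(examples):
            hits = ex.hits if hasattr(ex, "hits") else ex
            per_hit_domains = []
            for h in hits:
                ds = [self._dom_idx[h.subject_id]] if h.subject_id in self._dom_idx else []
                gen = hierarchy.parent[h.subject_id]
                if gen in self._dom_idx:
                    ds.append(self._dom_idx[gen])
                per_hit_domains.append(ds)
                self.counts[i, self._gen_idx[gen]] += 1
                length = h.end - h.start
                for d in ds:
                    if h.evalue < self.min_ev[i, d]:
                        self.min_ev[i, d] = h.evalue
                    ok_min = length >= limits
                    ok_max = length <= limits
                    np.minimum(
                        self.min_ev_len[i, d, 0], np.where(ok_min, h.evalue, inf),
                        out=self.min_ev_len[i, d, 0],
                    )
                    np.minimum(
                        self.min_ev_len[i, d, 1], np.where(ok_max, h.evalue, inf),
                        out=self.min_ev_len[i, d, 1],
                    )
            for a, ha in enumerate(hits):
                for b, hb in enumerate(hits):
                    if ha.start >= hb.start:
                        continue
                    worst = max(ha.evalue, hb.evalue)
                    for d1 in per_hit_domains[a]:
                        for d2 in per_hit_domains[b]:
                            if worst < self.pair_ev[i, d1, d2]:
                                self.pair_ev[i, d1, d2] = worst

    def evaluate(self, test: RelationalTest) -> np.ndarray:
        """Boolean vector of the test outcome for every profiled example."""
        v = test.variant
        if v == OCCURS:
            return self.min_ev[:, self._dom_idx[test.domain]] <= test.evalue_max
        if v == OCCURS_LEN:
            d = self._dom_idx[test.domain]
            k = 0 if test.length_dir == "min" else 1
            j = self.cfg.length_grid.index(test.length_limit)
            return self.min_ev_len[:, d, k, j] <= test.evalue_max
        if v == BEFORE:
            d1 = self._dom_idx[test.domain]
            d2 = self._dom_idx[test.domain2]
            return self.pair_ev[:, d1, d2] <= test.evalue_max
        if v == COUNT:
            return self.counts[:, self._gen_idx[test.domain]] > test.count_threshold
        raise ValueError(v)

    def matrix(self, tests: Iterable[RelationalTest]) -> np.ndarray:
        """Dense boolean matrix, one row per test, one column per example."""
        return np.vstack([self.evaluate(t) for t in tests])
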