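"""Iterative homolog harvesting and candidate-set delineation.

The collection algorithm mirrors a database-era iterative search, run at
desk scale: a seed similarity search, a census of the domain content of
the seed hits, collection of every protein whose resolved architecture
carries one of the frequent domains, extraction of those domain regions
as expansion queries, and a final union - followed by the exclusion rules
that delineate the small-GTPase candidate set (ABC-transporter-like
architectures out; sequences shorter than 150 aa out; sequences longer
than 240 aa kept for tree context but flagged not small).

Similarity hits may come from the built-in search backend or from an
ingested hit table; the two sources are interchangeable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .io_formats import DomainHit, SimilarityHit
from .search_backend import SearchParams, search_all

__all__ = [
    "DomainArchitecture",
    "HarvestConfig",
    "HarvestResult",
    "ConfigurationError",
    "resolve_architecture",
    "resolve_all_architectures",
    "census_domains",
    "extract_region",
    "iterative_collect",
    "make_search_source",
    "make_table_source",
]

#: hit source contract: queries (id -> sequence) -> similarity hits
HitSource = Callable[[Mapping[str, str]], list[SimilarityHit]]


class ConfigurationError(ValueError):
    pass


@dataclass
class DomainArchitecture:
    """Non-overlapping, coordinate-ordered domain content of one protein."""

    protein_id: str
    kept: list[DomainHit] = field(default_factory=list)
    #: (discarded hit, id of the kept hit it overlapped)
    resolution_log: list[tuple[DomainHit, str]] = field(default_factory=list)

    @property
    def domain_names(self) -> set[str]:
        return {h.domain_name for h in self.kept}


def _overlap_len(a: DomainHit, b: DomainHit) -> int:
    return min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from) + 1


def resolve_architecture(
    hits: Sequence[DomainHit], min_overlap_fraction: float = 0.0
) -> DomainArchitecture:
    """Greedy overlap resolution: best-scoring domain model wins.

    Repeatedly keep the highest-scoring remaining hit and discard every
    hit overlapping it, until none remain.  Two hits overlap when they
    share at least one residue and the shared span exceeds
    `min_overlap_fraction` of the shorter interval (the default, 0,
    makes any shared residue an overlap).  Score ties break by lower
    e-value, then longer interval, then domain name.
    """
    if not hits:
        return DomainArchitecture(protein_id="")
    pids = {h.protein_id for h in hits}
    if len(pids) != 1:
        raise ValueError(f"hits span multiple proteins: {sorted(pids)}")
    arch = DomainArchitecture(protein_id=hits[0].protein_id)
    remaining = sorted(
        hits,
        key=lambda h: (
            -h.bit_score,
            h.e_value,
            -(h.ali_to - h.ali_from + 1),
            h.domain_name,
        ),
    )
    while remaining:
        best = remaining.pop(0)
        arch.kept.append(best)
        still = []
        for h in remaining:
            ov = _overlap_len(best, h)
            shorter = min(h.ali_to - h.ali_from + 1, best.ali_to - best.ali_from + 1)
            if ov >= 1 and ov >= min_overlap_fraction * shorter:
                arch.resolution_log.append((h, best.domain_name))
            else:
                still.append(h)
        remaining = still
    arch.kept.sort(key=lambda h: h.ali_from)
    return arch


def resolve_all_architectures(
    hits: Iterable[DomainHit], min_overlap_fraction: float = 0.0
) -> dict[str, DomainArchitecture]:
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    return {
        pid: resolve_architecture(hs, min_overlap_fraction)
        for pid, hs in by_protein.items()
    }


def census_domains(
    seed_hits: Sequence[SimilarityHit],
    architectures: Mapping[str, DomainArchitecture],
) -> tuple[list[tuple[str, int]], set[str]]:
    """Domain frequency among seed-hit subjects.

    Returns ``(ranked table, no-domain subject ids)``: the table maps each
    domain name to the number of distinct seed-hit subjects whose resolved
    architecture contains it, descending (ties by name); subjects with no
    significant domain content are reported separately.
    """
    subjects = sorted({h.subject_id for h in seed_hits})
    counts: Counter[str] = Counter()
    no_domain: set[str] = set()
    for sid in subjects:
        arch = architectures.get(sid)
        if arch is None or not arch.kept:
            no_domain.add(sid)
            continue
        counts.update(arch.domain_names)
    table = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return table, no_domain


def extract_region(sequence: str, ali_from: int, ali_to: int) -> str:
    """Inclusive 1-based slice of a protein sequence."""
    if not (1 <= ali_from <= ali_to <= len(sequence)):
        raise ValueError(
            f"region {ali_from}-{ali_to} out of range for length {len(sequence)}"
        )
    return sequence[ali_from - 1 : ali_to]


def make_search_source(database: Mapping[str, str], params: SearchParams) -> HitSource:
    """Hit source backed by the built-in Smith-Waterman search."""

    def source(queries: Mapping[str, str]) -> list[SimilarityHit]:
        if not queries:
            return []
        return search_all(dict(queries), dict(database), params)

    return source


def make_table_source(hits: Sequence[SimilarityHit]) -> HitSource:
    """Hit source backed by an ingested (externally computed) hit table."""

    def source(queries: Mapping[str, str]) -> list[SimilarityHit]:
        return [h for h in hits if h.query_id in queries]

    return source


@dataclass(frozen=True)
class HarvestConfig:
    seed_ids: tuple[str, ...]
    e_value_threshold: float = 1e-4
    min_length: int = 150
    max_length: int = 240
    mglb_mode: bool = False
    mglb_band: tuple[int, int] = (129, 179)
    excluded_architecture_domains: frozenset[str] = frozenset(
        {"ABC_tran", "ABC_tran_2", "AAA_21"}
    )
    expansion_rounds: int = 1
    #: how many of the most frequent census domains become collection domains
    collect_top_k: int = 4
    #: cap on deduplicated expansion queries per round (desk-scale bound)
    max_expansion_queries: int = 40
    min_overlap_fraction: float = 0.0

    def __post_init__(self):
        if self.min_length >= self.max_length:
            raise ValueError("min_length must be < max_length")
        if self.e_value_threshold <= 0:
            raise ValueError("e_value_threshold must be > 0")


@dataclass
class HarvestResult:
    #: candidate id -> provenance tags (seed-hit | domain-member | expansion-hit)
    candidates: dict[str, list[str]]
    #: excluded id -> primary reason (decoy-architecture | short)
    excluded: dict[str, str]
    #: candidate id -> inside the small band (GTPase mode) / length band note
    small: dict[str, bool]
    selected_domains: list[str]
    domain_census: list[tuple[str, int]]
    no_domain_subjects: set[str]

    @property
    def small_candidates(self) -> set[str]:
        return {c for c, s in self.small.items() if s}


def iterative_collect(
    config: HarvestConfig,
    proteome: Mapping[str, str],
    domain_hits: Iterable[DomainHit],
    hit_source: HitSource,
) -> HarvestResult:
    """Run the full seed -> census -> collect -> expand -> exclude harvest."""
    missing = [s for s in config.seed_ids if s not in proteome]
    if missing or not config.seed_ids:
        raise ConfigurationError(f"seeds not found in proteome: {missing or 'none given'}")

    architectures = resolve_all_architectures(domain_hits, config.min_overlap_fraction)

    def significant(hits):
        return [h for h in hits if h.e_value <= config.e_value_threshold]

    provenance: dict[str, list[str]] = {}

    def note(pid, tag):
        tags = provenance.setdefault(pid, [])
        if tag not in tags:
            tags.append(tag)

    # (i) seed search
    seed_hits = significant(hit_source({s: proteome[s] for s in config.seed_ids}))
    for h in seed_hits:
        if h.subject_id in proteome:
            note(h.subject_id, "seed-hit")

    # (ii) domain census over seed-hit subjects; collect domain members
    table, no_domain = census_domains(seed_hits, architectures)
    selected = [d for d, _ in table[: config.collect_top_k]]
    for pid in sorted(proteome):
        arch = architectures.get(pid)
        if arch and arch.domain_names & set(selected):
            note(pid, "domain-member")

    # (iii) expansion rounds: regions of the selected domains as new queries
    previous = set(provenance)
    for round_no in range(config.expansion_rounds):
        queries: dict[str, str] = {}
        seen_seqs: set[str] = set()
        for pid in sorted(previous):
            arch = architectures.get(pid)
            if arch is None:
                continue
            for hit in arch.kept:
                if hit.domain_name not in selected:
                    continue
                try:
                    region = extract_region(proteome[pid], hit.ali_from, min(hit.ali_to, len(proteome[pid])))
                except (KeyError, ValueError):
                    continue
                if region in seen_seqs:
                    continue
                seen_seqs.add(region)
                queries[f"{pid}::{hit.domain_name}"] = region
                if len(queries) >= config.max_expansion_queries:
                    break
            if len(queries) >= config.max_expansion_queries:
                break
        if not queries:
            break
        for h in significant(hit_source(queries)):
            if h.subject_id in proteome:
                note(h.subject_id, "expansion-hit")
        newly = set(provenance) - previous
        if not newly:
            break
        previous = set(provenance)

    # exclusions
    candidates: dict[str, list[str]] = {}
    excluded: dict[str, str] = {}
    small: dict[str, bool] = {}
    lo, hi = (config.mglb_band if config.mglb_mode else (config.min_length, config.max_length))
    for pid in sorted(provenance):
        arch = architectures.get(pid)
        if arch and arch.domain_names & config.excluded_architecture_domains:
            excluded[pid] = "decoy-architecture"
            continue
        length = len(proteome[pid])
        if not config.mglb_mode and length < config.min_length:
            excluded[pid] = "short"
            continue
        candidates[pid] = provenance[pid]
        small[pid] = lo <= length <= hi
    return HarvestResult(
        candidates=candidates,
        excluded=excluded,
        small=small,
        selected_domains=selected,
        domain_census=table,
        no_domain_subjects=no_domain,
    )
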