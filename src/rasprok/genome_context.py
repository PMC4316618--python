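"""Gene-neighborhood analysis: GTPase-MglB coupling, orphans, stoichiometry.

A GTPase and an mglB gene are *coupled* when they lie on the same replicon
within a gene-index window (default 4, i.e. at most three intervening
genes), strand-agnostic; distances on circular replicons wrap.  Family
members without a qualifying partner are *orphans*.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import GeneRecord

__all__ = [
    "CouplingRecord",
    "ContextSummary",
    "GeneIndex",
    "find_couplings",
    "classify_stoichiometry",
    "neighborhood_composition",
]

DEFAULT_WINDOW = 4


@dataclass(frozen=True)
class Located:
    genome_id: str
    replicon_id: str
    topology: str
    gene_index: int
    n_genes: int
    locus_tag: str
    product: str


class GeneIndex:
    """Lookup from protein/locus ids into replicon coordinates.

    Accepts ids either as plain locus tags or as ``genome|locus`` protein
    ids (the proteome header convention).
    """

    def __init__(self, gene_records: Iterable[GeneRecord]):
        self._by_locus: dict[tuple[str, str], GeneRecord] = {}
        self._replicon_sizes: dict[tuple[str, str], int] = {}
        self._by_position: dict[tuple[str, str, int], GeneRecord] = {}
        for r in gene_records:
            self._by_locus[(r.genome_id, r.locus_tag)] = r
            key = (r.genome_id, r.replicon_id)
            self._replicon_sizes[key] = max(self._replicon_sizes.get(key, 0), r.gene_index + 1)
            self._by_position[(r.genome_id, r.replicon_id, r.gene_index)] = r

    def locate(self, pid: str) -> Located:
        if "|" in pid:
            genome, locus = pid.split("|", 1)
            rec = self._by_locus.get((genome, locus))
        else:
            rec = next(
                (r for (g, l), r in self._by_locus.items() if l == pid), None
            )
        if rec is None:
            raise KeyError(f"id {pid!r} not found in gene table")
        return Located(
            genome_id=rec.genome_id,
            replicon_id=rec.replicon_id,
            topology=rec.topology,
            gene_index=rec.gene_index,
            n_genes=self._replicon_sizes[(rec.genome_id, rec.replicon_id)],
            locus_tag=rec.locus_tag,
            product=rec.product,
        )

    def at(self, genome_id: str, replicon_id: str, index: int) -> GeneRecord | None:
        return self._by_position.get((genome_id, replicon_id, index))


def ordinal_distance(i: int, j: int, n_genes: int, topology: str) -> int:
    d = abs(i - j)
    if topology == "circular" and n_genes > 0:
        d = min(d, n_genes - d)
    return d


@dataclass(frozen=True)
class CouplingRecord:
    """One coupled GTPase with every qualifying MglB partner."""

    gtpase_id: str
    replicon_id: str
    #: (mglb id, gene-index distance), nearest first
    partners: tuple[tuple[str, int], ...]

    @property
    def stoichiometry(self) -> str:
        return f"1:{len(self.partners)}"


def find_couplings(
    gtpases: Sequence[str],
    mglbs: Sequence[str],
    gene_index: GeneIndex,
    window: int = DEFAULT_WINDOW,
) -> list[CouplingRecord]:
    """All GTPase-MglB pairs within `window` ordinal genes on one replicon.

    Every qualifying pair is reported; a GTPase with no partner in range
    yields no record.  Raises KeyError for ids absent from the gene table.
    """
    mglb_loc = [(m, gene_index.locate(m)) for m in mglbs]
    out: list[CouplingRecord] = []
    for g in gtpases:
        loc = gene_index.locate(g)
        partners = []
        for m, ml in mglb_loc:
            if m == g:
                continue
            if (ml.genome_id, ml.replicon_id) != (loc.genome_id, loc.replicon_id):
                continue
            d = ordinal_distance(loc.gene_index, ml.gene_index, loc.n_genes, loc.topology)
            if 1 <= d <= window:
                partners.append((m, d))
        if partners:
            partners.sort(key=lambda p: (p[1], p[0]))
            out.append(
                CouplingRecord(gtpase_id=g, replicon_id=loc.replicon_id, partners=tuple(partners))
            )
    return sorted(out, key=lambda c: c.gtpase_id)


@dataclass
class ContextSummary:
    coupled_gtpases: dict[str, str]  # gtpase id -> stoichiometry label
    orphan_gtpases: list[str]
    coupled_mglbs: list[str]
    orphan_mglbs: list[str]
    stoichiometry_counts: Counter = field(default_factory=Counter)


def classify_stoichiometry(
    gtpases: Sequence[str],
    mglbs: Sequence[str],
    couplings: Sequence[CouplingRecord],
) -> ContextSummary:
    """Partition both families into coupled and orphan; label 1:k systems.

    Stoichiometry counts up to two partners verbatim as "1:1"/"1:2";
    larger k is reported as "1:k" with the observed k (not an error).
    Every input id lands in exactly one of {coupled, orphan}.
    """
    by_gtpase = {c.gtpase_id: c for c in couplings}
    coupled_g: dict[str, str] = {}
    for g in gtpases:
        c = by_gtpase.get(g)
        if c is not None:
            coupled_g[g] = c.stoichiometry
    orphan_g = sorted(set(gtpases) - set(coupled_g))
    coupled_b = sorted(
        {m for c in couplings for m, _ in c.partners}
    )
    orphan_b = sorted(set(mglbs) - set(coupled_b))
    counts = Counter(coupled_g.values())
    return ContextSummary(
        coupled_gtpases=coupled_g,
        orphan_gtpases=orphan_g,
        coupled_mglbs=coupled_b,
        orphan_mglbs=orphan_b,
        stoichiometry_counts=counts,
    )


def neighborhood_composition(
    system_ids: Sequence[str],
    gene_index: GeneIndex,
    window: int = DEFAULT_WINDOW,
) -> list[tuple[str, str]]:
    """Products of genes within `window` of any system gene.

    The system's own genes are excluded; results are ``(locus_tag,
    product)`` ordered by gene index (a label multiset with positions).
    window=0 yields an empty list.
    """
    if not system_ids:
        return []
    own = set()
    spans: list[Located] = []
    for pid in system_ids:
        loc = gene_index.locate(pid)
        own.add((loc.genome_id, loc.locus_tag))
        spans.append(loc)
    seen: dict[tuple[str, str, int], tuple[str, str]] = {}
    for loc in spans:
        for off in range(-window, window + 1):
            idx = loc.gene_index + off
            if loc.topology == "circular":
                idx %= loc.n_genes
            elif not (0 <= idx < loc.n_genes):
                continue
            rec = gene_index.at(loc.genome_id, loc.replicon_id, idx)
            if rec is None or (rec.genome_id, rec.locus_tag) in own:
                continue
            seen[(loc.genome_id, loc.replicon_id, idx)] = (rec.locus_tag, rec.product)
    return [seen[k] for k in sorted(seen)]
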