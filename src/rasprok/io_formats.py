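"""Readers and writers for the on-disk formats the census pipeline touches.

Dialects are strict: malformed input is rejected with an error naming the
file and line rather than silently repaired.  Sequence coordinates are
1-based inclusive throughout; gene indices are 0-based ordinals along a
replicon.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import skbio

__all__ = [
    "FormatError",
    "GeneRecord",
    "DomainHit",
    "SimilarityHit",
    "read_gene_table",
    "write_gene_table",
    "read_fasta",
    "write_fasta",
    "read_similarity_hits",
    "write_similarity_hits",
    "read_domain_hits",
    "write_domain_hits",
    "read_newick",
    "write_newick",
    "read_json",
    "write_json",
]

GENE_TABLE_COLUMNS = (
    "genome_id",
    "replicon_id",
    "topology",
    "locus_tag",
    "gene_index",
    "start",
    "end",
    "strand",
    "product",
)

#: outfmt-6 compatible column order; the last two are reserved (written as ".").
SIMILARITY_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "rsv1",
    "rsv2",
)


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""

    def __init__(self, message: str, path: str | Path | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc += ": "
        super().__init__(loc + message)


@dataclass(frozen=True)
class GeneRecord:
    """One gene on a replicon of a (possibly multi-replicon) genome."""

    genome_id: str
    replicon_id: str
    topology: str  # "circular" | "linear"
    locus_tag: str
    gene_index: int  # 0-based ordinal position along the replicon
    start: int  # 1-based inclusive nucleotide coordinates
    end: int
    strand: str  # "+" | "-"
    product: str = ""

    def __post_init__(self):
        if not self.locus_tag:
            raise ValueError("locus_tag must be non-empty")
        if self.start > self.end:
            raise ValueError(f"start > end for {self.locus_tag}")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class DomainHit:
    """A scored domain-model match on a protein (domtblout-style)."""

    protein_id: str
    domain_name: str
    ali_from: int  # 1-based inclusive residue coordinates
    ali_to: int
    bit_score: float
    e_value: float
    clan_name: str | None = None

    def __post_init__(self):
        if self.ali_from > self.ali_to:
            raise ValueError(f"ali_from > ali_to for {self.protein_id}/{self.domain_name}")
        if not math.isfinite(self.bit_score):
            raise ValueError("bit_score must be finite")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


@dataclass(frozen=True)
class SimilarityHit:
    """A pairwise local-alignment hit (12-column tabular compatible)."""

    query_id: str
    subject_id: str
    pct_identity: float
    ali_length: int
    q_from: int
    q_to: int
    s_from: int
    s_to: int
    e_value: float
    bit_score: float

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if min(self.q_from, self.q_to, self.s_from, self.s_to) < 1:
            raise ValueError("alignment coordinates are 1-based")


# ---------------------------------------------------------------------------
# gene tables


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a TSV gene table; validates uniqueness and index contiguity.

    Records are returned grouped by (genome, replicon) and sorted by
    gene_index.  Within a replicon the gene_index values must be exactly
    0..n-1 with no duplicates or gaps.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if tuple(header.split("\t")) != GENE_TABLE_COLUMNS:
            raise FormatError(
                f"bad header; expected {list(GENE_TABLE_COLUMNS)}", path, 1
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(GENE_TABLE_COLUMNS):
                raise FormatError(
                    f"expected {len(GENE_TABLE_COLUMNS)} columns, got {len(parts)}",
                    path,
                    lineno,
                )
            try:
                rec = GeneRecord(
                    genome_id=parts[0],
                    replicon_id=parts[1],
                    topology=parts[2],
                    locus_tag=parts[3],
                    gene_index=int(parts[4]),
                    start=int(parts[5]),
                    end=int(parts[6]),
                    strand=parts[7],
                    product=parts[8],
                )
            except ValueError as exc:
                raise FormatError(str(exc), path, lineno) from exc
            records.append(rec)
    _validate_gene_records(records, path)
    return sorted(records, key=lambda r: (r.genome_id, r.replicon_id, r.gene_index))


def _validate_gene_records(records: Iterable[GeneRecord], path=None) -> None:
    seen_tags: dict[tuple[str, str], None] = {}
    by_replicon: dict[tuple[str, str], list[int]] = {}
    for rec in records:
        key = (rec.genome_id, rec.locus_tag)
        if key in seen_tags:
            raise FormatError(
                f"duplicate locus_tag {rec.locus_tag!r} in genome {rec.genome_id}", path
            )
        seen_tags[key] = None
        by_replicon.setdefault((rec.genome_id, rec.replicon_id), []).append(rec.gene_index)
    for (genome, replicon), idx in by_replicon.items():
        if sorted(idx) != list(range(len(idx))):
            raise FormatError(
                f"gene_index not consecutive 0..n-1 on replicon {replicon} of {genome}",
                path,
            )


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    records = sorted(records, key=lambda r: (r.genome_id, r.replicon_id, r.gene_index))
    _validate_gene_records(records)
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.genome_id,
                        r.replicon_id,
                        r.topology,
                        r.locus_tag,
                        str(r.gene_index),
                        str(r.start),
                        str(r.end),
                        r.strand,
                        r.product,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> uppercase sequence map.

    The id is the full header line up to the first whitespace.  Duplicate
    ids and empty sequences are rejected.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []

    def _flush(lineno):
        if current is not None:
            seq = "".join(chunks).upper()
            if not seq:
                raise FormatError(f"empty sequence for {current!r}", path, lineno)
            seqs[current] = seq

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                current = line[1:].split()[0] if len(line) > 1 else ""
                if not current:
                    raise FormatError("empty FASTA header", path, lineno)
                if current in seqs:
                    raise FormatError(f"duplicate id {current!r}", path, lineno)
                chunks = []
            else:
                if current is None:
                    raise FormatError("sequence data before first header", path, lineno)
                chunks.append(line)
        _flush(None)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# similarity hits (outfmt-6 compatible, 12 columns)


def read_similarity_hits(path: str | Path) -> list[SimilarityHit]:
    path = Path(path)
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(f"expected 12 columns, got {len(parts)}", path, lineno)
            try:
                hit = SimilarityHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    pct_identity=float(parts[2]),
                    ali_length=int(parts[3]),
                    q_from=int(parts[4]),
                    q_to=int(parts[5]),
                    s_from=int(parts[6]),
                    s_to=int(parts[7]),
                    e_value=float(parts[8]),
                    bit_score=float(parts[9]),
                )
            except ValueError as exc:
                raise FormatError(str(exc), path, lineno) from exc
            hits.append(hit)
    return hits


def write_similarity_hits(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        str(h.ali_length),
                        str(h.q_from),
                        str(h.q_to),
                        str(h.s_from),
                        str(h.s_to),
                        f"{h.e_value:.3g}",
                        f"{h.bit_score:.1f}",
                        ".",
                        ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# domain hits (domtblout-compatible)

# Consumed domtblout (per-domain) columns, 0-based:
#   0 target(domain) name, 3 query(protein) name, 12 i-Evalue, 13 domain score,
#   17 ali from, 18 ali to, 22+ description (optionally "clan=<name>").
_DOMTBL_MIN_COLS = 23


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    path = Path(path)
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < _DOMTBL_MIN_COLS:
                raise FormatError(
                    f"expected >= {_DOMTBL_MIN_COLS} whitespace columns, got {len(parts)}",
                    path,
                    lineno,
                )
            desc = " ".join(parts[22:])
            clan = None
            for token in desc.split():
                if token.startswith("clan="):
                    clan = token[5:] or None
            try:
                hit = DomainHit(
                    protein_id=parts[3],
                    domain_name=parts[0],
                    ali_from=int(parts[17]),
                    ali_to=int(parts[18]),
                    bit_score=float(parts[13]),
                    e_value=float(parts[12]),
                    clan_name=clan,
                )
            except ValueError as exc:
                raise FormatError(str(exc), path, lineno) from exc
            hits.append(hit)
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in a domtblout-compatible whitespace layout.

    Columns not carried by :class:`DomainHit` are emitted as "-" / 0
    placeholders; the clan, when present, rides in the description field.
    """
    with open(path, "w") as fh:
        fh.write("# domain hits (domtblout-compatible)\n")
        for h in hits:
            desc = f"clan={h.clan_name}" if h.clan_name else "-"
            row = [
                h.domain_name,  # 0 target name
                "-",  # 1 accession
                "0",  # 2 tlen
                h.protein_id,  # 3 query name
                "-",  # 4 accession
                "0",  # 5 qlen
                f"{h.e_value:.3g}",  # 6 full E-value
                f"{h.bit_score:.1f}",  # 7 full score
                "0.0",  # 8 bias
                "1",  # 9 this domain #
                "1",  # 10 of
                f"{h.e_value:.3g}",  # 11 c-Evalue
                f"{h.e_value:.3g}",  # 12 i-Evalue
                f"{h.bit_score:.1f}",  # 13 domain score
                "0.0",  # 14 bias
                "0",  # 15 hmm from
                "0",  # 16 hmm to
                str(h.ali_from),  # 17 ali from
                str(h.ali_to),  # 18 ali to
                str(h.ali_from),  # 19 env from
                str(h.ali_to),  # 20 env to
                "0.00",  # 21 acc
                desc,  # 22 description
            ]
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# Newick trees


def read_newick(source: str | Path) -> skbio.TreeNode:
    """Read a single-tree Newick file; duplicate leaf labels are rejected."""
    tree = skbio.TreeNode.read(str(source), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise FormatError(f"duplicate leaf labels {dupes}", source)
    return tree


def parse_newick(text: str) -> skbio.TreeNode:
    """Parse a Newick string (same validation as :func:`read_newick`)."""
    tree = skbio.TreeNode.read(io.StringIO(text), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise FormatError("duplicate leaf labels")
    return tree


def write_newick(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def tree_to_newick(tree: skbio.TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# JSON helpers (manifest et al.)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
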