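"""Synthetic prokaryotic genomes with planted small-GTPase/MglB systems.

The generator emits desk-scale gene tables, proteomes, domain annotations
and a ground-truth manifest so that every downstream census stage (homolog
harvesting, coupling analysis, motif profiling, tree building, family
classification) can be tested against a known answer without any database
searches.

What is planted
---------------
* Five MglA groups and two Rup groups of Ras-superfamily small GTPases.
  Each group carries its own G1-G5 motif set: the intrinsic-arginine
  Group 1 type (G2 ``TR``, G3 ``TVPGQ``), the shared Groups 2-5 type
  (G2 threonine pair, G3 ``GTPGQ``), and the two eukaryote-like Rup types
  (G3 ``DTAGQ`` with, ``DTAGE`` without, the catalytic glutamine).
  Bacterial MglA groups additionally carry an insertion between G1 and G2
  that Rup (and the archaeal-style group) lack.
* MglB (Roadblock/LC7) partners coupled to each MglA gene within a
  configurable gene-index distance of at most four, including systems with
  two MglB genes per GTPase, plus orphan MglBs placed with enough clearance
  that they cannot couple to anything.
* Decoys: ABC-transporter-like architectures that spuriously carry a
  GTPase domain label, truncations shorter than 150 aa that have lost
  motifs, and long Roco-like proteins with N-terminal leucine-rich repeats.

Sequences are simulated hierarchically: a family-level background makes
groups of one family recognizably related while the MglA and Rup families
are only distantly related, so seed searches largely stay within a family
and the domain-architecture collection route is what first bridges
families, as in a real iterative harvest.  Members within a group diverge
by substitutions only (no indels), with motif windows frozen.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import skbio

from .io_formats import (
    DomainHit,
    GeneRecord,
    tree_to_newick,
    write_domain_hits,
    write_fasta,
    write_gene_table,
    write_json,
)

__all__ = [
    "SimulationConfig",
    "MotifTemplate",
    "CensusData",
    "SizingError",
    "TEMPLATES",
    "MOTIF_NAMES",
    "generate_census",
    "realize_template",
    "evolve_family",
    "write_census",
]

MOTIF_NAMES = ("G1", "G2", "G3", "G4", "G5")

# Fixed background amino-acid frequency table (uniform-ish with a realistic
# skew toward A/L/G/S and away from C/W).  Chosen once for reproducibility.
AA = "ACDEFGHIKLMNPQRSTVWY"
BG_FREQS = np.array(
    [
        0.083,  # A
        0.014,  # C
        0.055,  # D
        0.062,  # E
        0.040,  # F
        0.072,  # G
        0.022,  # H
        0.057,  # I
        0.058,  # K
        0.092,  # L
        0.024,  # M
        0.044,  # N
        0.047,  # P
        0.037,  # Q
        0.052,  # R
        0.066,  # S
        0.055,  # T
        0.069,  # V
        0.013,  # W
        0.038,  # Y
    ]
)
BG_FREQS = BG_FREQS / BG_FREQS.sum()

_SEGMENT = 12  # genes per placement segment; guarantees >=5 cross-item clearance


class SizingError(ValueError):
    """Configuration asks for more planted material than fits."""


@dataclass(frozen=True)
class MotifTemplate:
    """Blueprint for one group's G-domain layout.

    Motif consensus strings use a tiny ambiguity grammar: an uppercase
    letter is fixed, ``x`` is drawn from the background table, and
    ``[TS]`` is a uniform choice over the bracketed set.
    """

    group: str
    g1: str
    g2: str
    g3: str
    g4: str
    g5: str
    mechanism: str
    leader: int = 8
    spacer_g1_g2: int = 24  # base spacing, before any insertion
    g1_g2_insertion_length: int = 0
    spacer_g2_g3: int = 12
    spacer_g3_g4: int = 45
    spacer_g4_g5: int = 20
    total_length: int = 180
    #: 0-based offset of the conserved G2 threonine within the G2 window
    g2_thr_offset: int = 1

    def motif_strings(self) -> dict[str, str]:
        return {"G1": self.g1, "G2": self.g2, "G3": self.g3, "G4": self.g4, "G5": self.g5}

    def minimum_length(self) -> int:
        toks = {m: _parse_consensus(s) for m, s in self.motif_strings().items()}
        return (
            self.leader
            + sum(len(t) for t in toks.values())
            + self.spacer_g1_g2
            + self.g1_g2_insertion_length
            + self.spacer_g2_g3
            + self.spacer_g3_g4
            + self.spacer_g4_g5
        )


def _parse_consensus(s: str) -> list[str]:
    """Parse a consensus string into per-position residue sets ('' = background)."""
    out: list[str] = []
    i = 0
    while i < len(s):
        c = s[i]
        if c == "[":
            j = s.index("]", i)
            body = s[i + 1 : j].replace("/", "")
            out.append(body)
            i = j + 1
        elif c == "x":
            out.append("")
            i += 1
        else:
            out.append(c)
            i += 1
    return out


def _draw_bg(rng: np.random.Generator, n: int) -> str:
    idx = rng.choice(20, size=n, p=BG_FREQS)
    return "".join(AA[i] for i in idx)


def realize_template(template: MotifTemplate, rng: np.random.Generator):
    """Instantiate a template into a concrete protein sequence.

    Returns ``(sequence, offsets)`` where ``offsets`` maps motif name to
    its 1-based inclusive (start, end) residue coordinates.

    Raises :class:`SizingError` when motifs plus spacers exceed the
    declared total length.
    """
    if template.minimum_length() > template.total_length:
        raise SizingError(
            f"template {template.group}: motifs+spacers "
            f"({template.minimum_length()}) exceed total_length ({template.total_length})"
        )
    parts: list[str] = []
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0

    def emit_bg(n):
        nonlocal pos
        parts.append(_draw_bg(rng, n))
        pos += n

    def emit_motif(name, consensus):
        nonlocal pos
        toks = _parse_consensus(consensus)
        chars = []
        for t in toks:
            if t == "":
                chars.append(_draw_bg(rng, 1))
            elif len(t) == 1:
                chars.append(t)
            else:
                chars.append(t[rng.integers(len(t))])
        parts.append("".join(chars))
        offsets[name] = (pos + 1, pos + len(toks))
        pos += len(toks)

    emit_bg(template.leader)
    emit_motif("G1", template.g1)
    emit_bg(template.spacer_g1_g2 + template.g1_g2_insertion_length)
    emit_motif("G2", template.g2)
    emit_bg(template.spacer_g2_g3)
    emit_motif("G3", template.g3)
    emit_bg(template.spacer_g3_g4)
    emit_motif("G4", template.g4)
    emit_bg(template.spacer_g4_g5)
    emit_motif("G5", template.g5)
    emit_bg(template.total_length - pos)
    return "".join(parts), offsets


def motif_mask(template: MotifTemplate, offsets: dict[str, tuple[int, int]], length: int) -> np.ndarray:
    """Boolean array: True where substitutions are allowed (background only)."""
    mask = np.ones(length, dtype=bool)
    for s, e in offsets.values():
        mask[s - 1 : e] = False
    return mask


def _root_from_template(template: MotifTemplate, bg: str, rng: np.random.Generator):
    """Instantiate a template with background drawn from a family background.

    Non-insertion background segments take residues from `bg` at canonical
    positions shared by every template (all templates have equal motif and
    spacer lengths), so homologous sites correspond across the groups of a
    family; the G1-G2 insertion is drawn fresh (non-homologous between
    groups), making it a true indel relative to insertion-free templates.
    Returns ``(sequence, motif offsets)``.
    """
    if template.minimum_length() > template.total_length:
        raise SizingError(f"template {template.group}: motifs+spacers exceed total_length")
    parts: list[str] = []
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0  # position in the emitted sequence
    canon = 0  # canonical position in the family background

    def emit_bg(n):
        nonlocal pos, canon
        parts.append(bg[canon : canon + n])
        pos += n
        canon += n

    def emit_insertion(n):
        nonlocal pos
        parts.append(_draw_bg(rng, n))
        pos += n

    def emit_motif(name, consensus):
        nonlocal pos, canon
        toks = _parse_consensus(consensus)
        chars = []
        for t in toks:
            if t == "":
                chars.append(_draw_bg(rng, 1))
            elif len(t) == 1:
                chars.append(t)
            else:
                chars.append(t[rng.integers(len(t))])
        parts.append("".join(chars))
        offsets[name] = (pos + 1, pos + len(toks))
        pos += len(toks)
        canon += len(toks)

    emit_bg(template.leader)
    emit_motif("G1", template.g1)
    emit_bg(template.spacer_g1_g2)
    emit_insertion(template.g1_g2_insertion_length)
    emit_motif("G2", template.g2)
    emit_bg(template.spacer_g2_g3)
    emit_motif("G3", template.g3)
    emit_bg(template.spacer_g3_g4)
    emit_motif("G4", template.g4)
    emit_bg(template.spacer_g4_g5)
    emit_motif("G5", template.g5)
    emit_bg(template.total_length - pos)
    return "".join(parts), offsets


# ---------------------------------------------------------------------------
# group templates

TEMPLATES: dict[str, MotifTemplate] = {
    # Group 1: intrinsic arginine finger adjacent to the G2 threonine,
    # distinctive TVPGQ switch-II motif.
    "MglA-1": MotifTemplate(
        group="MglA-1",
        g1="GxxxxGK[T/S]", g2="GTRPE", g3="TVPGQ", g4="[N/T]KxD", g5="SA[K/L]",
        mechanism="INTRINSIC_ARG", g1_g2_insertion_length=12, total_length=195,
    ),
    # Groups 2-5: threonine in place of the arginine, shared GTPGQ motif.
    "MglA-2": MotifTemplate(
        group="MglA-2",
        g1="GxxxxGK[T/S]", g2="GTTPE", g3="GTPGQ", g4="NxFD", g5="DAR",
        mechanism="G2THR_GTPGQ", g1_g2_insertion_length=10, total_length=176,
    ),
    "MglA-3": MotifTemplate(
        group="MglA-3",
        g1="GxxxxGK[T/S]", g2="GTTPE", g3="GTPGQ", g4="NxxD", g5="DAR",
        mechanism="G2THR_GTPGQ", g1_g2_insertion_length=11, total_length=185,
    ),
    # Group 4 is the archaeal-style group: no G1-G2 insertion.
    "MglA-4": MotifTemplate(
        group="MglA-4",
        g1="GxxxxGK[T/S]", g2="GTTPE", g3="GTPGQ", g4="[N/T]KxD", g5="SA[K/L]",
        mechanism="G2THR_GTPGQ", g1_g2_insertion_length=0, total_length=172,
    ),
    "MglA-5": MotifTemplate(
        group="MglA-5",
        g1="GxxxxGK[T/S]", g2="GTTPE", g3="GTPGQ", g4="[N/T]KxD", g5="SA[K/L]",
        mechanism="G2THR_GTPGQ", g1_g2_insertion_length=14, total_length=190,
    ),
    # Rup groups: eukaryote-like conservation; Group 1 lacks the catalytic
    # glutamine of switch II, Group 2 retains it.
    "Rup-1": MotifTemplate(
        group="Rup-1",
        g1="GxxxxGK[T/S]", g2="GTxPE", g3="DTAGE", g4="NKxD", g5="SAK",
        mechanism="RAS_LIKE_NO_Q", total_length=178,
    ),
    "Rup-2": MotifTemplate(
        group="Rup-2",
        g1="GxxxxGK[T/S]", g2="GTxPE", g3="DTAGQ", g4="[N/T]KxD", g5="SAL",
        mechanism="RAS_LIKE_Q", total_length=165,
    ),
}

MGLA_GROUPS = ("MglA-1", "MglA-2", "MglA-3", "MglA-4", "MglA-5")
RUP_GROUPS = ("Rup-1", "Rup-2")

#: domain labels used by the synthetic annotator (P-loop NTPase clan members)
GTPASE_DOMAINS = ("Miro", "Ras", "Arf", "ATP_bind_1")
GTPASE_DOMAIN_WEIGHTS = (0.35, 0.30, 0.20, 0.15)
ABC_DOMAINS = ("ABC_tran", "AAA_21")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic census.

    Defaults describe a desk-scale census of 30 genomes carrying roughly
    six planted items per genome at low within-group divergence.
    """

    seed: int
    n_genomes: int = 30
    genes_per_replicon: int = 84
    replicon_topology: str = "circular"
    mgla_systems: tuple[int, int, int, int, int] = (16, 14, 12, 10, 10)
    rup_systems: tuple[int, int] = (12, 8)
    frac_orphan_mglb: float = 0.4
    frac_1to2_systems: float = 0.1
    coupling_distance_weights: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    n_decoy_abc: int = 8
    n_truncations: int = 6
    n_roco: int = 6
    #: expected substitutions/site from a group root to each member
    substitution_rate: float = 0.2
    #: divergence between group roots within one family
    group_divergence: float = 0.30
    #: divergence separating the MglA and Rup family backgrounds
    family_divergence: float = 0.7

    def __post_init__(self):
        counts = (
            self.n_genomes,
            self.genes_per_replicon,
            *self.mgla_systems,
            *self.rup_systems,
            self.n_decoy_abc,
            self.n_truncations,
            self.n_roco,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        for f in (self.frac_orphan_mglb, self.frac_1to2_systems):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.substitution_rate < 0:
            raise ValueError("substitution_rate must be >= 0")
        if self.replicon_topology not in ("circular", "linear"):
            raise ValueError("replicon_topology must be circular|linear")
        if len(self.coupling_distance_weights) != 4 or any(
            w < 0 for w in self.coupling_distance_weights
        ) or sum(self.coupling_distance_weights) == 0:
            raise ValueError("coupling_distance_weights: four non-negative weights, not all zero")


@dataclass
class CensusData:
    """In-memory bundle produced by :func:`generate_census`."""

    gene_records: list[GeneRecord]
    proteome: dict[str, str]  # protein_id ("genome|locus") -> sequence
    domain_hits: list[DomainHit]
    manifest: dict
    true_trees: dict[str, str]  # label -> newick

    def proteomes_by_genome(self) -> dict[str, dict[str, str]]:
        out: dict[str, dict[str, str]] = {}
        for pid, seq in self.proteome.items():
            out.setdefault(pid.split("|")[0], {})[pid] = seq
        return out


# ---------------------------------------------------------------------------
# evolution


def _random_ultrametric_tree(leaf_names: list[str], depth: float, rng: np.random.Generator) -> skbio.TreeNode:
    """Random balanced ultrametric tree: every root-to-tip path = depth.

    The leaf set is split recursively into random halves and node heights
    scale with log2 of the subtree size, so internal edges are of order
    depth/log2(n) rather than depth/n - every edge then carries a
    resolvable number of substitutions, which is what a planted-truth
    benchmark needs.
    """
    total = len(leaf_names)
    log_total = max(math.log2(total), 1.0)

    def height(n_leaves: int) -> float:
        return depth * math.log2(n_leaves) / log_total if n_leaves > 1 else 0.0

    def build(names: list[str]) -> skbio.TreeNode:
        if len(names) == 1:
            return skbio.TreeNode(name=names[0])
        names = list(names)
        rng.shuffle(names)
        half = len(names) // 2
        left, right = sorted(names[:half]), sorted(names[half:])
        node = skbio.TreeNode()
        for part in (left, right):
            child = build(part)
            child.length = height(len(names)) - height(len(part))
            node.append(child)
        return node

    return build(sorted(leaf_names))


def _mutate(seq: str, t: float, mask: np.ndarray, rng: np.random.Generator) -> str:
    """Apply substitutions at rate t (expected subs/site) at allowed positions.

    A fraction 1 - exp(-t) of the allowed sites (rounded to a fixed count,
    sampled without replacement) substitutes; a substitution draws a
    background residue different from the current one.  The fixed count
    keeps the realized divergence at its expectation on every branch, so
    short internal branches still leave a phylogenetic trace.
    """
    if t <= 0:
        return seq
    p = 1.0 - math.exp(-t)
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    free = np.flatnonzero(mask)
    m = int(round(p * len(free)))
    if m == 0 and p > 0 and len(free) > 0:
        m = 1
    hit = np.zeros(len(seq), dtype=bool)
    if len(free):
        hit[rng.choice(free, size=min(m, len(free)), replace=False)] = True
    for i in np.flatnonzero(hit):
        cur = arr[i]
        while True:
            new = AA[rng.choice(20, p=BG_FREQS)]
            if new != cur:
                break
        arr[i] = new
    return "".join(arr)


def evolve_family(
    root: str,
    leaf_names: list[str],
    rate: float,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
    tree: skbio.TreeNode | None = None,
    leaf_map: dict[str, str] | None = None,
) -> tuple[dict[str, str], skbio.TreeNode]:
    """Diverge `root` into one sequence per leaf along a random (or given) tree.

    `rate` is the expected substitutions per free site from root to each
    tip.  Positions where `mask` is False (motif windows) are never touched.
    When `tree` is given its shape is reused and tips are renamed through
    `leaf_map` (old tip name -> new name), preserving the correspondence.
    Returns ``(leaf_name -> sequence, true tree)``; the returned tree is a
    fresh copy with the requested leaf names.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if mask is None:
        mask = np.ones(len(root), dtype=bool)
    if not leaf_names:
        return {}, None
    if len(leaf_names) == 1:
        t = skbio.TreeNode(name=leaf_names[0])
        t.length = rate
        return {leaf_names[0]: _mutate(root, rate, mask, rng)}, t
    if tree is None:
        tree = _random_ultrametric_tree(list(leaf_names), rate, rng)
    else:
        tree = tree.copy()
        tips = list(tree.tips())
        if len(tips) != len(leaf_names):
            raise ValueError("tree leaf count does not match leaf_names")
        if leaf_map is None:
            leaf_map = dict(zip([t.name for t in tips], leaf_names))
        for tip in tips:
            tip.name = leaf_map[tip.name]
        # rescale donor branch lengths so root-to-tip depth equals `rate`
        depth = max(
            sum(n.length or 0.0 for n in tip.ancestors() if n.length is not None) + (tip.length or 0.0)
            for tip in tips
        )
        if depth > 0 and rate > 0:
            scale = rate / depth
            for n in tree.traverse(include_self=False):
                if n.length is not None:
                    n.length *= scale
    seqs: dict[str, str] = {}

    def descend(node, seq):
        for child in node.children:
            bl = child.length or 0.0
            child_seq = _mutate(seq, bl, mask, rng)
            if child.is_tip():
                seqs[child.name] = child_seq
            else:
                descend(child, child_seq)

    descend(tree, root)
    return seqs, tree


# ---------------------------------------------------------------------------
# placement planning


@dataclass
class _Item:
    kind: str  # system | rup | orphan_mglb | abc | truncation | roco
    group: str | None = None
    distance: int | None = None
    one_to_two: bool = False
    # filled during placement:
    genome: str | None = None
    gene_slots: dict[str, int] = field(default_factory=dict)  # role -> gene index
    locus: dict[str, str] = field(default_factory=dict)  # role -> locus tag


def _plan_items(config: SimulationConfig, rng: np.random.Generator) -> list[_Item]:
    items: list[_Item] = []
    weights = np.asarray(config.coupling_distance_weights, dtype=float)
    weights = weights / weights.sum()
    w3 = weights[:3] / weights[:3].sum() if weights[:3].sum() > 0 else np.array([1, 0, 0.0])

    n_mgla = sum(config.mgla_systems)
    n_1to2 = int(round(config.frac_1to2_systems * n_mgla))
    one_to_two_flags = [True] * n_1to2 + [False] * (n_mgla - n_1to2)
    rng.shuffle(one_to_two_flags)
    k = 0
    for group, count in zip(MGLA_GROUPS, config.mgla_systems):
        for _ in range(count):
            two = one_to_two_flags[k]
            k += 1
            if group == "MglA-2":
                # conservon block: kinase, MglB, unknown, MglA -> distance 2
                d = 2
            elif two:
                d = int(rng.choice(3, p=w3)) + 1
            else:
                d = int(rng.choice(4, p=weights)) + 1
            items.append(_Item(kind="system", group=group, distance=d, one_to_two=two))
    for group, count in zip(RUP_GROUPS, config.rup_systems):
        items.extend(_Item(kind="rup", group=group) for _ in range(count))
    n_coupled_mglb = n_mgla + n_1to2
    if config.frac_orphan_mglb < 1:
        n_orphan = int(round(n_coupled_mglb * config.frac_orphan_mglb / (1 - config.frac_orphan_mglb)))
    else:
        n_orphan = 0
    for i in range(n_orphan):
        items.append(_Item(kind="orphan_mglb", group=MGLA_GROUPS[i % len(MGLA_GROUPS)]))
    items.extend(_Item(kind="abc") for _ in range(config.n_decoy_abc))
    for i in range(config.n_truncations):
        items.append(_Item(kind="truncation", group=MGLA_GROUPS[i % len(MGLA_GROUPS)]))
    for i in range(config.n_roco):
        items.append(_Item(kind="roco", group=RUP_GROUPS[i % len(RUP_GROUPS)]))
    return items


def _place_items(config: SimulationConfig, items: list[_Item], master: np.random.Generator):
    """Assign items to genomes and concrete gene indices (segment scheme).

    Each item occupies its own 12-gene segment; in-segment offsets keep at
    least 5 ordinal positions between genes of different items (also across
    the circular wrap), so planted couplings and orphanhood are unambiguous
    under the window-4 rule.
    """
    if config.genes_per_replicon < _SEGMENT:
        if items:
            raise SizingError("genes_per_replicon too small for any planted item")
        segs_per_genome = 0
    else:
        segs_per_genome = config.genes_per_replicon // _SEGMENT
    order = list(range(len(items)))
    master.shuffle(order)
    capacity = segs_per_genome * config.n_genomes
    if len(items) > capacity:
        raise SizingError(
            f"{len(items)} planted items exceed capacity {capacity} "
            f"({config.n_genomes} genomes x {segs_per_genome} segments)"
        )
    # deal shuffled items round-robin across genomes
    per_genome: list[list[_Item]] = [[] for _ in range(config.n_genomes)]
    for pos, item_idx in enumerate(order):
        per_genome[pos % config.n_genomes].append(items[item_idx])

    for g in range(config.n_genomes):
        genome_id = f"G{g:03d}"
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1000 + g,)))
        seg_ids = list(range(segs_per_genome))
        rng.shuffle(seg_ids)
        for item, seg in zip(per_genome[g], seg_ids):
            base = seg * _SEGMENT
            item.genome = genome_id
            if item.kind == "system":
                d = item.distance
                extra = 1 if item.one_to_two else 0
                hi = 7 - d - extra
                a = int(rng.integers(3, hi + 1)) if hi >= 3 else 3
                slots = {"gtpase": base + a, "mglb": base + a + d}
                if item.one_to_two:
                    slots["mglb2"] = base + a + d + 1
                if item.group == "MglA-2":
                    # conservon: CvnA kinase, CvnB (MglB), CvnC unknown, CvnD (MglA)
                    a = int(rng.integers(3, 5))
                    slots = {
                        "kinase": base + a,
                        "mglb": base + a + 1,
                        "unknown": base + a + 2,
                        "gtpase": base + a + 3,
                    }
                    if item.one_to_two:
                        slots["mglb2"] = base + a + 4
                elif item.group in ("MglA-1", "MglA-5") and rng.random() < 0.3:
                    if a - 1 >= base + 2:
                        slots["patan"] = base + a - 1
                item.gene_slots = slots
            elif item.kind in ("rup", "orphan_mglb", "abc", "truncation", "roco"):
                a = int(rng.integers(3, 8))
                role = {"rup": "gtpase", "orphan_mglb": "mglb"}.get(item.kind, item.kind)
                item.gene_slots = {role: base + a}
    return per_genome


_PRODUCTS = {
    "gtpase": "Ras-superfamily small GTPase",
    "mglb": "MglB-like Roadblock/LC7 protein",
    "mglb2": "MglB-like Roadblock/LC7 protein",
    "kinase": "conservon histidine kinase CvnA",
    "unknown": "conservon protein CvnC",
    "patan": "PATAN-domain response regulator",
    "abc": "ABC transporter ATP-binding protein",
    "truncation": "Ras-superfamily small GTPase (fragment)",
    "roco": "Roco-family LRR-GTPase",
}


# ---------------------------------------------------------------------------
# the generator


def generate_census(config: SimulationConfig) -> CensusData:
    """Generate one synthetic census: genomes, proteome, annotation, truth.

    Deterministic for a fixed config (including seed).  Per-genome random
    substreams are derived by fixed splitting, so increasing ``n_genomes``
    does not reshuffle earlier genomes' placements.
    """
    master = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    items = _plan_items(config, master)
    per_genome = _place_items(config, items, master)

    # ---- sequence simulation (global streams, independent of placement rngs)
    rng_templates = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    rng_evo = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    rng_decoy = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(3,)))
    rng_annot = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(4,)))

    # family-level backgrounds derive from one superfamily background, so
    # the MglA and Rup families are distantly related (alignable but well
    # separated) while groups within a family are closer; group roots copy
    # their background positions from the family background and diverge.
    superfam_bg = _draw_bg(rng_templates, 400)
    all_free = np.ones(400, dtype=bool)
    fam_bg = {
        "mgla": _mutate(superfam_bg, config.family_divergence / 2, all_free, rng_templates),
        "rup": _mutate(superfam_bg, config.family_divergence / 2, all_free, rng_templates),
    }
    # Per-group backgrounds evolve along a group-level tree per family;
    # the MglB family background mirrors the MglA group tree, so the deep
    # (between-group) structure of the two families coevolves just like
    # the within-group structure does.
    group_bgs: dict[str, str] = {}
    mgla_group_tree = None
    for fam, groups in (("mgla", MGLA_GROUPS), ("rup", RUP_GROUPS)):
        bgs, gtree = evolve_family(
            fam_bg[fam], list(groups), config.group_divergence, rng_templates
        )
        group_bgs.update(bgs)
        if fam == "mgla":
            mgla_group_tree = gtree
    group_roots: dict[str, tuple[str, dict]] = {}
    for group, template in TEMPLATES.items():
        group_roots[group] = _root_from_template(template, group_bgs[group], rng_templates)

    # MglB family root and per-group roots (mirroring the MglA group tree)
    mglb_lengths = {g: 150 + 7 * i for i, g in enumerate(MGLA_GROUPS)}  # 150..178
    mglb_family_bg = _draw_bg(rng_templates, 200)
    mglb_group_bgs, _ = evolve_family(
        mglb_family_bg, list(MGLA_GROUPS), config.group_divergence, rng_templates,
        tree=mgla_group_tree, leaf_map={g: g for g in MGLA_GROUPS},
    )
    mglb_roots: dict[str, str] = {}
    for g in MGLA_GROUPS:
        L = mglb_lengths[g]
        base = mglb_group_bgs[g][:L]
        # conserved aspartate-glycine anchor shared by the family
        base = base[:60] + "LDG" + base[63:]
        mglb_roots[g] = base

    # ---- assign locus tags, gene tables, fillers
    gene_records: list[GeneRecord] = []
    proteome: dict[str, str] = {}
    manifest_proteins: dict[str, dict] = {}
    true_trees: dict[str, str] = {}

    role_by_gene: dict[tuple[str, int], tuple[_Item, str]] = {}
    for g_index in range(config.n_genomes):
        genome_id = f"G{g_index:03d}"
        for item in per_genome[g_index]:
            for role, idx in item.gene_slots.items():
                role_by_gene[(genome_id, idx)] = (item, role)
                item.locus[role] = f"{genome_id}_{idx:04d}"

    filler_rngs = {
        f"G{g:03d}": np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2000 + g,)))
        for g in range(config.n_genomes)
    }

    def add_protein(pid, seq, rec):
        proteome[pid] = seq
        rec["protein_id"] = pid
        rec["length"] = len(seq)
        manifest_proteins[pid] = rec

    # ---- evolve families group by group, naming leaves by final protein ids
    systems_by_group: dict[str, list[_Item]] = {g: [] for g in (*MGLA_GROUPS, *RUP_GROUPS)}
    for item in items:
        if item.kind in ("system", "rup"):
            systems_by_group[item.group].append(item)

    references: dict[str, str] = {}
    for group in (*MGLA_GROUPS, *RUP_GROUPS):
        template = TEMPLATES[group]
        group_items = systems_by_group[group]
        if not group_items:
            continue
        root, offsets = group_roots[group]
        mask = motif_mask(template, offsets, len(root))
        gt_ids = [f"{it.genome}|{it.locus['gtpase']}" for it in group_items]
        seqs, gt_tree = evolve_family(root, gt_ids, config.substitution_rate, rng_evo, mask=mask)
        if gt_tree is not None and len(gt_ids) > 1:
            true_trees[group] = tree_to_newick(gt_tree)
        references[group] = gt_ids[0]
        is_mgla = group.startswith("MglA")
        for it, pid in zip(group_items, gt_ids):
            partners = [it.locus["mglb"]] if is_mgla else []
            if it.one_to_two:
                partners.append(it.locus["mglb2"])
            add_protein(
                pid,
                seqs[pid],
                {
                    "genome_id": it.genome,
                    "locus_tag": it.locus["gtpase"],
                    "family": "mgla" if is_mgla else "rup",
                    "group": group,
                    "mechanism": template.mechanism,
                    "decoy_class": "none",
                    "coupled": is_mgla,
                    "partner_locus_tags": partners,
                    "coupling_distance": (
                        min(abs(it.gene_slots["gtpase"] - it.gene_slots[r])
                            for r in ("mglb", "mglb2") if r in it.gene_slots)
                        if is_mgla else None
                    ),
                    "motif_offsets": {k: list(v) for k, v in offsets.items()},
                    "insertion_length": template.g1_g2_insertion_length,
                },
            )
        # coupled MglB partners evolve along the same tree shape (coevolution)
        if is_mgla:
            mglb_ids = [f"{it.genome}|{it.locus['mglb']}" for it in group_items]
            L = len(mglb_roots[group])
            bmask = np.ones(L, dtype=bool)
            bmask[60:63] = False  # keep the DG anchor
            # MglB partners tick ~1.5x faster than their GTPases (shorter,
            # less constrained proteins), along the same tree shape
            bseqs, b_tree = evolve_family(
                mglb_roots[group], mglb_ids, config.substitution_rate * 1.5, rng_evo,
                mask=bmask, tree=gt_tree if len(mglb_ids) > 1 else None,
                leaf_map=dict(zip(gt_ids, mglb_ids)),
            )
            if b_tree is not None and len(mglb_ids) > 1:
                true_trees[f"mglb_{group}"] = tree_to_newick(b_tree)
            for it, pid in zip(group_items, mglb_ids):
                add_protein(
                    pid,
                    bseqs[pid],
                    {
                        "genome_id": it.genome,
                        "locus_tag": it.locus["mglb"],
                        "family": "mglb",
                        "group": group,
                        "mechanism": "none",
                        "decoy_class": "none",
                        "coupled": True,
                        "partner_locus_tags": [it.locus["gtpase"]],
                        "coupling_distance": it.distance,
                        "motif_offsets": {},
                        "insertion_length": 0,
                    },
                )
                if it.one_to_two:
                    pid2 = f"{it.genome}|{it.locus['mglb2']}"
                    seq2 = _mutate(bseqs[pid], 0.02, bmask, rng_evo)
                    add_protein(
                        pid2,
                        seq2,
                        {
                            "genome_id": it.genome,
                            "locus_tag": it.locus["mglb2"],
                            "family": "mglb",
                            "group": group,
                            "mechanism": "none",
                            "decoy_class": "none",
                            "coupled": True,
                            "partner_locus_tags": [it.locus["gtpase"]],
                            "coupling_distance": abs(it.gene_slots["mglb2"] - it.gene_slots["gtpase"]),
                            "motif_offsets": {},
                            "insertion_length": 0,
                        },
                    )

    # orphan MglBs: diverged singletons of their assigned group
    for item in items:
        if item.kind != "orphan_mglb":
            continue
        L = len(mglb_roots[item.group])
        bmask = np.ones(L, dtype=bool)
        bmask[60:63] = False
        seq = _mutate(mglb_roots[item.group], config.substitution_rate * 1.5, bmask, rng_evo)
        pid = f"{item.genome}|{item.locus['mglb']}"
        add_protein(
            pid,
            seq,
            {
                "genome_id": item.genome,
                "locus_tag": item.locus["mglb"],
                "family": "mglb",
                "group": item.group,
                "mechanism": "none",
                "decoy_class": "none",
                "coupled": False,
                "partner_locus_tags": [],
                "coupling_distance": None,
                "motif_offsets": {},
                "insertion_length": 0,
            },
        )

    # ---- decoys
    abc_root = _draw_bg(rng_decoy, 232)
    for item in items:
        if item.kind == "abc":
            seq = _mutate(abc_root, 0.05, np.ones(len(abc_root), dtype=bool), rng_decoy)
            pid = f"{item.genome}|{item.locus['abc']}"
            add_protein(pid, seq, _decoy_record(item, "abc", role="abc"))
        elif item.kind == "truncation":
            root, offsets = group_roots[item.group]
            template = TEMPLATES[item.group]
            mask = motif_mask(template, offsets, len(root))
            full = _mutate(root, 0.1, mask, rng_decoy)
            cut = int(offsets["G4"][0] - 1 - rng_decoy.integers(0, 8))  # drops G4 and G5
            seq = full[:cut]
            kept = {k: list(v) for k, v in offsets.items() if v[1] <= len(seq)}
            rec = _decoy_record(item, "truncation", role="truncation")
            rec["motif_offsets"] = kept
            pid = f"{item.genome}|{item.locus['truncation']}"
            add_protein(pid, seq, rec)
        elif item.kind == "roco":
            # N-terminal LRR repeats, then a Rup-derived G domain, then a tail
            unit = "LSELNLSNNQLTSLPESLFK"
            lrr = "".join(_mutate(unit, 0.15, np.ones(len(unit), dtype=bool), rng_decoy) for _ in range(7))
            root, offsets = group_roots[item.group]
            template = TEMPLATES[item.group]
            mask = motif_mask(template, offsets, len(root))
            gdom = _mutate(root, 0.15, mask, rng_decoy)
            tail = _draw_bg(rng_decoy, 60)
            seq = lrr + gdom + tail
            rec = _decoy_record(item, "roco", role="roco")
            shift = len(lrr)
            rec["motif_offsets"] = {k: [v[0] + shift, v[1] + shift] for k, v in offsets.items()}
            pid = f"{item.genome}|{item.locus['roco']}"
            add_protein(pid, seq, rec)

    # ---- neighbor/accessory proteins and fillers; gene records
    for g_index in range(config.n_genomes):
        genome_id = f"G{g_index:03d}"
        rng = filler_rngs[genome_id]
        pos = 1
        for idx in range(config.genes_per_replicon):
            locus = f"{genome_id}_{idx:04d}"
            hit = role_by_gene.get((genome_id, idx))
            if hit is not None:
                item, role = hit
                product = _PRODUCTS.get(role, "hypothetical protein")
                pid = f"{genome_id}|{locus}"
                if pid not in proteome:  # accessory neighbor (kinase/unknown/patan)
                    seq = _draw_bg(rng, int(rng.integers(140, 400)))
                    add_protein(
                        pid,
                        seq,
                        {
                            "genome_id": genome_id,
                            "locus_tag": locus,
                            "family": "filler",
                            "group": None,
                            "mechanism": "none",
                            "decoy_class": "none",
                            "coupled": False,
                            "partner_locus_tags": [],
                            "coupling_distance": None,
                            "motif_offsets": {},
                            "insertion_length": 0,
                            "accessory_role": role,
                        },
                    )
            else:
                product = "hypothetical protein"
                pid = f"{genome_id}|{locus}"
                seq = _draw_bg(rng, int(rng.integers(110, 171)))
                add_protein(
                    pid,
                    seq,
                    {
                        "genome_id": genome_id,
                        "locus_tag": locus,
                        "family": "filler",
                        "group": None,
                        "mechanism": "none",
                        "decoy_class": "none",
                        "coupled": False,
                        "partner_locus_tags": [],
                        "coupling_distance": None,
                        "motif_offsets": {},
                        "insertion_length": 0,
                    },
                )
            aa_len = len(proteome[pid])
            start = pos
            end = pos + aa_len * 3 + 2
            pos = end + 50
            gene_records.append(
                GeneRecord(
                    genome_id=genome_id,
                    replicon_id=f"{genome_id}_chr",
                    topology=config.replicon_topology,
                    locus_tag=locus,
                    gene_index=idx,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    product=product,
                )
            )

    domain_hits = _annotate(manifest_proteins, proteome, rng_annot)

    # seeds: the reference Group-1 MglA and its coupled MglB (falls back to
    # any planted member if group 1 is empty)
    seed_gtpase = references.get("MglA-1") or next(iter(references.values()), None)
    seed_mglb = None
    if seed_gtpase is not None and manifest_proteins[seed_gtpase]["family"] == "mgla":
        g, partner = manifest_proteins[seed_gtpase]["genome_id"], manifest_proteins[seed_gtpase]["partner_locus_tags"]
        if partner:
            seed_mglb = f"{g}|{partner[0]}"
    if seed_mglb is None:
        seed_mglb = next(
            (p for p, r in manifest_proteins.items() if r["family"] == "mglb"), None
        )

    coordinate_map = None
    if seed_gtpase is not None and manifest_proteins[seed_gtpase].get("motif_offsets"):
        offs = manifest_proteins[seed_gtpase]["motif_offsets"]
        coordinate_map = {
            "reference_id": seed_gtpase,
            "core_range": [offs["G1"][0], min(offs["G5"][1] + 5, manifest_proteins[seed_gtpase]["length"])],
            "motif_windows": offs,
            "g2_thr_offset": TEMPLATES["MglA-1"].g2_thr_offset,
            "reference_g1_g2_spacing": TEMPLATES["MglA-1"].spacer_g1_g2
            + TEMPLATES["MglA-1"].g1_g2_insertion_length,
            "base_g1_g2_spacing": TEMPLATES["MglA-1"].spacer_g1_g2,
        }

    manifest = {
        "config": dataclasses.asdict(config),
        "proteins": manifest_proteins,
        "seeds": {"gtpase": seed_gtpase, "mglb": seed_mglb},
        "references": references,
        "coordinate_map": coordinate_map,
    }
    return CensusData(
        gene_records=gene_records,
        proteome=proteome,
        domain_hits=domain_hits,
        manifest=manifest,
        true_trees=true_trees,
    )


def _decoy_record(item: _Item, decoy_class: str, role: str) -> dict:
    return {
        "genome_id": item.genome,
        "locus_tag": item.locus[role],
        "family": "decoy",
        "group": item.group,
        "mechanism": "none",
        "decoy_class": decoy_class,
        "coupled": False,
        "partner_locus_tags": [],
        "coupling_distance": None,
        "motif_offsets": {},
        "insertion_length": 0,
    }


def _annotate(manifest_proteins: dict, proteome: dict[str, str], rng: np.random.Generator) -> list[DomainHit]:
    """Manifest-driven synthetic domain annotation.

    GTPases carry one P-loop-NTPase-clan domain label (a random draw, as
    in mixed real architectures) over their G domain, or no label at all
    for a minority; MglBs carry Robl_LC7; ABC decoys carry ABC transporter
    domains plus a spurious GTPase-domain match; Roco decoys carry LRR
    repeats plus a GTPase domain.
    """
    hits: list[DomainHit] = []
    weights = np.asarray(GTPASE_DOMAIN_WEIGHTS)
    weights = weights / weights.sum()
    for pid in sorted(manifest_proteins):
        rec = manifest_proteins[pid]
        L = len(proteome[pid])
        fam, decoy = rec["family"], rec["decoy_class"]
        if fam in ("mgla", "rup") and decoy == "none":
            if rng.random() < 0.9:
                dom = GTPASE_DOMAINS[rng.choice(len(GTPASE_DOMAINS), p=weights)]
                offs = rec["motif_offsets"]
                a, b = offs["G1"][0], offs["G5"][1]
                score = float(rng.uniform(120, 200))
                hits.append(DomainHit(pid, dom, a, b, score, 10 ** (-score / 8), clan_name="P-loop_NTPase"))
                if rng.random() < 0.2:
                    # weaker overlapping clan-mate, to be resolved away
                    hits.append(
                        DomainHit(pid, "GTP_EFTU", a + 5, b - 5, score - 40,
                                  10 ** (-(score - 40) / 8), clan_name="P-loop_NTPase")
                    )
        elif fam == "mglb":
            if rng.random() < 0.9:
                score = float(rng.uniform(80, 140))
                hits.append(
                    DomainHit(pid, "Robl_LC7", 10, max(11, L - 10), score, 10 ** (-score / 8),
                              clan_name="Roadblock")
                )
        elif decoy == "abc":
            s1 = float(rng.uniform(150, 220))
            hits.append(DomainHit(pid, "ABC_tran", 15, 120, s1, 10 ** (-s1 / 8), clan_name="P-loop_NTPase"))
            s2 = float(rng.uniform(40, 60))
            hits.append(DomainHit(pid, "Miro", 130, 225, s2, 10 ** (-s2 / 8), clan_name="P-loop_NTPase"))
        elif decoy == "truncation":
            offs = rec["motif_offsets"]
            if offs:
                a = offs["G1"][0]
                b = min(L, max(v[1] for v in offs.values()) + 5)
                score = float(rng.uniform(60, 90))
                hits.append(DomainHit(pid, "Miro", a, b, score, 10 ** (-score / 8), clan_name="P-loop_NTPase"))
        elif decoy == "roco":
            for k in range(3):
                s = float(rng.uniform(30, 45))
                hits.append(
                    DomainHit(pid, "LRR_8", 5 + 40 * k, 5 + 40 * k + 38, s, 10 ** (-s / 8), clan_name="LRR")
                )
            offs = rec["motif_offsets"]
            a, b = offs["G1"][0], offs["G5"][1]
            s = float(rng.uniform(100, 160))
            hits.append(DomainHit(pid, "Ras", a, b, s, 10 ** (-s / 8), clan_name="P-loop_NTPase"))
    return hits


# ---------------------------------------------------------------------------
# on-disk emission


def write_census(data: CensusData, outdir: str | Path) -> None:
    """Write the census bundle under `outdir` (gene table, per-genome FASTA,
    combined FASTA, domain table, manifest JSON, true trees)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gene_table(data.gene_records, outdir / "genes.tsv")
    write_fasta(dict(sorted(data.proteome.items())), outdir / "proteome.faa")
    per_genome = data.proteomes_by_genome()
    fadir = outdir / "genomes"
    fadir.mkdir(exist_ok=True)
    for genome_id in sorted(per_genome):
        write_fasta(dict(sorted(per_genome[genome_id].items())), fadir / f"{genome_id}.faa")
    write_domain_hits(data.domain_hits, outdir / "domains.domtbl")
    write_json(data.manifest, outdir / "manifest.json")
    treedir = outdir / "trees"
    treedir.mkdir(exist_ok=True)
    for label in sorted(data.true_trees):
        (treedir / f"{label}.nwk").write_text(data.true_trees[label] + "\n")
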