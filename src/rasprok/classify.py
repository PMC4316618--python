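"""Final family/group assignment and the census report.

Family assignment is reference-anchored: a candidate is MglA when it
falls in the minimal tree clade holding every MglA reference and no Rup
reference (and symmetrically for Rup).  When the tree is ambiguous the
call falls back to a vote over independent evidence: coupling to an mglB
gene and a G1-G2 insertion argue for MglA, an eukaryote-like Ras motif
signature argues for Rup.  Groups are maximal monophyletic clades whose
references all carry one group label.  The census report tallies, per
family, all sequences / small sequences / coupled / small coupled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import skbio

from .motifs import MechanismCall

__all__ = [
    "FamilyAssignment",
    "CensusReport",
    "assign_family",
    "assign_group",
    "census",
]

SMALL_BAND = (150, 240)
RAS_LIKE = ("RAS_LIKE_Q", "RAS_LIKE_NO_Q")


@dataclass
class FamilyAssignment:
    protein_id: str
    family: str  # MglA | Rup | MglB | none
    group: str = "unclassified"
    small: bool = False
    coupled: bool = False
    roco: bool = False
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.roco:
            self.small = False  # Roco-length proteins are never "small"


def _rooted_at_outgroup(tree: skbio.TreeNode, leaves: Sequence[str], outgroup: str | None):
    """Shear to `leaves` (+outgroup) and root on the outgroup edge.

    Returns (rooted tree, outgroup tip name or None).  Without an
    outgroup the sheared topology keeps its arbitrary rooting.
    """
    keep = list(leaves)
    if outgroup is not None:
        keep = keep + [outgroup]
    sub = tree.shear(keep)
    if outgroup is not None:
        og = sub.find(outgroup)
        if og.parent is not None and og.parent.parent is not None:
            sub = sub.root_at(og.parent)
    return sub, outgroup


def _clade_leaves(tree: skbio.TreeNode, in_refs: list[str], out_refs: list[str]) -> set[str] | None:
    """Leaves of the minimal clade containing all in_refs and no out_refs.

    The tree is rooted on the first available out-reference so "clade"
    is well defined; returns None when no clean clade exists.
    """
    names = {t.name for t in tree.tips()}
    in_refs = [r for r in in_refs if r in names]
    out_refs = [r for r in out_refs if r in names]
    if not in_refs:
        return None
    work = tree
    if out_refs:
        og = work.find(out_refs[0])
        if og.parent is not None and og.parent.parent is not None:
            work = work.root_at(og.parent)
    if len(in_refs) == 1:
        node = work.find(in_refs[0])
    else:
        node = work.lca(in_refs)
    clade = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
    if clade & set(out_refs):
        return None
    return clade


def assign_family(
    tree: skbio.TreeNode,
    references: Mapping[str, str],  # reference leaf id -> "MglA" | "Rup"
    coupled_ids: set[str],
    mechanism_calls: Mapping[str, MechanismCall],
    insertion_flags: Mapping[str, bool],
    roco_flags: Mapping[str, bool],
    lengths: Mapping[str, int],
    small_band: tuple[int, int] = SMALL_BAND,
) -> dict[str, FamilyAssignment]:
    """Assign every tree leaf to MglA, Rup or none (with evidence trail)."""
    leaves = [t.name for t in tree.tips()]
    refs_mgla = sorted(r for r, f in references.items() if f == "MglA" and r in leaves)
    refs_rup = sorted(r for r, f in references.items() if f == "Rup" and r in leaves)
    if not refs_mgla and not refs_rup:
        raise ValueError("no references present in tree")
    mgla_clade = _clade_leaves(tree, refs_mgla, refs_rup) or set()
    rup_clade = _clade_leaves(tree, refs_rup, refs_mgla) or set()
    both = mgla_clade & rup_clade

    lo, hi = small_band
    out: dict[str, FamilyAssignment] = {}
    for leaf in leaves:
        coupled = leaf in coupled_ids
        insertion = bool(insertion_flags.get(leaf))
        mech = mechanism_calls.get(leaf)
        roco = bool(roco_flags.get(leaf))
        evidence: list[str] = []
        if leaf in references:
            family = references[leaf]
            evidence.append("reference")
        elif leaf in mgla_clade and leaf not in both:
            family = "MglA"
            evidence.append("clade")
        elif leaf in rup_clade and leaf not in both:
            family = "Rup"
            evidence.append("clade")
        else:
            votes_mgla = 0
            votes_rup = 0
            if coupled:
                votes_mgla += 1
                evidence.append("coupling")
            if insertion:
                votes_mgla += 1
                evidence.append("insertion")
            if mech is not None and mech.call in RAS_LIKE:
                votes_rup += 1
                evidence.append("motif")
            if votes_mgla > votes_rup:
                family = "MglA"
            elif votes_rup > votes_mgla:
                family = "Rup"
            else:
                family = "none"
                evidence.append("ambiguous")
        # supporting (non-deciding) evidence lines
        if coupled and "coupling" not in evidence:
            evidence.append("coupling")
        if insertion and "insertion" not in evidence:
            evidence.append("insertion")
        if mech is not None and mech.call != "UNCALLED" and "motif" not in evidence:
            evidence.append("motif")
        L = lengths.get(leaf, 0)
        out[leaf] = FamilyAssignment(
            protein_id=leaf,
            family=family,
            small=lo <= L <= hi,
            coupled=coupled,
            roco=roco,
            evidence=evidence,
        )
    return out


def assign_group(
    assignments: Mapping[str, FamilyAssignment],
    tree: skbio.TreeNode,
    group_references: Mapping[str, str],  # reference leaf id -> group label
) -> list[str]:
    """Label groups as maximal monophyletic reference-pure clades.

    Members of a clade whose references carry exactly one group label
    inherit that label; leaves under no labeled clade stay unclassified.
    Returns warnings for clades where conflicting references could not be
    separated.  Mutates the `group` field of the assignments.
    """
    warnings: list[str] = []
    families = sorted({a.family for a in assignments.values() if a.family in ("MglA", "Rup")})
    leaf_names = {t.name for t in tree.tips()}
    for family in families:
        members = sorted(
            pid for pid, a in assignments.items() if a.family == family and pid in leaf_names
        )
        if len(members) < 2:
            for pid in members:
                g = group_references.get(pid)
                if g:
                    assignments[pid].group = g
            continue
        outgroup = next(
            (pid for pid, a in sorted(assignments.items())
             if a.family in ("MglA", "Rup") and a.family != family and pid in leaf_names),
            None,
        )
        sub, og = _rooted_at_outgroup(tree, members, outgroup)
        member_set = set(members)

        def groups_under(node) -> set[str]:
            return {
                group_references[t.name]
                for t in ([node] if node.is_tip() else node.tips())
                if t.name in group_references and t.name in member_set
            }

        def walk(node):
            gs = groups_under(node)
            node_leaves = [
                t.name for t in ([node] if node.is_tip() else node.tips())
                if t.name in member_set
            ]
            if not gs:
                return
            if len(gs) == 1:
                label = next(iter(gs))
                for pid in node_leaves:
                    assignments[pid].group = label
                return
            if node.is_tip() or not node.children:
                warnings.append(
                    f"{family}: conflicting group references in one clade: {sorted(gs)}"
                )
                return
            for child in node.children:
                walk(child)

        walk(sub)
    return warnings


@dataclass
class CensusReport:
    """Per-family counts shaped like a four-row coupling/length table."""

    families: dict[str, dict[str, int]]
    groups: dict[str, dict[str, int]]

    def to_rows(self) -> list[dict]:
        rows = []
        for fam in sorted(self.families):
            row = {"family": fam}
            row.update(self.families[fam])
            rows.append(row)
        return rows


def census(assignments: Mapping[str, FamilyAssignment]) -> CensusReport:
    """Tally all / small / coupled / small-coupled per family and group.

    The "small" band end is inclusive (240 aa or less counts as small).
    """
    fams: dict[str, dict[str, int]] = {}
    groups: dict[str, dict[str, int]] = {}
    for a in assignments.values():
        f = fams.setdefault(
            a.family, {"all": 0, "small": 0, "coupled": 0, "small_coupled": 0}
        )
        f["all"] += 1
        f["small"] += a.small
        f["coupled"] += a.coupled
        f["small_coupled"] += a.small and a.coupled
        key = f"{a.family}/{a.group}"
        g = groups.setdefault(key, {"all": 0, "small": 0, "coupled": 0, "small_coupled": 0})
        g["all"] += 1
        g["small"] += a.small
        g["coupled"] += a.coupled
        g["small_coupled"] += a.small and a.coupled
    return CensusReport(families=fams, groups=groups)
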