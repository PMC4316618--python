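"""End-to-end census driver and ground-truth evaluation.

``run_census_pipeline`` executes the full procedure on one census (real
or synthetic inputs): harvest GTPase and MglB candidate sets, resolve
gene-neighborhood couplings and stoichiometry, align each candidate set,
project motifs and call catalytic mechanisms, build core-region trees,
assign families and groups, and tally the census report plus the
coupled-tree congruence statistic.  ``evaluate_against_manifest``
compares a pipeline result with a synthetic ground-truth manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import skbio

from . import classify, genome_context, harvest, motifs, phylo
from .io_formats import GeneRecord
from .msa import align_sequences
from .search_backend import SearchParams
from .synthetic_data import CensusData

__all__ = ["PipelineOptions", "PipelineResult", "run_census_pipeline", "evaluate_against_manifest"]


@dataclass(frozen=True)
class PipelineOptions:
    e_value_threshold: float = 1e-4
    coupling_window: int = 4
    bootstrap_replicates: int = 0  # 0 = single tree, no bootstrap
    seed: int = 0
    min_insertion: int = 5


@dataclass
class PipelineResult:
    gtpase_harvest: harvest.HarvestResult
    mglb_harvest: harvest.HarvestResult
    couplings: list
    context: genome_context.ContextSummary
    motif_sets: dict[str, motifs.MotifSet]
    mechanism_calls: dict[str, motifs.MechanismCall]
    gtpase_tree: skbio.TreeNode
    mglb_tree: skbio.TreeNode | None
    gtpase_tree_summary: phylo.TreeSummary | None
    assignments: dict[str, classify.FamilyAssignment]
    group_warnings: list[str]
    report: classify.CensusReport
    congruence: phylo.CongruenceReport | None
    partner_map: dict[str, list[str]] = field(default_factory=dict)


def extract_core_columns(alignment: Mapping[str, str], reference_id: str, core_range: tuple[int, int]) -> dict[str, str]:
    """Restrict an alignment to the columns of the reference core region."""
    ref = alignment[reference_id]
    cols = [i for i, c in enumerate(ref) if c not in "-."]
    a, b = core_range
    keep = cols[a - 1 : b]
    return {sid: "".join(row[i] for i in keep) for sid, row in alignment.items()}


def run_census_pipeline(data: CensusData, options: PipelineOptions = PipelineOptions()) -> PipelineResult:
    manifest = data.manifest
    seeds = manifest["seeds"]
    if not seeds.get("gtpase") or not seeds.get("mglb"):
        raise ValueError("census has no seed proteins")
    params = SearchParams(e_value_threshold=options.e_value_threshold)
    source = harvest.make_search_source(data.proteome, params)

    gt_cfg = harvest.HarvestConfig(seed_ids=(seeds["gtpase"],), e_value_threshold=options.e_value_threshold)
    gt_res = harvest.iterative_collect(gt_cfg, data.proteome, data.domain_hits, source)
    mb_cfg = harvest.HarvestConfig(
        seed_ids=(seeds["mglb"],), e_value_threshold=options.e_value_threshold,
        mglb_mode=True, collect_top_k=1,
    )
    mb_res = harvest.iterative_collect(mb_cfg, data.proteome, data.domain_hits, source)

    # MglB candidates that are themselves GTPase candidates (shared clan
    # labels can cross-collect) are kept on the GTPase side only.
    mglb_ids = sorted(set(mb_res.candidates) - set(gt_res.candidates))
    gtpase_ids = sorted(set(gt_res.candidates) - set(mglb_ids))

    gene_index = genome_context.GeneIndex(data.gene_records)
    couplings = genome_context.find_couplings(
        gtpase_ids, mglb_ids, gene_index, window=options.coupling_window
    )
    context = genome_context.classify_stoichiometry(gtpase_ids, mglb_ids, couplings)

    # alignment, motifs, insertion
    cmap = motifs.MotifCoordinateMap.from_dict(manifest["coordinate_map"])
    gt_aln = align_sequences(
        {pid: data.proteome[pid] for pid in gtpase_ids}, center_id=cmap.reference_id
    )
    motif_sets = motifs.project_motifs(gt_aln, cmap)
    for m in motif_sets.values():
        motifs.detect_insertion(m, cmap.base_g1_g2_spacing, options.min_insertion)
    mech = {pid: motifs.call_mechanism(m, cmap.g2_thr_offset) for pid, m in motif_sets.items()}

    # trees from core columns
    core = extract_core_columns(gt_aln, cmap.reference_id, cmap.core_range)
    gt_tree = phylo.neighbor_joining(phylo.distances(core))
    summary = None
    if options.bootstrap_replicates > 0:
        summary = phylo.bootstrap_consensus(core, options.bootstrap_replicates, options.seed)

    mglb_tree = None
    if len(mglb_ids) >= 3:
        mb_aln = align_sequences({pid: data.proteome[pid] for pid in mglb_ids})
        mglb_tree = phylo.neighbor_joining(phylo.distances(mb_aln))

    # classification
    references = {pid: ("MglA" if g.startswith("MglA") else "Rup")
                  for g, pid in manifest["references"].items()}
    group_references = {pid: g for g, pid in manifest["references"].items()}
    arches = harvest.resolve_all_architectures(data.domain_hits)
    roco_flags = {
        pid: any(h.domain_name.startswith("LRR") for h in arches[pid].kept)
        if pid in arches else False
        for pid in gtpase_ids
    }
    insertion_flags = {pid: m.insertion_present for pid, m in motif_sets.items()}
    lengths = {pid: len(data.proteome[pid]) for pid in gtpase_ids}
    coupled_ids = set(context.coupled_gtpases)
    assignments = classify.assign_family(
        gt_tree, references, coupled_ids, mech, insertion_flags, roco_flags, lengths
    )
    warnings = classify.assign_group(assignments, gt_tree, group_references)
    for pid in mglb_ids:
        assignments[pid] = classify.FamilyAssignment(
            protein_id=pid,
            family="MglB",
            small=False,
            coupled=pid in set(context.coupled_mglbs),
            evidence=["harvest"],
        )
    report = classify.census(assignments)

    # coevolution congruence over coupled MglA leaves (up to two partners)
    partner_map = {
        c.gtpase_id: [m for m, _ in c.partners[:2]]
        for c in couplings
        if assignments.get(c.gtpase_id) and assignments[c.gtpase_id].family == "MglA"
    }
    cong = None
    if mglb_tree is not None and len(partner_map) >= 4:
        cong = phylo.congruence(gt_tree, mglb_tree, partner_map)

    return PipelineResult(
        gtpase_harvest=gt_res,
        mglb_harvest=mb_res,
        couplings=couplings,
        context=context,
        motif_sets=motif_sets,
        mechanism_calls=mech,
        gtpase_tree=gt_tree,
        mglb_tree=mglb_tree,
        gtpase_tree_summary=summary,
        assignments=assignments,
        group_warnings=warnings,
        report=report,
        congruence=cong,
        partner_map=partner_map,
    )


_FAMILY_NAMES = {"mgla": "MglA", "rup": "Rup", "mglb": "MglB"}


def evaluate_against_manifest(result: PipelineResult, manifest: dict) -> dict[str, float]:
    """Score a pipeline run against the generator's ground truth.

    Returns harvest sensitivity/precision, family/group/mechanism
    accuracy, coupling-status and stoichiometry accuracy, and decoy
    exclusion checks (all fractions in [0, 1]).
    """
    prot = manifest["proteins"]
    planted_gt = {p for p, r in prot.items() if r["family"] in ("mgla", "rup") and r["decoy_class"] == "none"}
    planted_mglb = {p for p, r in prot.items() if r["family"] == "mglb"}
    decoys = {p: r["decoy_class"] for p, r in prot.items() if r["family"] == "decoy"}

    gt_cand = set(result.gtpase_harvest.candidates)
    # sensitivity/precision of the small-GTPase harvest vs planted truth
    # (Roco decoys legitimately appear among candidates but not as small)
    small = result.gtpase_harvest.small_candidates
    tp = len(small & planted_gt)
    sens = tp / len(planted_gt) if planted_gt else 1.0
    prec = tp / len(small) if small else 1.0

    mb_cand = set(result.mglb_harvest.candidates)
    mb_tp = len(mb_cand & planted_mglb)
    mb_sens = mb_tp / len(planted_mglb) if planted_mglb else 1.0
    mb_prec = mb_tp / len(mb_cand) if mb_cand else 1.0

    # family accuracy over planted GTPases that were harvested
    fam_ok = fam_n = 0
    for p in sorted(planted_gt & gt_cand):
        a = result.assignments.get(p)
        if a is None:
            continue
        fam_n += 1
        fam_ok += a.family == _FAMILY_NAMES[prot[p]["family"]]
    fam_acc = fam_ok / fam_n if fam_n else 0.0

    # group recovery over planted GTPases
    grp_ok = grp_n = 0
    for p in sorted(planted_gt & gt_cand):
        a = result.assignments.get(p)
        if a is None:
            continue
        grp_n += 1
        grp_ok += a.group == prot[p]["group"]
    grp_acc = grp_ok / grp_n if grp_n else 0.0

    # coupling status: planted coupled flag vs pipeline coupled flag
    cpl_ok = cpl_n = 0
    for p in sorted((planted_gt | planted_mglb)):
        a = result.assignments.get(p)
        if a is None:
            continue
        cpl_n += 1
        cpl_ok += a.coupled == bool(prot[p]["coupled"])
    cpl_acc = cpl_ok / cpl_n if cpl_n else 0.0

    # stoichiometry: planted 1:2 systems called 1:2, 1:1 called 1:1
    st_ok = st_n = 0
    for p, r in sorted(prot.items()):
        if r["family"] != "mgla" or r["decoy_class"] != "none":
            continue
        if p not in result.context.coupled_gtpases:
            continue
        st_n += 1
        expected = f"1:{len(r['partner_locus_tags'])}"
        st_ok += result.context.coupled_gtpases[p] == expected
    st_acc = st_ok / st_n if st_n else 0.0

    # mechanism agreement over planted, harvested GTPases
    mech_ok = mech_n = 0
    for p in sorted(planted_gt & set(result.mechanism_calls)):
        mech_n += 1
        mech_ok += result.mechanism_calls[p].call == prot[p]["mechanism"]
    mech_acc = mech_ok / mech_n if mech_n else 0.0

    # decoys: none in the small set; excluded with the right ledger reason
    excl = result.gtpase_harvest.excluded
    decoy_in_small = sum(1 for p in decoys if p in small)
    abc_ok = all(excl.get(p) == "decoy-architecture" for p, c in decoys.items() if c == "abc")
    trunc_ok = all(
        excl.get(p) == "short"
        for p, c in decoys.items()
        if c == "truncation" and (p in excl or p in gt_cand)
    )
    roco_flagged = sum(
        1 for p, c in decoys.items() if c == "roco" and p in gt_cand and not result.gtpase_harvest.small[p]
    )
    n_roco_cand = sum(1 for p, c in decoys.items() if c == "roco" and p in gt_cand)

    return {
        "harvest_sensitivity": sens,
        "harvest_precision": prec,
        "mglb_sensitivity": mb_sens,
        "mglb_precision": mb_prec,
        "family_accuracy": fam_acc,
        "group_accuracy": grp_acc,
        "coupling_accuracy": cpl_acc,
        "stoichiometry_accuracy": st_acc,
        "mechanism_accuracy": mech_acc,
        "decoys_in_small_set": float(decoy_in_small),
        "abc_excluded_correctly": float(abc_ok),
        "truncations_excluded_correctly": float(trunc_ok),
        "roco_flagged_not_small": float(roco_flagged == n_roco_cand),
        "congruence_fraction": result.congruence.fraction if result.congruence else float("nan"),
    }
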