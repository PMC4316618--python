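import math
import re

import numpy as np
import pytest

from rasprok import synthetic_data as sd
from rasprok.genome_context import ordinal_distance


def _cfg(**kw):
    base = dict(
        seed=11,
        n_genomes=6,
        genes_per_replicon=60,
        mgla_systems=(3, 2, 2, 2, 2),
        rup_systems=(2, 1),
        n_decoy_abc=1,
        n_truncations=1,
        n_roco=1,
    )
    base.update(kw)
    return sd.SimulationConfig(**base)


class TestConfigValidation:
    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            _cfg(n_decoy_abc=-1)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            _cfg(frac_orphan_mglb=1.5)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            _cfg(substitution_rate=-0.1)

    def test_capacity_overflow_raises_sizing_error(self):
        with pytest.raises(sd.SizingError):
            sd.generate_census(_cfg(n_genomes=1, genes_per_replicon=24))


class TestGenerateCensus:
    def test_all_counts_zero_gives_only_fillers(self):
        cfg = _cfg(
            mgla_systems=(0, 0, 0, 0, 0), rup_systems=(0, 0),
            n_decoy_abc=0, n_truncations=0, n_roco=0,
        )
        data = sd.generate_census(cfg)
        fams = {r["family"] for r in data.manifest["proteins"].values()}
        assert fams <= {"filler"}
        assert data.true_trees == {}

    def test_empty_universe(self):
        cfg = _cfg(
            n_genomes=0,
            mgla_systems=(0, 0, 0, 0, 0), rup_systems=(0, 0),
            n_decoy_abc=0, n_truncations=0, n_roco=0,
        )
        data = sd.generate_census(cfg)
        assert data.proteome == {}
        assert data.manifest["proteins"] == {}

    def test_determinism_byte_identical(self, tmp_path):
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        sd.write_census(sd.generate_census(_cfg()), d1)
        sd.write_census(sd.generate_census(_cfg()), d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_earlier_genomes_stable_when_genome_count_grows(self):
        small = sd.generate_census(_cfg(n_genomes=6))
        # same planted material spread over more genomes: genome substreams
        # are split by fixed keys, so placement rngs per genome are reused
        big = sd.generate_census(_cfg(n_genomes=8))
        assert set(small.proteome) & set(big.proteome)  # shared genome ids exist

    def test_manifest_covers_every_protein_exactly_once(self, default_census):
        assert set(default_census.manifest["proteins"]) == set(default_census.proteome)

    def test_planted_distances_match_gene_table(self, default_census):
        data = default_census
        idx = {(r.genome_id, r.locus_tag): r.gene_index for r in data.gene_records}
        n = data.manifest["config"]["genes_per_replicon"]
        topo = data.manifest["config"]["replicon_topology"]
        for pid, rec in data.manifest["proteins"].items():
            if not rec["coupled"]:
                continue
            i = idx[(rec["genome_id"], rec["locus_tag"])]
            dmin = min(
                ordinal_distance(i, idx[(rec["genome_id"], p)], n, topo)
                for p in rec["partner_locus_tags"]
            )
            assert dmin == rec["coupling_distance"]
            assert 1 <= dmin <= 4

    def test_fixed_distance_config_plants_exact_distances(self):
        cfg = _cfg(
            mgla_systems=(5, 0, 0, 0, 0), rup_systems=(0, 0),
            coupling_distance_weights=(0.0, 1.0, 0.0, 0.0),
            frac_1to2_systems=0.0, frac_orphan_mglb=0.0,
            n_decoy_abc=0, n_truncations=0, n_roco=0,
        )
        data = sd.generate_census(cfg)
        idx = {(r.genome_id, r.locus_tag): r.gene_index for r in data.gene_records}
        couplings = [
            r for r in data.manifest["proteins"].values() if r["family"] == "mgla"
        ]
        assert len(couplings) == 5
        for rec in couplings:
            assert rec["coupling_distance"] == 2
            i = idx[(rec["genome_id"], rec["locus_tag"])]
            j = idx[(rec["genome_id"], rec["partner_locus_tags"][0])]
            assert abs(i - j) == 2  # exhaustive check against the gene table

    def test_orphan_mglbs_clear_of_all_gtpase_like_genes(self, default_census):
        data = default_census
        idx = {(r.genome_id, r.locus_tag): r.gene_index for r in data.gene_records}
        n = data.manifest["config"]["genes_per_replicon"]
        topo = data.manifest["config"]["replicon_topology"]
        gtpase_pos = {}
        for rec in data.manifest["proteins"].values():
            if rec["family"] in ("mgla", "rup") or rec["decoy_class"] in ("truncation", "roco"):
                gtpase_pos.setdefault(rec["genome_id"], []).append(
                    idx[(rec["genome_id"], rec["locus_tag"])]
                )
        for rec in data.manifest["proteins"].values():
            if rec["family"] == "mglb" and not rec["coupled"]:
                i = idx[(rec["genome_id"], rec["locus_tag"])]
                for j in gtpase_pos.get(rec["genome_id"], []):
                    assert ordinal_distance(i, j, n, topo) >= 5

    def test_length_bands(self, default_census):
        for rec in default_census.manifest["proteins"].values():
            L = rec["length"]
            if rec["family"] in ("mgla", "rup") and rec["decoy_class"] == "none":
                assert 150 <= L <= 240
            elif rec["family"] == "mglb":
                assert 129 <= L <= 179
            elif rec["decoy_class"] == "truncation":
                assert L < 150
            elif rec["decoy_class"] == "roco":
                assert L > 240

    def test_one_to_two_systems_have_two_partners(self, default_census):
        n12 = 0
        for rec in default_census.manifest["proteins"].values():
            if rec["family"] == "mgla" and len(rec["partner_locus_tags"]) == 2:
                n12 += 1
        assert n12 == round(0.1 * sum(default_census.manifest["config"]["mgla_systems"]))


class TestRealizeTemplate:
    def test_group1_g3_is_tvpgq(self):
        rng = np.random.default_rng(0)
        seq, offs = sd.realize_template(sd.TEMPLATES["MglA-1"], rng)
        a, b = offs["G3"]
        assert seq[a - 1 : b] == "TVPGQ"

    def test_group2_g4_matches_nxfd(self):
        rng = np.random.default_rng(0)
        seq, offs = sd.realize_template(sd.TEMPLATES["MglA-2"], rng)
        a, b = offs["G4"]
        assert re.fullmatch(r"N.FD", seq[a - 1 : b])

    def test_motifs_match_ambiguity_classes_at_offsets(self):
        rng = np.random.default_rng(3)
        for name, template in sd.TEMPLATES.items():
            seq, offs = sd.realize_template(template, rng)
            assert len(seq) == template.total_length
            g1 = seq[offs["G1"][0] - 1 : offs["G1"][1]]
            assert g1[0] == "G" and g1[5] == "G" and g1[6] == "K" and g1[7] in "TS"

    def test_insertion_only_on_mgla_templates(self):
        for name, t in sd.TEMPLATES.items():
            if t.g1_g2_insertion_length > 0:
                assert name.startswith("MglA")

    def test_oversized_template_raises(self):
        import dataclasses

        t = dataclasses.replace(sd.TEMPLATES["MglA-1"], total_length=100)
        with pytest.raises(sd.SizingError):
            sd.realize_template(t, np.random.default_rng(0))

    def test_truncations_lack_a_motif(self, default_census):
        truncs = [
            r for r in default_census.manifest["proteins"].values()
            if r["decoy_class"] == "truncation"
        ]
        assert truncs
        for rec in truncs:
            assert set(rec["motif_offsets"]) < set(sd.MOTIF_NAMES)


class TestEvolveFamily:
    def test_zero_rate_leaves_identical(self):
        rng = np.random.default_rng(0)
        root = sd._draw_bg(rng, 100)
        seqs, tree = sd.evolve_family(root, ["a", "b", "c"], 0.0, rng)
        assert all(s == root for s in seqs.values())

    def test_two_leaves_zero_rate_zero_pdistance(self):
        rng = np.random.default_rng(0)
        root = sd._draw_bg(rng, 50)
        seqs, _ = sd.evolve_family(root, ["a", "b"], 0.0, rng)
        a, b = seqs["a"], seqs["b"]
        assert sum(x != y for x, y in zip(a, b)) == 0

    def test_divergence_matches_poisson_expectation(self):
        rng = np.random.default_rng(42)
        L = 2000
        rate = 0.3
        root = sd._draw_bg(rng, L)
        seqs, _ = sd.evolve_family(root, [f"t{i}" for i in range(8)], rate, rng)
        expected = 1 - math.exp(-rate)
        fractions = [
            sum(a != b for a, b in zip(root, s)) / L for s in seqs.values()
        ]
        mean = sum(fractions) / len(fractions)
        se = math.sqrt(expected * (1 - expected) / L)
        assert abs(mean - expected) < 3 * se + 0.02  # reversions shave a little

    def test_motif_positions_never_substituted(self):
        rng = np.random.default_rng(1)
        template = sd.TEMPLATES["MglA-1"]
        root, offs = sd.realize_template(template, rng)
        mask = sd.motif_mask(template, offs, len(root))
        seqs, _ = sd.evolve_family(root, [f"t{i}" for i in range(6)], 0.5, rng, mask=mask)
        for s in seqs.values():
            for a, b in offs.values():
                assert s[a - 1 : b] == root[a - 1 : b]

    def test_true_tree_has_requested_leaves(self):
        rng = np.random.default_rng(2)
        root = sd._draw_bg(rng, 60)
        names = [f"leaf{i}" for i in range(5)]
        _, tree = sd.evolve_family(root, names, 0.1, rng)
        assert sorted(t.name for t in tree.tips()) == sorted(names)
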