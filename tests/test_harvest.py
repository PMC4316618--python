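import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rasprok import harvest as hv
from rasprok.io_formats import DomainHit, SimilarityHit
from rasprok.search_backend import SearchParams


def _hit(name, a, b, score, e=None, pid="p"):
    return DomainHit(pid, name, a, b, score, 10 ** (-score / 10) if e is None else e)


def _oracle_resolution(hits):
    """Independent greedy trace: linear-scan argmax + fresh overlap test."""
    kept = []
    pool = list(hits)
    while pool:
        best = pool[0]
        for h in pool[1:]:
            key_h = (h.bit_score, -h.e_value, h.ali_to - h.ali_from, tuple(sorted(h.domain_name))[:0] or h.domain_name)
            # explicit comparison chain (higher score, lower e, longer, name)
            if (h.bit_score, -h.e_value, h.ali_to - h.ali_from) > (
                best.bit_score, -best.e_value, best.ali_to - best.ali_from
            ):
                best = h
            elif (h.bit_score, -h.e_value, h.ali_to - h.ali_from) == (
                best.bit_score, -best.e_value, best.ali_to - best.ali_from
            ) and h.domain_name < best.domain_name:
                best = h
        kept.append(best)
        pool = [
            h for h in pool
            if h is not best
            and (h.ali_to < best.ali_from or h.ali_from > best.ali_to)
        ]
    return sorted(kept, key=lambda h: h.ali_from)


class TestResolveArchitecture:
    def test_empty_input(self):
        arch = hv.resolve_architecture([])
        assert arch.kept == [] and arch.resolution_log == []

    def test_two_disjoint_hits_kept_in_coordinate_order(self):
        hits = [_hit("B", 50, 80, 30.0), _hit("A", 1, 40, 20.0)]
        arch = hv.resolve_architecture(hits)
        assert [h.domain_name for h in arch.kept] == ["A", "B"]

    def test_overlap_resolved_to_best_scorer(self):
        hits = [_hit("weak", 10, 60, 20.0), _hit("strong", 30, 90, 50.0)]
        arch = hv.resolve_architecture(hits)
        assert [h.domain_name for h in arch.kept] == ["strong"]
        assert arch.resolution_log[0][0].domain_name == "weak"

    def test_mixed_protein_ids_rejected(self):
        with pytest.raises(ValueError, match="multiple proteins"):
            hv.resolve_architecture([_hit("A", 1, 5, 10.0, pid="x"), _hit("B", 1, 5, 10.0, pid="y")])

    def test_every_discarded_hit_overlaps_a_better_kept_hit(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(1, 9)
            hits = []
            for k in range(n):
                a = int(rng.integers(1, 100))
                b = a + int(rng.integers(0, 40))
                hits.append(_hit(f"d{rng.integers(4)}", a, b, float(rng.integers(1, 6) * 10)))
            arch = hv.resolve_architecture(hits)
            for discarded, kept_name in arch.resolution_log:
                overlapping = [
                    k for k in arch.kept
                    if min(k.ali_to, discarded.ali_to) - max(k.ali_from, discarded.ali_from) >= 0
                ]
                assert any(k.bit_score >= discarded.bit_score for k in overlapping)

    def test_randomized_sets_match_independent_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            n = int(rng.integers(0, 9))
            hits = []
            for k in range(n):
                a = int(rng.integers(1, 80))
                b = a + int(rng.integers(0, 30))
                hits.append(_hit(f"d{int(rng.integers(5))}", a, b, float(rng.integers(1, 8) * 5)))
            got = hv.resolve_architecture(hits).kept
            expected = _oracle_resolution(hits)
            assert [(h.domain_name, h.ali_from, h.ali_to) for h in got] == [
                (h.domain_name, h.ali_from, h.ali_to) for h in expected
            ]


class TestCensusDomains:
    def test_single_subject_single_domain(self):
        arch = {"s": hv.resolve_architecture([_hit("Ras", 1, 100, 50.0, pid="s")])}
        hits = [SimilarityHit("q", "s", 99.0, 100, 1, 100, 1, 100, 1e-50, 300.0)]
        table, none = hv.census_domains(hits, arch)
        assert table == [("Ras", 1)] and none == set()

    def test_subjects_without_domains_flagged(self):
        hits = [SimilarityHit("q", "s", 99.0, 100, 1, 100, 1, 100, 1e-50, 300.0)]
        table, none = hv.census_domains(hits, {})
        assert table == [] and none == {"s"}

    def test_counts_equal_brute_force_tally(self, default_census):
        from collections import Counter

        arch = hv.resolve_all_architectures(default_census.domain_hits)
        subjects = sorted(default_census.proteome)[:200]
        hits = [
            SimilarityHit("q", s, 90.0, 10, 1, 10, 1, 10, 1e-10, 60.0) for s in subjects
        ]
        table, _ = hv.census_domains(hits, arch)
        brute = Counter()
        for s in set(subjects):
            if s in arch:
                for name in {h.domain_name for h in arch[s].kept}:
                    brute[name] += 1
        assert dict(table) == dict(brute)


class TestExtractRegion:
    def test_whole_sequence(self):
        assert hv.extract_region("MGDT", 1, 4) == "MGDT"

    def test_inner_slice(self):
        assert hv.extract_region("MGDT", 2, 4) == "GDT"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hv.extract_region("MGDT", 0, 3)
        with pytest.raises(ValueError):
            hv.extract_region("MGDT", 2, 5)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(1, 60), st.integers(1, 60))
    def test_slice_length_property(self, a, b):
        seq = "A" * 60
        lo, hi = min(a, b), max(a, b)
        assert len(hv.extract_region(seq, lo, hi)) == hi - lo + 1


class TestIterativeCollect:
    def test_seed_only_proteome(self):
        seq = "MGDTARVLLVGDSGVGKTSL" * 8  # 160 aa, inside the small band
        proteome = {"seed": seq}
        cfg = hv.HarvestConfig(seed_ids=("seed",))
        source = hv.make_search_source(proteome, SearchParams())
        res = hv.iterative_collect(cfg, proteome, [], source)
        assert set(res.candidates) == {"seed"}
        assert res.excluded == {}

    def test_missing_seed_is_configuration_error(self):
        with pytest.raises(hv.ConfigurationError):
            hv.iterative_collect(
                hv.HarvestConfig(seed_ids=("nope",)), {"a": "MG"}, [], lambda q: []
            )

    def test_planted_families_recovered_and_decoys_separated(self, default_census, pipeline_result):
        man = default_census.manifest
        res = pipeline_result.gtpase_harvest
        planted = {
            p for p, r in man["proteins"].items()
            if r["family"] in ("mgla", "rup") and r["decoy_class"] == "none"
        }
        assert planted <= set(res.candidates)
        abc = {p for p, r in man["proteins"].items() if r["decoy_class"] == "abc"}
        assert abc.isdisjoint(res.candidates)
        assert all(res.excluded[p] == "decoy-architecture" for p in abc)

    def test_truncations_excluded_as_short(self, default_census, pipeline_result):
        man = default_census.manifest
        res = pipeline_result.gtpase_harvest
        truncs = {p for p, r in man["proteins"].items() if r["decoy_class"] == "truncation"}
        assert truncs <= set(res.excluded)
        assert all(res.excluded[p] == "short" for p in truncs)

    def test_roco_retained_but_not_small(self, default_census, pipeline_result):
        man = default_census.manifest
        res = pipeline_result.gtpase_harvest
        rocos = {p for p, r in man["proteins"].items() if r["decoy_class"] == "roco"}
        harvested = rocos & set(res.candidates)
        assert harvested
        assert all(not res.small[p] for p in harvested)

    def test_candidate_and_excluded_sets_disjoint(self, pipeline_result):
        res = pipeline_result.gtpase_harvest
        assert not (set(res.candidates) & set(res.excluded))
        assert all(res.candidates.values())  # provenance non-empty

    def test_extra_expansion_round_never_shrinks_candidates(self, small_census):
        source = hv.make_search_source(small_census.proteome, SearchParams())
        seeds = (small_census.manifest["seeds"]["gtpase"],)
        r1 = hv.iterative_collect(
            hv.HarvestConfig(seed_ids=seeds, expansion_rounds=1),
            small_census.proteome, small_census.domain_hits, source,
        )
        r2 = hv.iterative_collect(
            hv.HarvestConfig(seed_ids=seeds, expansion_rounds=2),
            small_census.proteome, small_census.domain_hits, source,
        )
        assert set(r1.candidates) <= set(r2.candidates)

    def test_search_and_table_sources_agree(self, small_census):
        # record every hit the live backend produces, then replay the same
        # rows from an ingested table: results must be identical
        proteome = small_census.proteome
        live = hv.make_search_source(proteome, SearchParams())
        recorded = []

        def recording_source(queries):
            hits = live(queries)
            recorded.extend(hits)
            return hits

        seeds = (small_census.manifest["seeds"]["gtpase"],)
        cfg = hv.HarvestConfig(seed_ids=seeds)
        res_search = hv.iterative_collect(
            cfg, proteome, small_census.domain_hits, recording_source
        )
        res_table = hv.iterative_collect(
            cfg, proteome, small_census.domain_hits, hv.make_table_source(recorded)
        )
        assert res_search.candidates == res_table.candidates
        assert res_search.excluded == res_table.excluded
        assert res_search.small == res_table.small
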