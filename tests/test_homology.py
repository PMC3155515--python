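import itertools

import numpy as np
import pytest

from isopipe import homology
from isopipe.io_formats import HSP, GeneModel, OrthologyTable
from isopipe.syndata import (
    SimConfig,
    generate_hit_table,
    generate_isotigs,
    generate_reference_panel,
)


def hsp(q0, q1, t0, t1, bits=None, target="t1", strand="+", query="q1"):
    return HSP(query, target, q0, q1, t0, t1, strand,
               95.0, bits if bits is not None else float(q1 - q0), 1e-20)


# ---------------------------------------------------------------------------
# independent oracle: exhaustive best-subset search
# ---------------------------------------------------------------------------

def brute_force_chain(hsps):
    """Best colinear, query/target-disjoint subset by (coverage, bits)."""
    best = (0, 0.0)
    best_subset = []
    for r in range(1, len(hsps) + 1):
        for subset in itertools.combinations(hsps, r):
            ordered = sorted(subset, key=lambda h: (h.q_start, h.q_end))
            ok = all(
                homology._compatible(a, b)
                for a, b in itertools.combinations(ordered, 2)
            )
            if not ok:
                continue
            score = (sum(h.q_len for h in ordered), sum(h.bit_score for h in ordered))
            if score > best:
                best, best_subset = score, list(ordered)
    return best, best_subset


def random_instance(rng, n_max=12):
    n = int(rng.integers(1, n_max + 1))
    out = []
    for _ in range(n):
        q0 = int(rng.integers(0, 90))
        q1 = q0 + int(rng.integers(5, 40))
        t0 = int(rng.integers(0, 90))
        t1 = t0 + int(rng.integers(5, 40))
        out.append(hsp(q0, q1, t0, t1, bits=float(rng.integers(10, 200))))
    return out


class TestChaining:
    def test_single_hsp_chain(self):
        chain = homology.chain_hsps([hsp(0, 100, 500, 600)])
        assert chain.coverage == 100
        assert len(chain.members) == 1

    def test_colinear_triple_beats_order_crossing_hsp(self):
        # three colinear 100 bp HSPs plus one that crosses their target order
        colinear = [hsp(0, 100, 0, 100), hsp(100, 200, 200, 300), hsp(200, 300, 400, 500)]
        crossing = hsp(120, 180, 50, 110, bits=500.0)
        chain = homology.chain_hsps(colinear + [crossing])
        (score, subset) = brute_force_chain(colinear + [crossing])
        assert chain.coverage == 300 == score[0]
        assert [h.q_start for h in chain.members] == [h.q_start for h in subset]

    def test_query_overlap_forces_single_member(self):
        a = hsp(0, 100, 0, 100, bits=90.0)
        b = hsp(90, 190, 150, 250, bits=120.0)  # overlaps a by 10 bp on the query
        chain = homology.chain_hsps([a, b])
        score, _ = brute_force_chain([a, b])
        assert chain.coverage == 100 == score[0]
        assert chain.members[0].bit_score == 120.0  # larger-bits HSP wins

    def test_minus_strand_chains_descend_on_target(self):
        a = hsp(0, 50, 200, 250, strand="-")
        b = hsp(50, 100, 100, 150, strand="-")
        chain = homology.chain_hsps([a, b])
        assert chain.coverage == 100
        assert [h.t_start for h in chain.members] == [200, 100]

    def test_empty_and_mixed_strand_rejected(self):
        with pytest.raises(homology.ChainingError):
            homology.chain_hsps([])
        with pytest.raises(homology.ChainingError, match="strand"):
            homology.chain_hsps([hsp(0, 10, 0, 10), hsp(20, 30, 20, 30, strand="-")])

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            instance = random_instance(rng)
            chain = homology.chain_hsps(instance)
            (cov, bits), _ = brute_force_chain(instance)
            assert chain.coverage == cov
            assert chain.total_bits == pytest.approx(bits)


def make_model(tid="t1", gene="g1", cds=(100, 400), length=700):
    return GeneModel(tid, gene, "mouse", "chr1", [(1000, 1000 + length)],
                     cds, "A" * length)


class TestResolveGene:
    def test_chain_in_utr_has_zero_coding(self):
        model = make_model()
        chain = homology.ChainedHit("q1", "t1", [hsp(0, 100, 450, 550)])
        homology.resolve_gene(chain, {"t1": model})
        assert (chain.coding_bp, chain.utr_bp) == (0, 100)
        assert chain.gene_id == "g1"

    def test_chain_spanning_cds_exactly(self):
        model = make_model()
        chain = homology.ChainedHit("q1", "t1", [hsp(0, 300, 100, 400)])
        homology.resolve_gene(chain, {"t1": model})
        assert (chain.coding_bp, chain.utr_bp) == (300, 0)

    def test_half_in_cds(self):
        model = make_model()  # CDS 100-400
        chain = homology.ChainedHit("q1", "t1", [hsp(0, 300, 250, 550)])
        homology.resolve_gene(chain, {"t1": model})
        assert chain.coding_bp == 150

    def test_unknown_transcript_raises(self):
        chain = homology.ChainedHit("q1", "tX", [hsp(0, 10, 0, 10)])
        with pytest.raises(KeyError):
            homology.resolve_gene(chain, {"t1": make_model()})


def resolved_chain(coverage, bits, gene, target="t1", query="q1"):
    c = homology.ChainedHit(query, target, [hsp(0, coverage, 0, coverage, bits=bits,
                                                target=target, query=query)])
    c.gene_id = gene
    return c


class TestUniqueRule:
    def test_lone_hit_is_unique(self):
        call = homology.classify_unique([resolved_chain(100, 90.0, "g1")])
        assert call.status == "unique"

    def test_both_ratios_at_least_two_is_unique(self):
        call = homology.classify_unique(
            [resolved_chain(1000, 900.0, "g1"), resolved_chain(400, 420.0, "g2")]
        )
        assert call.status == "unique"
        assert call.size_ratio == pytest.approx(2.5)
        assert call.bits_ratio == pytest.approx(900 / 420)

    def test_conjunctive_rule_fails_on_bits(self):
        call = homology.classify_unique(
            [resolved_chain(1000, 900.0, "g1"), resolved_chain(400, 460.0, "g2")]
        )
        assert call.status == "ambiguous"
        assert call.bits_ratio < 2.0 < call.size_ratio

    def test_same_gene_transcripts_are_exempt(self):
        # two transcripts of one gene with near-equal scores: naive rule
        # would call ambiguous, same-gene grouping keeps it unique
        call = homology.classify_unique(
            [
                resolved_chain(1000, 900.0, "g1", target="t1a"),
                resolved_chain(950, 880.0, "g1", target="t1b"),
            ]
        )
        assert call.status == "unique"

    def test_empty_input_is_no_hit(self):
        assert homology.classify_unique([]).status == "no-hit"

    def test_invariant_to_order_and_duplication(self):
        chains = [
            resolved_chain(1000, 900.0, "g1"),
            resolved_chain(400, 420.0, "g2"),
            resolved_chain(300, 100.0, "g3"),
        ]
        statuses = set()
        for perm in itertools.permutations(chains):
            statuses.add(homology.classify_unique(list(perm)).status)
        statuses.add(homology.classify_unique(chains + [chains[1]]).status)
        assert statuses == {"unique"}


class TestDecoyBoundary:
    @pytest.mark.parametrize("ratio,expected", [(0.49, "unique"), (0.51, "ambiguous")])
    def test_planted_decoy_ratio_decides_status(self, ratio, expected):
        cfg = SimConfig(seed=21, n_genes=6, frac_decoy=1.0, decoy_ratio=ratio,
                        frac_novel_isotigs=0, frac_splice_variants=0)
        panel = generate_reference_panel(cfg)
        records, _ = generate_isotigs(panel, cfg)
        hsps, chain_truth = generate_hit_table(records, panel, cfg)
        models = panel.models_by_transcript()
        sp0 = panel.species[0]
        checked = 0
        for rec in records:
            if not chain_truth[(rec.isotig_id, sp0)]["decoy"]:
                continue
            grouped = {}
            for h in hsps:
                if h.query_id == rec.isotig_id and models[h.target_id].species == sp0:
                    grouped.setdefault(h.target_id, []).append(h)
            chains = [
                homology.resolve_gene(homology.chain_hsps(g), models)
                for g in grouped.values()
            ]
            assert homology.classify_unique(chains).status == expected
            checked += 1
        assert checked > 0


class TestClusters:
    def _call(self, iso, coverage, t0, t1, bits=None, gene="g1", target="t1"):
        c = homology.ChainedHit(
            iso, target, [hsp(0, coverage, t0, t1, bits=bits, target=target, query=iso)]
        )
        c.gene_id = gene
        return homology.UniqueCall(iso, "unique", c)

    def test_disjoint_thirds_all_selected(self):
        model = make_model(length=900, cds=(0, 900))
        calls = [
            self._call("isoA", 300, 0, 300),
            self._call("isoB", 300, 300, 600),
            self._call("isoC", 300, 600, 900),
        ]
        (cluster,) = homology.cluster_by_gene(calls, "mouse", {"t1": model})
        assert sorted(cluster.non_overlapping) == ["isoA", "isoB", "isoC"]
        assert cluster.representative == "isoA"  # tie on coverage -> lexicographic

    def test_nested_footprints_keep_larger_only(self):
        model = make_model(length=900, cds=(0, 900))
        calls = [self._call("big", 500, 0, 500), self._call("small", 200, 100, 300)]
        (cluster,) = homology.cluster_by_gene(calls, "mouse", {"t1": model})
        assert cluster.non_overlapping == ["big"]
        assert cluster.representative == "big"

    def test_greedy_matches_bruteforce_on_fixture(self):
        model = make_model(length=1000, cds=(0, 999))
        spans = {"i1": (0, 400), "i2": (350, 500), "i3": (420, 700),
                 "i4": (720, 900), "i5": (880, 1000)}
        calls = [self._call(k, e - s, s, e) for k, (s, e) in spans.items()]
        (cluster,) = homology.cluster_by_gene(calls, "mouse", {"t1": model})

        best = (0, [])
        for r in range(1, 6):
            for sub in itertools.combinations(spans, r):
                ivs = sorted(spans[k] for k in sub)
                if all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:])):
                    cov = sum(e - s for s, e in ivs)
                    if cov > best[0]:
                        best = (cov, sorted(sub))
        assert sorted(cluster.non_overlapping) == best[1]


class TestCategories:
    def setup_method(self):
        self.orth = OrthologyTable()
        for sp in ("mouse", "rat", "human"):
            self.orth.add(sp, f"gA_{sp}", "OG_A")
        self.orth.add("mouse", "gB_mouse", "OG_B1")
        self.orth.add("rat", "gB_rat", "OG_B2")
        self.orth.add("human", "gB_human", "OG_B3")

    def test_three_species_one_group_is_category_three(self):
        call = homology.assign_category(
            "iso1",
            {"mouse": "gA_mouse", "rat": "gA_rat", "human": "gA_human"},
            self.orth,
        )
        assert call.category == 3

    def test_missing_species_caps_at_category_two(self):
        call = homology.assign_category(
            "iso1", {"mouse": "gA_mouse", "rat": "gA_rat", "human": None}, self.orth
        )
        assert call.category == 2

    def test_three_distinct_groups_is_category_one(self):
        call = homology.assign_category(
            "iso1",
            {"mouse": "gB_mouse", "rat": "gB_rat", "human": "gB_human"},
            self.orth,
        )
        assert call.category == 1

    def test_no_calls_at_all_raises(self):
        with pytest.raises(ValueError):
            homology.assign_category("iso1", {"mouse": None}, self.orth)

    def test_planted_categories_recovered_from_panel(self):
        cfg = SimConfig(seed=33, n_genes=40, frac_decoy=0,
                        frac_novel_isotigs=0, frac_splice_variants=0,
                        frac_category1=0.1, frac_species_dropout=0.1,
                        frac_group_reassign=0.1)
        panel = generate_reference_panel(cfg)
        records, truth = generate_isotigs(panel, cfg)
        hsps, _ = generate_hit_table(records, panel, cfg)
        models = panel.models_by_transcript()
        for rec in records:
            genes = {}
            for sp in panel.species:
                grouped = {}
                for h in hsps:
                    if h.query_id == rec.isotig_id and models[h.target_id].species == sp:
                        grouped.setdefault(h.target_id, []).append(h)
                chains = [
                    homology.resolve_gene(homology.chain_hsps(g), models)
                    for g in grouped.values()
                ]
                call = homology.classify_unique(chains)
                genes[sp] = call.best.gene_id if call.status == "unique" else None
            cat = homology.assign_category(rec.isotig_id, genes, panel.orthology)
            assert cat.category == truth.planted_categories[rec.gene_core]


class TestUtrProfile:
    def test_portion_and_size_histograms(self):
        calls = [
            homology.CategoryCall("i1", {}, 3, coding_portion=0.0, aligned_total=100),
            homology.CategoryCall("i2", {}, 3, coding_portion=0.5, aligned_total=900),
            homology.CategoryCall("i3", {}, 1, coding_portion=0.1, aligned_total=2000),
        ]
        prof = homology.utr_profile(calls)
        assert prof[3]["coding_portion"].tolist() == [1, 0, 1, 0]
        assert prof[3]["aligned_total"].tolist() == [1, 0, 1, 0]
        assert prof[1]["coding_portion"].tolist() == [1, 0, 0, 0]
        assert prof[1]["aligned_total"].tolist() == [0, 0, 0, 1]
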