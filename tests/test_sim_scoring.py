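"""Component scores, the two-stage predictor, and the evaluation metrics.

The predictor is cross-checked against an independent brute-force scorer
that enumerates every (region, template, homolog-pair) triple directly
from the formulas.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from campnets.io_formats import AlignmentHit, DistanceTable
from campnets.sim_scoring import (InteractionNetwork, evaluate, f2_score,
                                  joint_evalue, predict_partners,
                                  region_query_id, roc_auc, score_es,
                                  score_irs, score_jss, score_qul, score_rank,
                                  score_topo)
from campnets.synthetic import FixtureConfig, make_interactome_fixture
from campnets.template_curation import count_evidence, exclude_self_templates


class TestComponentScores:
    @pytest.mark.parametrize("si,L,Q,expected", [
        (1.0, 100, 100, 1.0),
        (0.5, 50, 100, 0.5),       # sqrt(0.5 * 0.5)
        (0.0, 80, 100, 0.0),
        (1.0, 200, 100, 1.0),      # coverage clipped at 1
    ])
    def test_irs(self, si, L, Q, expected):
        assert score_irs(si, L, Q) == pytest.approx(expected)

    def test_irs_bad_region_length(self):
        with pytest.raises(ValueError):
            score_irs(0.5, 50, 0)

    @pytest.mark.parametrize("xm,xt,xr,expected", [
        (2, 2, 2, 1.0),
        (0, 0, 0, 0.0),
        (1, 0, 5, 0.5),            # (1 + 0 + 2) / 6
        (3, 1, 5, 5 / 6),          # caps applied
    ])
    def test_qul(self, xm, xt, xr, expected):
        assert score_qul(xm, xt, xr) == pytest.approx(expected)

    def test_qul_negative_count(self):
        with pytest.raises(ValueError):
            score_qul(-1, 0, 0)

    @pytest.mark.parametrize("ea,eb,eas,ebs,expected", [
        (1e-50, 1e-50, 1e-50, 1e-50, 1.0),          # self-normalization
        (1e-50, 1e-20, 1e-200, 1e-80, 0.25),        # sqrt(50/200)*sqrt(20/80)
        (1.0, 1e-50, 1e-100, 1e-100, 0.0),          # E >= 1 kills the ratio
    ])
    def test_jss(self, ea, eb, eas, ebs, expected):
        assert score_jss(ea, eb, eas, ebs) == pytest.approx(expected)

    def test_jss_ratio_clipped_when_cross_beats_self(self):
        # floored E-values can invert the ratio; it must clip to 1
        assert score_jss(1e-150, 1e-150, 1e-100, 1e-100) == pytest.approx(1.0)

    @pytest.mark.parametrize("r,rmax,expected", [
        (1, 100, 1.0),
        (100, 100, 0.0),
        (10, 100, 0.5),
        (1, 1, 1.0),               # lone candidate
    ])
    def test_rank(self, r, rmax, expected):
        assert score_rank(r, rmax) == pytest.approx(expected)

    def test_rank_out_of_range(self):
        with pytest.raises(ValueError):
            score_rank(101, 100)

    @pytest.mark.parametrize("evidence,expected", [
        ({"f1": (0.6, 1)}, 0.3),
        ({"f1": (0.6, 2)}, 0.6),
        ({"f1": (0.6, 5)}, 0.6),                    # m_f capped at 2
        ({"f1": (0.8, 2), "f2": (0.9, 2)}, 1.0),    # clipped at 1
        ({}, 0.0),
    ])
    def test_es(self, evidence, expected):
        assert score_es(evidence) == pytest.approx(expected)

    @pytest.mark.parametrize("c,n,rb,rmax,expected", [
        (2, 8, 1, 13913, 0.5),     # sqrt(0.25 * 1)
        (0, 5, 100, 13913, 0.0),
        (5, 5, 1, 10, 1.0),
        (0, 0, 1, 10, 0.0),        # isolated protein
    ])
    def test_topo(self, c, n, rb, rmax, expected):
        assert score_topo(c, n, rb, rmax) == pytest.approx(expected)

    def test_topo_shared_exceeding_degree(self):
        with pytest.raises(ValueError):
            score_topo(6, 5, 1, 10)


class TestComponentProperties:
    @settings(deadline=None, max_examples=100)
    @given(st.floats(0, 1), st.integers(1, 500), st.integers(1, 500))
    def test_irs_in_unit_interval(self, si, L, Q):
        assert 0.0 <= score_irs(si, L, Q) <= 1.0

    @settings(deadline=None, max_examples=100)
    @given(st.floats(1e-180, 0.99), st.floats(1e-180, 0.99),
           st.floats(1e-180, 0.99), st.floats(1e-180, 0.99))
    def test_jss_in_unit_interval(self, ea, eb, eas, ebs):
        assert 0.0 <= score_jss(ea, eb, eas, ebs) <= 1.0

    @settings(deadline=None, max_examples=60)
    @given(st.floats(0.1, 1.0), st.floats(0.1, 1.0), st.integers(10, 400))
    def test_irs_monotone_in_identity(self, si_lo, si_hi, Q):
        lo, hi = sorted((si_lo, si_hi))
        assert score_irs(lo, Q, Q) <= score_irs(hi, Q, Q) + 1e-12

    @settings(deadline=None, max_examples=60)
    @given(st.floats(-170, -11), st.floats(-170, -11))
    def test_jss_decreasing_in_cross_evalue(self, la, lb):
        lo, hi = sorted((la, lb))   # lo is the smaller exponent = better hit
        better = score_jss(10 ** lo, 1e-50, 1e-180, 1e-180)
        worse = score_jss(10 ** hi, 1e-50, 1e-180, 1e-180)
        assert worse <= better + 1e-12

    @settings(deadline=None, max_examples=60)
    @given(st.integers(1, 1000), st.integers(1, 1000))
    def test_rank_decreasing_in_rank(self, r1, r2):
        lo, hi = sorted((r1, r2))
        rmax = 1000
        assert score_rank(hi, rmax) <= score_rank(lo, rmax) + 1e-12

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 20), st.integers(0, 20), st.integers(1, 50))
    def test_topo_increasing_in_shared(self, c1, c2, rb):
        lo, hi = sorted((c1, c2))
        n, rmax = 20, 50
        assert score_topo(lo, n, rb, rmax) <= score_topo(hi, n, rb, rmax) + 1e-12


class TestNetwork:
    def test_fractional_ranks(self):
        net = InteractionNetwork.from_edges(
            [("hub", x) for x in "abc"] + [("a", "b")])
        # degrees: hub=3, a=2, b=2, c=1
        assert net.rank["hub"] == 1.0
        assert net.rank["a"] == net.rank["b"] == 2.5
        assert net.rank["c"] == net.r_max == 4.0

    def test_asymmetric_adjacency_rejected(self):
        with pytest.raises(ValueError):
            InteractionNetwork(adjacency={"a": frozenset("b"), "b": frozenset()})


def brute_force_predict(mp, templates, region_hits, proteome_hits,
                        network, distances, target_species="human"):
    """Independent scorer: plain nested loops over every triple."""
    best_hit = {}
    for h in list(region_hits) + list(proteome_hits):
        k = (h.query_id, h.subject_id)
        if k not in best_hit or h.evalue < best_hit[k].evalue:
            best_hit[k] = h
    triples = []
    for region in mp.cytoplasmic_regions:
        qid = region_query_id(mp.id, region)
        for t in templates:
            for a, b in ((t.protein_a, t.protein_b), (t.protein_b, t.protein_a)):
                rh = best_hit.get((qid, a))
                if rh is None:
                    continue
                ah = best_hit.get((a, mp.id))
                a_self, b_self = best_hit.get((a, a)), best_hit.get((b, b))
                if ah is None or a_self is None or b_self is None:
                    continue
                if ah.evalue > 1e-10:
                    continue
                for (q, s), bh in best_hit.items():
                    if q != b or s in (a, b, mp.id):
                        continue
                    if bh.evalue > 1e-10:
                        continue
                    if math.sqrt(ah.evalue * bh.evalue) > 1e-40:
                        continue
                    qd = region[1] - region[0] + 1
                    s_irs = math.sqrt(rh.identity * min(rh.aligned_length / qd, 1))
                    xm, xt, xr = count_evidence(t)
                    s_qul = (xm + xt + xr) / 6
                    ra = min(math.log10(ah.evalue) / math.log10(a_self.evalue), 1)
                    rb = min(math.log10(bh.evalue) / math.log10(b_self.evalue), 1)
                    s_jss = math.sqrt(max(ra, 0)) * math.sqrt(max(rb, 0))
                    triples.append(dict(partner=s, template=t, s_irs=s_irs,
                                        s_qul=s_qul, s_jss=s_jss))
    # ranks within template
    for t in {id(tr["template"]): tr["template"] for tr in triples}.values():
        sub = [tr for tr in triples if tr["template"] is t]
        ranks = rankdata([-tr["s_jss"] for tr in sub], method="average")
        for tr, r in zip(sub, ranks):
            tr["s_rank"] = (1.0 if len(sub) == 1
                            else 1 - math.log10(r) / math.log10(len(sub)))
    # evolutionary conservation per partner
    scores = {}
    for tr in triples:
        partner = tr["partner"]
        tset = {t2["template"] for t2 in triples if t2["partner"] == partner}
        per_org = {}
        for t2 in tset:
            org = t2.species[0] if len(t2.species) == 1 else "+".join(t2.species)
            d = (distances.get(target_species, t2.species[0])
                 if len(t2.species) == 1 else
                 np.mean([distances.get(target_species, s) for s in t2.species]))
            cnt, _ = per_org.get(org, (0, d))
            per_org[org] = (cnt + 1, d)
        s_es = min(sum(d * min(m, 2) / 2 for m, d in per_org.values()), 1.0)
        s_topo = network.topo_score(mp.id, partner) if network else 0.0
        total = (tr["s_irs"] + tr["s_qul"] + tr["s_jss"] + tr["s_rank"]
                 + s_es + s_topo)
        scores[partner] = max(scores.get(partner, -1), total)
    return scores


class TestPredictPartners:
    def test_matches_brute_force_on_small_instance(self, interactome):
        fx = interactome
        mp = fx.mps[0]
        templates = exclude_self_templates(mp, fx.templates)
        cands = predict_partners(fx.proteins[mp], templates, fx.region_hits,
                                 fx.proteome_hits, fx.network, fx.distances,
                                 threshold=0.0)
        got = {c.partner_id: c.s_sim for c in cands}
        expected = brute_force_predict(fx.proteins[mp], templates,
                                       fx.region_hits, fx.proteome_hits,
                                       fx.network, fx.distances)
        assert set(got) == set(expected)
        for partner in got:
            assert got[partner] == pytest.approx(expected[partner], abs=1e-9)

    def test_components_in_bounds_and_sum(self, interactome):
        fx = interactome
        mp = fx.mps[1]
        cands = predict_partners(
            fx.proteins[mp], exclude_self_templates(mp, fx.templates),
            fx.region_hits, fx.proteome_hits, fx.network, fx.distances,
            threshold=0.0)
        assert cands
        for c in cands:
            for comp in (c.s_irs, c.s_qul, c.s_jss, c.s_rank, c.s_es, c.s_topo):
                assert 0.0 <= comp <= 1.0
            assert 0.0 <= c.s_sim <= 6.0

    def test_joint_evalue_gate_excludes(self):
        # single candidate whose per-protein Es pass but joint E fails
        from campnets.io_formats import ProteinRecord
        from campnets.template_curation import PPITemplate
        mp = ProteinRecord("MP", "human", 200, ((1, 100),), True)
        t = PPITemplate(protein_a="A", protein_b="B", species=("yeast",))
        qid = region_query_id("MP", (1, 100))
        hits_region = {AlignmentHit(qid, "A", 0.9, 100, 1e-30)}
        hits_prot = {
            AlignmentHit("A", "A", 1.0, 200, 1e-100),
            AlignmentHit("B", "B", 1.0, 200, 1e-100),
            AlignmentHit("A", "MP", 0.9, 200, 1e-30),
            AlignmentHit("B", "X", 0.9, 200, 1e-30),  # joint E = 1e-30 > 1e-40
        }
        dist = DistanceTable(pairs={("human", "yeast"): 0.8})
        assert predict_partners(mp, {t}, hits_region, hits_prot, None, dist,
                                threshold=0.0) == []

    def test_mp_without_cytoplasmic_region_empty(self, interactome):
        from campnets.io_formats import ProteinRecord
        fx = interactome
        bald = ProteinRecord("BALD", "human", 100)
        assert predict_partners(bald, fx.templates, fx.region_hits,
                                fx.proteome_hits, fx.network, fx.distances) == []

    def test_self_template_rejected(self, interactome):
        from campnets.template_curation import PPITemplate
        fx = interactome
        mp = fx.mps[0]
        own = PPITemplate(protein_a=mp, protein_b="Z", species=("human",))
        with pytest.raises(ValueError, match="exclude_self_templates"):
            predict_partners(fx.proteins[mp], set(fx.templates) | {own},
                             fx.region_hits, fx.proteome_hits, fx.network,
                             fx.distances)


class TestEvaluate:
    def test_perfect_separation(self):
        scored = {frozenset((f"p{i}", "m")): 5.0 for i in range(5)}
        scored.update({frozenset((f"n{i}", "m")): 1.0 for i in range(5)})
        res = evaluate(scored, [frozenset((f"p{i}", "m")) for i in range(5)],
                       [frozenset((f"n{i}", "m")) for i in range(5)])
        assert res["auc"] == 1.0
        assert res["best_f2"] == 1.0

    def test_f2_closed_form(self):
        assert f2_score(0.5, 1.0) == pytest.approx(5 / 6, abs=1e-4)

    def test_random_labels_auc_near_half(self, rng):
        scores = rng.normal(size=1000)
        labels = rng.random(1000) < 0.5
        pos = [frozenset((f"g{i}", "m")) for i in range(1000) if labels[i]]
        neg = [frozenset((f"g{i}", "m")) for i in range(1000) if not labels[i]]
        scored = {frozenset((f"g{i}", "m")): scores[i] for i in range(1000)}
        res = evaluate(scored, pos, neg)
        assert res["auc"] == pytest.approx(0.5, abs=0.05)

    def test_unscored_labeled_pairs_get_zero(self):
        scored = {frozenset(("a", "m")): 3.0}
        res = evaluate(scored, [frozenset(("a", "m"))],
                       [frozenset(("zzz", "m"))])
        assert res["auc"] == 1.0

    def test_empty_class_is_error(self):
        with pytest.raises(ValueError):
            evaluate({}, [frozenset(("a", "b"))], [])

    def test_tie_breaks_to_smallest_threshold(self):
        scored = {frozenset(("a", "m")): 2.0, frozenset(("b", "m")): 3.0}
        res = evaluate(scored, [frozenset(("a", "m")), frozenset(("b", "m"))],
                       [frozenset(("c", "m"))])
        # both thresholds 2.0 and 3.0 may yield the same F2; 2.0 wins ties
        assert res["best_threshold"] == 2.0
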