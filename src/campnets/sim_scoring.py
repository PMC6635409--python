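"""The six-component interaction score for membrane-protein PPI prediction.

A candidate interaction A'-B' (A' the membrane protein, B' a proteome
partner) is inferred from an interolog template A-B and scored as the sum
of six components, each in [0, 1]:

====== =====================================================================
s_irs  interacting-region similarity: sqrt(SI * L / Q_d) between a
       cytoplasmic region of the MP and a template protein
s_qul  template quality: capped evidence counts (x_m + x_t + x_r) / 6
s_jss  normalized joint sequence similarity: geometric mean of
       -log10(E') / -log10(E_self) ratios for the two sides
s_rank rank of the candidate among the template's candidates by s_jss:
       1 - log10(r) / log10(r_max)
s_es   evolutionary conservation: sum over source organisms of the
       normalized distance times min(m_f, 2)/2, clipped to [0, 1]
s_topo network topology: sqrt((C/N) * D) from shared neighbors and the
       partner's normalized degree rank
====== =====================================================================

The total ranges 0-6.  Candidate pairs must satisfy per-protein E <= 1e-10
and joint E (geometric mean of the two E-values) <= 1e-40; default score
thresholds are 3.6 for reported templates and 3.7 for direct templates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .io_formats import AlignmentHit, DistanceTable, ProteinRecord
from .template_curation import PPITemplate, ReliabilityMap, count_evidence

logger = logging.getLogger("campnets")

#: Per-protein homology gate (BLASTP E-value).
EVALUE_SINGLE_MAX = 1e-10
#: Joint E-value gate (geometric mean over the two sides).
EVALUE_JOINT_MAX = 1e-40
#: Default score thresholds by template mode.
THRESHOLD_REPORTED = 3.6
THRESHOLD_DIRECT = 3.7


# ---------------------------------------------------------------------------
# component scores
# ---------------------------------------------------------------------------

def score_irs(si: float, aligned_length: int, region_length: int) -> float:
    """Interacting-region similarity sqrt(SI * L/Q_d), L/Q_d clipped to 1."""
    if region_length <= 0:
        raise ValueError(f"region length must be positive, got {region_length}")
    if not 0.0 <= si <= 1.0:
        raise ValueError(f"sequence identity {si} outside [0,1]")
    if aligned_length < 1:
        raise ValueError(f"aligned length {aligned_length} < 1")
    coverage = min(aligned_length / region_length, 1.0)
    return math.sqrt(si * coverage)


def score_qul(x_m: int, x_t: int, x_r: int) -> float:
    """Template quality from capped evidence counts, in [0, 1]."""
    if min(x_m, x_t, x_r) < 0:
        raise ValueError("evidence counts must be nonnegative")
    return (min(x_m, 2) + min(x_t, 2) + min(x_r, 2)) / 6.0


def _log_ratio(e_cross: float, e_self: float) -> float:
    # E >= 1 carries no similarity signal; floored E-values can make the
    # cross log exceed the self log, hence the [0, 1] clip.
    if e_cross >= 1.0:
        return 0.0
    denom = -math.log10(e_self)
    if denom <= 0:
        return 0.0
    return min(max(-math.log10(e_cross) / denom, 0.0), 1.0)


def score_jss(e_a_prime: float, e_b_prime: float,
              e_a_self: float, e_b_self: float) -> float:
    """Joint sequence similarity: geometric mean of per-side log-E ratios."""
    return math.sqrt(_log_ratio(e_a_prime, e_a_self)) * \
        math.sqrt(_log_ratio(e_b_prime, e_b_self))


def score_rank(r: float, r_max: float) -> float:
    """Normalized candidate rank 1 - log10(r)/log10(r_max); top rank -> 1."""
    if r_max < 1:
        raise ValueError(f"r_max {r_max} < 1")
    if not 1 <= r <= r_max:
        raise ValueError(f"rank {r} outside [1, {r_max}]")
    if r_max == 1:
        return 1.0
    return 1.0 - math.log10(r) / math.log10(r_max)


def score_es(evidence: Mapping[str, tuple[float, int]]) -> float:
    """Evolutionary conservation over source organisms, clipped to [0, 1].

    ``evidence`` maps organism -> (normalized distance in [0, 1], number of
    templates m_f >= 1 supporting the candidate in that organism).
    Multiple templates (m_f >= 2) count as full conservation weight.
    """
    total = 0.0
    for organism, (dist, m_f) in evidence.items():
        if not 0.0 <= dist <= 1.0:
            raise ValueError(f"distance {dist} for {organism} outside [0,1]")
        if m_f < 1:
            raise ValueError(f"template count {m_f} for {organism} < 1")
        total += dist * min(m_f, 2) / 2.0
    return min(total, 1.0)


def score_topo(c: int, n: int, r_b: float, r_max: float) -> float:
    """Network-topology score sqrt((C/N) * D), D = 1 - (R_B - 1)/R_max."""
    if c < 0 or n < 0 or c > n:
        raise ValueError(f"need 0 <= C <= N, got C={c}, N={n}")
    if not 1 <= r_b <= r_max:
        raise ValueError(f"rank {r_b} outside [1, {r_max}]")
    if n == 0:
        return 0.0
    d = 1.0 - (r_b - 1.0) / r_max
    return math.sqrt((c / n) * d)


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------

@dataclass
class InteractionNetwork:
    """An undirected PPI network with fractional degree ranks.

    Rank 1 is the largest degree; ties get average (fractional) ranks;
    ``r_max`` is the rank of the smallest-degree protein.
    """

    adjacency: dict[str, frozenset[str]]
    degree: dict[str, int] = field(init=False)
    rank: dict[str, float] = field(init=False)
    r_max: float = field(init=False)

    def __post_init__(self) -> None:
        adj = {p: frozenset(nbrs) for p, nbrs in self.adjacency.items()}
        for p, nbrs in adj.items():
            for q in nbrs:
                if p not in adj.get(q, frozenset()):
                    raise ValueError(f"asymmetric adjacency: {p}->{q}")
        self.adjacency = adj
        self.degree = {p: len(nbrs) for p, nbrs in adj.items()}
        proteins = sorted(adj)
        degrees = np.array([self.degree[p] for p in proteins], dtype=float)
        # rankdata ranks ascending; negate for rank 1 = largest degree
        ranks = rankdata(-degrees, method="average")
        self.rank = dict(zip(proteins, ranks))
        self.r_max = float(ranks.max()) if len(ranks) else 1.0

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        adj: dict[str, set[str]] = {}
        for a, b in edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return cls(adjacency={p: frozenset(v) for p, v in adj.items()})

    def shared_neighbors(self, a: str, b: str) -> int:
        return len(self.adjacency.get(a, frozenset()) & self.adjacency.get(b, frozenset()))

    def topo_score(self, mp: str, partner: str) -> float:
        n = self.degree.get(mp, 0)
        if n == 0 or partner not in self.rank:
            return 0.0
        return score_topo(self.shared_neighbors(mp, partner), n,
                          self.rank[partner], self.r_max)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidatePPI:
    """A scored MP-partner candidate with its six components."""

    mp_id: str
    partner_id: str
    template: PPITemplate
    s_irs: float
    s_qul: float
    s_jss: float
    s_rank: float
    s_es: float
    s_topo: float

    @property
    def s_sim(self) -> float:
        return (self.s_irs + self.s_qul + self.s_jss +
                self.s_rank + self.s_es + self.s_topo)


def joint_evalue(e_a: float, e_b: float) -> float:
    """Geometric mean of the two per-protein E-values."""
    return math.sqrt(e_a * e_b)


def _best_hits(hits: Iterable[AlignmentHit]) -> dict[tuple[str, str], AlignmentHit]:
    """Index hits by (query, subject), keeping the lowest-E hit per pair."""
    best: dict[tuple[str, str], AlignmentHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        if key not in best or h.evalue < best[key].evalue:
            best[key] = h
    return best


def region_query_id(mp_id: str, region: tuple[int, int]) -> str:
    """Query identifier used for a cytoplasmic-region alignment search."""
    return f"{mp_id}:{region[0]}-{region[1]}"


def predict_partners(mp: ProteinRecord,
                     templates: Iterable[PPITemplate],
                     region_hits: Iterable[AlignmentHit],
                     proteome_hits: Iterable[AlignmentHit],
                     network: InteractionNetwork | None,
                     distances: DistanceTable,
                     target_species: str = "human",
                     reliability_map: ReliabilityMap | None = None,
                     threshold: float = THRESHOLD_REPORTED,
                     e_single_max: float = EVALUE_SINGLE_MAX,
                     e_joint_max: float = EVALUE_JOINT_MAX) -> list[CandidatePPI]:
    """Two-stage interolog prediction of partners for one membrane protein.

    Stage 1 selects templates hit by any cytoplasmic region of the MP
    (``region_hits``: query = region id, subject = template protein; the
    hit side becomes the MP-side template protein).  Stage 2 enumerates
    proteome homologs of the partner-side template protein
    (``proteome_hits``: query = template protein, subject = proteome
    protein, including self-alignments for normalization), applies the
    per-protein and joint E-value gates, scores every supported
    (region, template, partner) combination, and reports per (MP, partner)
    pair the maximum-scoring combination.  Candidates below ``threshold``
    are dropped.

    Templates must already exclude the MP's own interactions (see
    :func:`campnets.template_curation.exclude_self_templates`).
    """
    templates = list(templates)
    if not mp.cytoplasmic_regions:
        logger.warning("MP %s has no cytoplasmic region; no candidates", mp.id)
        return []
    region_index = _best_hits(region_hits)
    prot_index = _best_hits(proteome_hits)
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in prot_index.values():
        by_query.setdefault(h.query_id, []).append(h)

    # stage 1: template selection by cytoplasmic-region hits
    selected: list[tuple[tuple[int, int], PPITemplate, str, str, AlignmentHit]] = []
    for template in templates:
        if mp.id in template.pair:
            raise ValueError(
                f"template {template.protein_a}-{template.protein_b} involves the "
                f"query MP {mp.id}; apply exclude_self_templates first")
        for region in mp.cytoplasmic_regions:
            qid = region_query_id(mp.id, region)
            for a_side, b_side in ((template.protein_a, template.protein_b),
                                   (template.protein_b, template.protein_a)):
                hit = region_index.get((qid, a_side))
                if hit is not None:
                    selected.append((region, template, a_side, b_side, hit))

    # stage 2: enumerate, gate, and score candidates per template
    raw: list[dict] = []
    for region, template, a_side, b_side, region_hit in selected:
        e_a_self_hit = prot_index.get((a_side, a_side))
        e_b_self_hit = prot_index.get((b_side, b_side))
        e_a_hit = prot_index.get((a_side, mp.id))
        if e_a_self_hit is None or e_b_self_hit is None or e_a_hit is None:
            logger.warning("template %s-%s lacks alignment coverage; skipped",
                           template.protein_a, template.protein_b)
            continue
        e_a = e_a_hit.evalue
        if e_a > e_single_max:
            continue
        for b_hit in by_query.get(b_side, ()):
            partner = b_hit.subject_id
            if partner in (b_side, a_side, mp.id):
                continue
            e_b = b_hit.evalue
            if e_b > e_single_max:
                continue
            if joint_evalue(e_a, e_b) > e_joint_max:
                continue
            s_jss = score_jss(e_a, e_b, e_a_self_hit.evalue, e_b_self_hit.evalue)
            region_length = region[1] - region[0] + 1
            s_irs = score_irs(region_hit.identity, region_hit.aligned_length,
                              region_length)
            s_qul = score_qul(*count_evidence(template, reliability_map))
            raw.append({
                "partner": partner, "template": template, "region": region,
                "s_irs": s_irs, "s_qul": s_qul, "s_jss": s_jss,
            })

    if not raw:
        return []

    # s_rank: fractional ranks over each template's candidates, descending s_jss
    by_template: dict[frozenset[str], list[int]] = {}
    for i, rec in enumerate(raw):
        by_template.setdefault(rec["template"].pair, []).append(i)
    for indices in by_template.values():
        jss = np.array([raw[i]["s_jss"] for i in indices])
        ranks = rankdata(-jss, method="average")
        r_max = len(indices)
        for idx, r in zip(indices, ranks):
            raw[idx]["s_rank"] = score_rank(float(r), float(r_max))

    # s_es: per (MP, partner) pair across its supporting templates
    pair_templates: dict[str, set[PPITemplate]] = {}
    for rec in raw:
        pair_templates.setdefault(rec["partner"], set()).add(rec["template"])
    pair_es: dict[str, float] = {}
    for partner, tset in pair_templates.items():
        per_organism: dict[str, int] = {}
        org_dist: dict[str, float] = {}
        for t in tset:
            if len(t.species) == 1:
                organism = t.species[0]
                dist = distances.get(target_species, organism)
            else:
                # cross-species template: mean distance to the two sources
                organism = "+".join(t.species)
                dist = float(np.mean([distances.get(target_species, s)
                                      for s in t.species]))
            per_organism[organism] = per_organism.get(organism, 0) + 1
            org_dist[organism] = dist
        pair_es[partner] = score_es(
            {o: (org_dist[o], m) for o, m in per_organism.items()})

    # assemble: max S_SIM per (MP, partner) pair
    best: dict[str, CandidatePPI] = {}
    for rec in raw:
        partner = rec["partner"]
        s_topo = network.topo_score(mp.id, partner) if network is not None else 0.0
        cand = CandidatePPI(
            mp_id=mp.id, partner_id=partner, template=rec["template"],
            s_irs=rec["s_irs"], s_qul=rec["s_qul"], s_jss=rec["s_jss"],
            s_rank=rec["s_rank"], s_es=pair_es[partner], s_topo=s_topo)
        if partner not in best or cand.s_sim > best[partner].s_sim:
            best[partner] = cand
    return sorted((c for c in best.values() if c.s_sim >= threshold),
                  key=lambda c: -c.s_sim)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def roc_auc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """ROC AUC by the rank statistic with tie-averaging (Mann-Whitney)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2)
                 / (len(pos) * len(neg)))


def f2_score(precision: float, recall: float) -> float:
    """F2 = 5PR / (4P + R); recall-weighted F-measure."""
    if precision + recall == 0:
        return 0.0
    return 5.0 * precision * recall / (4.0 * precision + recall)


def evaluate(scored_pairs: Mapping[frozenset[str], float],
             positives: Iterable[frozenset[str]],
             negatives: Iterable[frozenset[str]]) -> dict:
    """Evaluate predictions against labeled positive and negative pairs.

    Unscored labeled pairs receive score 0.  Returns the ROC AUC, the
    precision/recall curve over the grid of observed scores, the best F2
    and the threshold attaining it (smallest threshold on ties).
    """
    positives = set(positives)
    negatives = set(negatives)
    if positives & negatives:
        raise ValueError("positives and negatives overlap")
    if not positives or not negatives:
        raise ValueError("both label classes must be non-empty")
    pos_scores = [scored_pairs.get(p, 0.0) for p in sorted(positives, key=sorted)]
    neg_scores = [scored_pairs.get(p, 0.0) for p in sorted(negatives, key=sorted)]
    auc = roc_auc(pos_scores, neg_scores)

    pos_arr = np.asarray(pos_scores)
    neg_arr = np.asarray(neg_scores)
    grid = np.unique(np.concatenate([pos_arr, neg_arr]))
    pr_curve = []
    best_f2, best_threshold = -1.0, None
    for thr in grid:
        tp = int((pos_arr >= thr).sum())
        fp = int((neg_arr >= thr).sum())
        fn = len(pos_scores) - tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f2 = f2_score(precision, recall)
        pr_curve.append((float(thr), precision, recall, f2))
        if f2 > best_f2:
            best_f2, best_threshold = f2, float(thr)
    return {"auc": auc, "pr_curve": pr_curve,
            "best_f2": best_f2, "best_threshold": best_threshold}
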