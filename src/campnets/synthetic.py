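"""Seeded synthetic fixtures with the statistical structure each pipeline
stage assumes.

Three generators cover the pipeline's inputs end to end:

* :func:`make_interactome_fixture` — a proteome with membrane proteins,
  interolog templates across source organisms, planted alignment hits
  (strong homology for true pairs, weak for decoys), a distance table,
  and a human interaction network with labeled positives/negatives.
* :func:`make_expression_survival_fixture` — log2 expression with planted
  differential-expression shifts, latent-factor co-expression blocks, and
  proportional-hazards survival tied to designated genes.
* :func:`make_pathway_fixture` — overlapping gene sets with a designated
  cancer-related subset and one pathway planted to be enriched against a
  designated community.

E-values are generated directly as a deterministic function of planted
identity and length plus log-scale noise; no aligner runs.  Every
generator is a pure function of its configuration (seed included), so the
same config reproduces bit-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (AlignmentHit, DistanceTable, ExpressionMatrix,
                         ProteinRecord, SurvivalTable)
from .networks import Community
from .sim_scoring import InteractionNetwork, region_query_id
from .template_curation import PPITemplate


@dataclass(frozen=True)
class FixtureConfig:
    """Configuration for all synthetic generators; the seed is mandatory."""

    seed: int
    # interactome
    n_mps: int = 4
    n_templates_per_mp: int = 6
    n_decoys_per_mp: int = 8
    organisms: tuple[str, ...] = ("mouse", "fly", "worm", "yeast")
    organism_distances: tuple[float, ...] = (0.15, 0.55, 0.65, 0.8)
    identity_positive: float = 0.85
    identity_decoy: float = 0.35
    log10e_positive: float = -60.0    # template-to-human cross E-values
    log10e_scored_decoy: float = -25.0
    log10e_gated_decoy: float = -12.0
    log10e_self: float = -100.0
    e_noise_sd: float = 3.0           # log10-scale noise on E-values
    # expression
    n_genes: int = 400
    n_tumor: int = 120
    n_normal: int = 40
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    noise_sd: float = 1.0
    block_size: int = 20
    n_blocks: int = 2
    target_r: float = 0.7
    delta_log2fc: float = 2.0
    n_extra_degs: int = 30
    # survival
    beta: float = 0.3                 # per-gene log-hazard on prognostic genes
    n_prognostic: int = 5
    baseline_hazard: float = 0.02     # events per month at linear predictor 0
    censor_hazard: float = 0.008
    # pathways
    n_pathways: int = 12
    pathway_size: int = 22
    n_cancer_related: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.target_r < 1.0:
            raise ValueError(f"target_r {self.target_r} outside (0,1)")
        if len(self.organisms) != len(self.organism_distances):
            raise ValueError("organisms and organism_distances differ in length")
        if self.n_templates_per_mp < 1:
            raise ValueError("need at least one template per MP")


def gene_names(cfg: FixtureConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(cfg.n_genes)]


def _community_layout(cfg: FixtureConfig) -> tuple[str, list[str], list[str]]:
    """Deterministic split of the first co-expression block into the
    designated community (mp + partners) and the planted pathway genes."""
    block0 = gene_names(cfg)[:cfg.block_size]
    half = cfg.block_size // 2
    mp, partners = block0[0], block0[1:half]
    pathway_genes = block0[half:]
    return mp, partners, pathway_genes


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------

@dataclass
class InteractomeFixture:
    proteins: dict[str, ProteinRecord]
    templates: set[PPITemplate]
    region_hits: set[AlignmentHit]
    proteome_hits: set[AlignmentHit]
    distances: DistanceTable
    network: InteractionNetwork
    positives: set[frozenset[str]]
    negatives: set[frozenset[str]]
    mps: list[str]


def _evalue(rng: np.random.Generator, log10e: float, sd: float) -> float:
    return float(10.0 ** min(log10e + rng.normal(0, sd), -10.5))


def make_interactome_fixture(cfg: FixtureConfig) -> InteractomeFixture:
    """Planted-homology interactome for exercising the interolog scorer.

    Per MP, each template (A, B) in a source organism receives a
    cytoplasmic-region hit against A and proteome hits mapping A to the
    MP (strong) and B to one true partner (strong), one scored decoy
    (borderline homology that passes the joint-E gate with a low score),
    and one gated decoy (joint E above the gate).  The human network links
    each MP with its true partners through shared neighbors, so true
    pairs also collect topology score.
    """
    rng = np.random.default_rng(cfg.seed)
    proteins: dict[str, ProteinRecord] = {}
    templates: set[PPITemplate] = set()
    region_hits: set[AlignmentHit] = set()
    proteome_hits: set[AlignmentHit] = set()
    positives: set[frozenset[str]] = set()
    negatives: set[frozenset[str]] = set()
    edges: list[tuple[str, str]] = []

    dist = DistanceTable(pairs={("human", o): d for o, d in
                                zip(cfg.organisms, cfg.organism_distances)})

    mps = [f"MP{i}" for i in range(cfg.n_mps)]
    for mi, mp_id in enumerate(mps):
        region = (21, 140)
        region_len = region[1] - region[0] + 1
        proteins[mp_id] = ProteinRecord(id=mp_id, species="human", length=300,
                                        cytoplasmic_regions=(region,), is_mp=True)
        qid = region_query_id(mp_id, region)
        for ti in range(cfg.n_templates_per_mp):
            org = cfg.organisms[ti % len(cfg.organisms)]
            a, b = f"A{mi}_{ti}", f"B{mi}_{ti}"
            proteins[a] = ProteinRecord(id=a, species=org, length=280)
            proteins[b] = ProteinRecord(id=b, species=org, length=320)
            templates.add(PPITemplate(
                protein_a=min(a, b), protein_b=max(a, b), species=(org,),
                detection_methods=frozenset({"MI:0114", "MI:0018"}),
                interaction_types=frozenset({"MI:0407"}),
                references=frozenset({f"PM{mi}{ti}0", f"PM{mi}{ti}1"})))
            # stage-1 hit: MP cytoplasmic region vs template protein A
            region_hits.add(AlignmentHit(
                query_id=qid, subject_id=a,
                identity=min(cfg.identity_positive + rng.normal(0, 0.03), 1.0),
                aligned_length=int(region_len * rng.uniform(0.85, 1.0)),
                evalue=_evalue(rng, cfg.log10e_positive, cfg.e_noise_sd)))
            # self-alignments used to normalize the joint similarity
            for prot in (a, b):
                proteome_hits.add(AlignmentHit(
                    query_id=prot, subject_id=prot, identity=1.0,
                    aligned_length=proteins[prot].length,
                    evalue=10.0 ** cfg.log10e_self))
            # A side maps to the MP itself
            proteome_hits.add(AlignmentHit(
                query_id=a, subject_id=mp_id,
                identity=min(cfg.identity_positive + rng.normal(0, 0.03), 1.0),
                aligned_length=260,
                evalue=_evalue(rng, cfg.log10e_positive, cfg.e_noise_sd)))
            # true partner: strong homolog of B
            partner = f"P{mi}_{ti}"
            proteins[partner] = ProteinRecord(id=partner, species="human", length=310)
            proteome_hits.add(AlignmentHit(
                query_id=b, subject_id=partner,
                identity=min(cfg.identity_positive + rng.normal(0, 0.03), 1.0),
                aligned_length=290,
                evalue=_evalue(rng, cfg.log10e_positive + 5, cfg.e_noise_sd)))
            positives.add(frozenset((mp_id, partner)))
            # network support: MP and true partner share neighbors
            hub = f"N{mi}_{ti}"
            edges += [(mp_id, hub), (partner, hub), (mp_id, partner)]

        for di in range(cfg.n_decoys_per_mp):
            ti = di % cfg.n_templates_per_mp
            b = f"B{mi}_{ti}"
            decoy = f"D{mi}_{di}"
            proteins[decoy] = ProteinRecord(id=decoy, species="human", length=305)
            gated = di % 2 == 1
            log10e = cfg.log10e_gated_decoy if gated else cfg.log10e_scored_decoy
            proteome_hits.add(AlignmentHit(
                query_id=b, subject_id=decoy,
                identity=max(cfg.identity_decoy + rng.normal(0, 0.03), 0.05),
                aligned_length=150,
                evalue=_evalue(rng, log10e, cfg.e_noise_sd)))
            negatives.add(frozenset((mp_id, decoy)))

    network = InteractionNetwork.from_edges(edges)
    return InteractomeFixture(
        proteins=proteins, templates=templates, region_hits=region_hits,
        proteome_hits=proteome_hits, distances=dist, network=network,
        positives=positives, negatives=negatives, mps=mps)


# ---------------------------------------------------------------------------
# expression + survival
# ---------------------------------------------------------------------------

@dataclass
class StudyTruth:
    """Ground truth planted into an expression/survival fixture."""

    planted_degs: frozenset[str]
    blocks: list[list[str]]
    betas: dict[str, float]
    target_r: float
    community: Community
    planted_pathway: str


def make_expression_survival_fixture(
        cfg: FixtureConfig,
        planted: bool = True) -> tuple[ExpressionMatrix, SurvivalTable, StudyTruth]:
    """Log2 expression plus proportional-hazards survival.

    Expression is baseline + planted differential-expression shifts +
    latent-factor co-expression blocks + Gaussian noise.  With
    ``planted=False`` all effects are zeroed (a pure null for calibration)
    while keeping the same shapes and seeds.

    Survival times are exponential with log-hazard sum(beta_g * x_g) over
    the prognostic genes (centered expression), censored independently.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    genes = gene_names(cfg)
    tumor_ids = [f"T{i:03d}" for i in range(cfg.n_tumor)]
    normal_ids = [f"N{i:03d}" for i in range(cfg.n_normal)]
    samples = tumor_ids + normal_ids
    n_samples = len(samples)

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    values = mu[:, None] + rng.normal(0, cfg.noise_sd, size=(cfg.n_genes, n_samples))

    blocks: list[list[str]] = []
    betas: dict[str, float] = {}
    planted_degs: frozenset[str] = frozenset()
    if planted:
        loading = np.sqrt(cfg.target_r) * cfg.noise_sd
        resid = np.sqrt(1.0 - cfg.target_r)
        for bi in range(cfg.n_blocks):
            members = genes[bi * cfg.block_size:(bi + 1) * cfg.block_size]
            blocks.append(members)
            factor = rng.normal(0, 1, size=n_samples)
            idx = [genes.index(g) for g in members]
            values[idx, :] = (mu[idx, None]
                              + loading * factor[None, :]
                              + resid * rng.normal(0, cfg.noise_sd,
                                                   size=(len(idx), n_samples)))
        # differential expression: block genes plus scattered extras, tumor only
        deg_list = [g for blk in blocks for g in blk]
        start = cfg.n_blocks * cfg.block_size
        deg_list += genes[start:start + cfg.n_extra_degs]
        planted_degs = frozenset(deg_list)
        idx = [genes.index(g) for g in deg_list]
        signs = np.where(rng.random(len(idx)) < 0.5, 1.0, -1.0)
        values[np.ix_(idx, range(cfg.n_tumor))] += (signs * cfg.delta_log2fc)[:, None]
        prognostic_pool = blocks[0] if blocks else (deg_list if deg_list else genes)
        betas = {g: cfg.beta for g in prognostic_pool[:cfg.n_prognostic]}

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        group=pd.Series(["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal,
                        index=samples))

    # survival over tumor samples
    tumor_vals = expr.values[tumor_ids]
    lp = np.zeros(cfg.n_tumor)
    for g, beta in betas.items():
        x = tumor_vals.loc[g].to_numpy()
        lp += beta * (x - x.mean())
    hazard = cfg.baseline_hazard * np.exp(lp)
    event_t = rng.exponential(1.0 / hazard)
    censor_t = rng.exponential(1.0 / cfg.censor_hazard, size=cfg.n_tumor)
    months = np.minimum(event_t, censor_t)
    months = np.maximum(months, 0.01)
    event = (event_t <= censor_t).astype(int)
    survival = SurvivalTable(table=pd.DataFrame(
        {"patient": tumor_ids, "months": months, "event": event}))

    mp, partners, pathway_genes = _community_layout(cfg)
    truth = StudyTruth(
        planted_degs=planted_degs, blocks=blocks, betas=betas,
        target_r=cfg.target_r,
        community=Community(mp=mp, partners=frozenset(partners)),
        planted_pathway="PATH000")
    return expr, survival, truth


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

def make_pathway_fixture(cfg: FixtureConfig):
    """Overlapping gene sets; PATH000 is planted against the designated
    community (both drawn from the first co-expression block)."""
    from .io_formats import PathwayCollection

    rng = np.random.default_rng(cfg.seed + 2)
    genes = gene_names(cfg)
    _mp, _partners, planted_genes = _community_layout(cfg)
    pathways: dict[str, frozenset[str]] = {
        "PATH000": frozenset(planted_genes)}
    pool = genes[cfg.block_size:]
    for pi in range(1, cfg.n_pathways):
        members = rng.choice(pool, size=min(cfg.pathway_size, len(pool)),
                             replace=False)
        pathways[f"PATH{pi:03d}"] = frozenset(members.tolist())
    cancer_related = frozenset(f"PATH{pi:03d}"
                               for pi in range(min(cfg.n_cancer_related,
                                                   cfg.n_pathways)))
    return PathwayCollection(pathways=pathways, cancer_related=cancer_related)


def make_null_communities(cfg: FixtureConfig, n_communities: int = 20,
                          size: int = 8) -> list[Community]:
    """Random communities with no planted structure (for calibration)."""
    rng = np.random.default_rng(cfg.seed + 3)
    genes = gene_names(cfg)
    out = []
    for i in range(n_communities):
        members = rng.choice(genes, size=size + 1, replace=False).tolist()
        out.append(Community(mp=members[0], partners=frozenset(members[1:])))
    return out
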