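"""Community-regulated pathway networks: enrichment, permutation nulls,
meta-analysis, homogeneity, and pan-cancer network structure.

An MPP community is a membrane protein plus its interaction partners
(reported/direct plus predicted).  Its association with a pathway in one
cancer is scored by the hypergeometric enrichment of co-expressed gene
pairs between the community's differentially expressed members and the
pathway's, against the universe of pairs toward all pathway DEGs:

    P = sum_{i=x}^{n} C(M, i) C(N-M, n-i) / C(N, n)

where n is the number of cross gene pairs between community and pathway
DEGs, x the co-expressed ones among them, and N, M the analogous totals
against the union of all pathway DEG sets.  The involvement score is
-log10(P).  Significance is confirmed by an empirical P from shuffled
communities (partner labels permuted across the pooled partner multiset,
community sizes preserved).  Per-cancer P values are combined across
cancers by Stouffer's unweighted Z-transform, and meta-z matrices feed the
pan-cancer network (degree, hubs, degree exponent) and its hierarchical
clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist
from scipy.special import zeta

from .coexpr_deg import CoexpressionPairSet

logger = logging.getLogger("campnets")

#: floor for p before the normal-quantile transform (keeps z finite)
P_FLOOR = 1e-16
#: pan-cancer enrichment gate on the meta-z
META_Z_GATE = 1.64
#: two-sided prognostic gate
META_Z_TWO_SIDED = 1.96
ENRICH_P_MAX = 0.05
EMPIRICAL_P_MAX = 0.05
HUB_QUANTILE = 0.75


@dataclass(frozen=True)
class Community:
    """A membrane protein with its partner gene set."""

    mp: str
    partners: frozenset[str]

    def __post_init__(self) -> None:
        if self.mp in self.partners:
            raise ValueError(f"MP {self.mp} listed among its own partners")

    @property
    def genes(self) -> frozenset[str]:
        return self.partners | {self.mp}

    def involved_genes(self, degs: frozenset[str]) -> frozenset[str]:
        """The community's differentially expressed members in one cancer."""
        return self.genes & degs


@dataclass
class EnrichmentResult:
    """One community-pathway-cancer enrichment record."""

    community: str
    pathway: str
    x: int
    n: int
    M: int
    N: int
    p: float
    involvement: float
    empirical_p: float | None = None
    z: float | None = None
    unevaluable: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.x <= self.n <= self.N and self.x <= self.M <= self.N):
            raise ValueError(
                f"inconsistent counts x={self.x} n={self.n} M={self.M} N={self.N}")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p={self.p} outside (0,1]")

    @property
    def significant(self) -> bool:
        ok = self.p <= ENRICH_P_MAX and not self.unevaluable
        if self.empirical_p is not None:
            ok = ok and self.empirical_p <= EMPIRICAL_P_MAX
        return ok


def _cross_pair_counts(involved: frozenset[str], targets: frozenset[str],
                       coexpr: CoexpressionPairSet,
                       exclude_identical: bool = True) -> tuple[int, int]:
    """(co-expressed, total) cross pairs between two gene sets.

    Identical-gene pairs (a gene present on both sides) are excluded from
    both counts by default.
    """
    n = len(involved) * len(targets)
    if exclude_identical:
        n -= len(involved & targets)
    nbrs = coexpr.neighbors
    x = sum(len(nbrs.get(g, frozenset()) & targets) for g in involved)
    # pairs with both endpoints in the intersection were counted from both
    # sides; fold them back to one count each
    both = involved & targets
    if both:
        x -= sum(len(nbrs.get(g, frozenset()) & both) for g in both) // 2
    return x, n


def hypergeom_tail(x: int, n: int, M: int, N: int) -> float:
    """Upper-tail hypergeometric probability sum_{i=x}^{n} pmf(i; N, M, n)."""
    if n == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, M, n))


def enrichment(community: Community,
               pathway: str,
               pathway_genes: frozenset[str],
               degs: frozenset[str],
               coexpr: CoexpressionPairSet,
               all_pathway_genes: frozenset[str],
               exclude_identical: bool = True) -> EnrichmentResult:
    """Hypergeometric enrichment of one community against one pathway.

    ``all_pathway_genes`` is the union of the gene sets of all pathways in
    the collection (the universe for M and N).  A community or pathway
    with no DEG members yields an unevaluable result with n = 0, p = 1.
    """
    involved = community.involved_genes(degs)
    pathway_degs = pathway_genes & degs
    universe_degs = all_pathway_genes & degs
    x, n = _cross_pair_counts(involved, pathway_degs, coexpr, exclude_identical)
    M, N = _cross_pair_counts(involved, universe_degs, coexpr, exclude_identical)
    if n == 0 or not involved:
        return EnrichmentResult(community=community.mp, pathway=pathway,
                                x=0, n=0, M=M, N=max(N, 0), p=1.0,
                                involvement=0.0, unevaluable=True)
    p = hypergeom_tail(x, n, M, N)
    return EnrichmentResult(community=community.mp, pathway=pathway,
                            x=x, n=n, M=M, N=N, p=p,
                            involvement=float(-np.log10(p)))


def _involvement_of(genes: frozenset[str], pathway_degs: frozenset[str],
                    universe_degs: frozenset[str], degs: frozenset[str],
                    coexpr: CoexpressionPairSet,
                    exclude_identical: bool) -> float:
    involved = genes & degs
    x, n = _cross_pair_counts(involved, pathway_degs, coexpr, exclude_identical)
    if n == 0:
        return 0.0
    M, N = _cross_pair_counts(involved, universe_degs, coexpr, exclude_identical)
    return float(-np.log10(hypergeom_tail(x, n, M, N)))


def empirical_p(community: Community,
                pathway_genes: frozenset[str],
                all_communities: Sequence[Community],
                degs: frozenset[str],
                coexpr: CoexpressionPairSet,
                all_pathway_genes: frozenset[str],
                B: int = 1000,
                seed: int | np.random.Generator = 0,
                exclude_identical: bool = True) -> float:
    """Permutation P for one community-pathway involvement.

    Each trial redraws the community's partners (without replacement, size
    preserved) from the pooled partner multiset of all communities, and
    recomputes the involvement.  Reported with the add-one convention
    (1 + #{shuffled >= observed}) / (B + 1), so never exactly zero.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pool = np.array(sorted(p for c in all_communities for p in c.partners))
    size = len(community.partners)
    if len(pool) < size:
        raise ValueError(
            f"pooled partner multiset ({len(pool)}) smaller than community ({size})")
    pathway_degs = pathway_genes & degs
    universe_degs = all_pathway_genes & degs
    observed = _involvement_of(community.genes, pathway_degs, universe_degs,
                               degs, coexpr, exclude_identical)
    hits = 0
    for _ in range(B):
        drawn = rng.choice(pool, size=size, replace=False)
        genes = frozenset(drawn) | {community.mp}
        shuffled = _involvement_of(genes, pathway_degs, universe_degs,
                                   degs, coexpr, exclude_identical)
        if shuffled >= observed:
            hits += 1
    return (1 + hits) / (B + 1)


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

def meta_z(p_values: Sequence[float], p_floor: float = P_FLOOR) -> float:
    """Stouffer's unweighted Z-transform of one-sided P values.

    Each p is floored at ``p_floor``, transformed to z = Phi^-1(1 - p),
    and combined as sum(z) / sqrt(k).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p values must lie in (0, 1)")
    z = stats.norm.isf(np.maximum(p, p_floor))
    return float(z.sum() / np.sqrt(p.size))


def stouffer_z(z_values: Sequence[float]) -> float:
    """Stouffer combination of z-scores: sum(z) / sqrt(k)."""
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ValueError("empty z vector")
    if not np.all(np.isfinite(z)):
        raise ValueError("z values must be finite")
    return float(z.sum() / np.sqrt(z.size))


@dataclass
class MetaZRecord:
    """Per-cancer z-scores and their Stouffer combination for one
    community-pathway association."""

    community: str
    pathway: str
    z_by_cancer: dict[str, float]

    @property
    def meta_z(self) -> float:
        return stouffer_z(list(self.z_by_cancer.values()))

    @property
    def k(self) -> int:
        return len(self.z_by_cancer)


def meta_z_matrix(results: Iterable[EnrichmentResult],
                  cancer_of: Mapping[int, str] | None = None) -> pd.DataFrame:
    """Build a community x pathway meta-z matrix from per-cancer results.

    ``results`` may simply be a flat iterable where each element carries a
    ``cancer`` attribute (set by the pipeline) or the mapping index ->
    cancer is supplied.  Cells with no defined z are NaN.
    """
    records: dict[tuple[str, str], list[float]] = {}
    for i, r in enumerate(results):
        if r.unevaluable:
            continue
        cancer = getattr(r, "cancer", None)
        if cancer is None and cancer_of is not None:
            cancer = cancer_of[i]
        z = float(stats.norm.isf(max(r.p, P_FLOOR)))
        records.setdefault((r.community, r.pathway), []).append(z)
    rows: dict[str, dict[str, float]] = {}
    for (community, pathway), zs in records.items():
        rows.setdefault(community, {})[pathway] = stouffer_z(zs)
    return pd.DataFrame(rows).T.sort_index()


def global_meta_z(meta_z_values: Sequence[float]) -> float:
    """Second-level Stouffer combination of meta-z values."""
    return stouffer_z(meta_z_values)


# ---------------------------------------------------------------------------
# homogeneity across cancers
# ---------------------------------------------------------------------------

def _shared_fraction(sig: pd.DataFrame, k: int) -> pd.Series:
    """Per pathway: fraction of communities significant in >= k cancers.

    ``sig`` is a boolean DataFrame indexed by (cancer, community) with
    pathway columns.
    """
    counts = sig.groupby(level="community").sum()  # community x pathway cancer counts
    return (counts >= k).sum(axis=0) / counts.shape[0]


def homogeneity(results_by_cancer: Mapping[str, Sequence[EnrichmentResult]],
                ks: Sequence[int] = (2, 3, 5, 7, 9),
                B: int = 1000,
                enrich_p_cutoff: float = ENRICH_P_MAX,
                empirical_p_cutoff: float = EMPIRICAL_P_MAX,
                pathways: Sequence[str] | None = None,
                seed: int | np.random.Generator = 0) -> dict:
    """Observed vs expected fractions of pathways shared across cancers.

    For each pathway and sharing threshold k, the observed statistic is
    the fraction of communities regulating it (enrichment p <= cutoff and
    empirical p <= cutoff) in at least k cancers.  Expected fractions are
    medians over B null sets obtained by permuting, within each cancer and
    pathway, the significance indicators across communities (preserving
    per-cancer per-pathway significant-call counts).  A paired Wilcoxon
    signed-rank test compares observed and expected fractions over the
    pathway panel at each k.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cancers = sorted(results_by_cancer)
    if pathways is None:
        pathways = sorted({r.pathway for rs in results_by_cancer.values() for r in rs})
    communities = sorted({r.community for rs in results_by_cancer.values() for r in rs})
    if max(ks) > len(cancers):
        raise ValueError(f"sharing threshold {max(ks)} exceeds cancer count {len(cancers)}")

    sig = np.zeros((len(cancers), len(communities), len(pathways)), dtype=bool)
    c_idx = {c: i for i, c in enumerate(cancers)}
    m_idx = {m: i for i, m in enumerate(communities)}
    p_idx = {p: i for i, p in enumerate(pathways)}
    for cancer, rs in results_by_cancer.items():
        for r in rs:
            if r.pathway not in p_idx or r.unevaluable:
                continue
            ok = r.p <= enrich_p_cutoff
            if r.empirical_p is not None:
                ok = ok and r.empirical_p <= empirical_p_cutoff
            sig[c_idx[cancer], m_idx[r.community], p_idx[r.pathway]] = ok

    def fractions(mat: np.ndarray) -> dict[int, np.ndarray]:
        counts = mat.sum(axis=0)  # community x pathway: number of cancers
        return {k: (counts >= k).mean(axis=0) for k in ks}

    observed = fractions(sig)
    null_samples = {k: np.empty((B, len(pathways))) for k in ks}
    for b in range(B):
        shuffled = np.empty_like(sig)
        for ci in range(len(cancers)):
            for pi in range(len(pathways)):
                shuffled[ci, :, pi] = rng.permutation(sig[ci, :, pi])
        fr = fractions(shuffled)
        for k in ks:
            null_samples[k][b] = fr[k]
    expected = {k: np.median(null_samples[k], axis=0) for k in ks}

    wilcoxon_p: dict[int, float] = {}
    for k in ks:
        diff = observed[k] - expected[k]
        if np.allclose(diff, 0):
            wilcoxon_p[k] = 1.0
        else:
            wilcoxon_p[k] = float(stats.wilcoxon(
                observed[k], expected[k], zero_method="wilcox",
                alternative="greater").pvalue)
    return {
        "pathways": list(pathways),
        "observed": {k: observed[k].tolist() for k in ks},
        "expected": {k: expected[k].tolist() for k in ks},
        "wilcoxon_p": wilcoxon_p,
    }


# ---------------------------------------------------------------------------
# pan-cancer network structure
# ---------------------------------------------------------------------------

def fit_power_law_gamma(degrees: Sequence[int], x_min: int = 1,
                        method: str = "mle") -> float:
    """Degree exponent of a discrete power law P(k) ~ k^-gamma, k >= x_min.

    ``mle`` maximizes the zeta-normalized likelihood; ``ls`` fits a
    log-log least-squares line to the degree histogram (for comparison).
    """
    k = np.asarray([d for d in degrees if d >= x_min], dtype=float)
    if k.size == 0:
        raise ValueError("no degrees >= x_min")
    if method == "ls":
        values, counts = np.unique(k, return_counts=True)
        slope, _ = np.polyfit(np.log10(values), np.log10(counts / counts.sum()), 1)
        return float(-slope)
    if method != "mle":
        raise ValueError(f"unknown method {method!r}")
    log_sum = np.log(k).sum()
    res = minimize_scalar(lambda g: k.size * np.log(zeta(g, x_min)) + g * log_sum,
                          bounds=(1.01, 10.0), method="bounded")
    return float(res.x)


def network_stats(meta_z_mat: pd.DataFrame,
                  gate: float = META_Z_GATE,
                  hub_quantile: float = HUB_QUANTILE,
                  gamma_method: str = "mle") -> dict:
    """Degree, mean meta-z, hubs, and degree exponent of the pan-cancer net.

    The matrix (communities x pathways) is filtered at meta-z > gate; a
    community's degree is its number of passing pathways and its mean
    meta-z the passing sum divided by the degree.  Hubs are communities in
    the top quartile of degree; the exponent gamma is fit to the nonzero
    degree sequence (undefined when every degree is zero).
    """
    passing = meta_z_mat.where(meta_z_mat > gate)
    degree = passing.notna().sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_meta_z = passing.sum(axis=1) / degree.replace(0, np.nan)
    nonzero = degree[degree > 0]
    if nonzero.empty:
        gamma = None
        hubs: list[str] = []
    else:
        cut = degree.quantile(hub_quantile)
        hubs = sorted(degree.index[degree >= max(cut, 1)])
        gamma = fit_power_law_gamma(nonzero.to_numpy(), method=gamma_method)
    return {"degree": degree, "mean_meta_z": mean_meta_z,
            "hubs": hubs, "gamma": gamma}


def cluster_meta_z(meta_z_mat: pd.DataFrame,
                   n_clusters: int = 4,
                   cut_height: float | None = None) -> dict:
    """Average-linkage hierarchical clustering with correlation distance.

    Distance between community rows is 1 - Pearson r.  Constant rows have
    no defined correlation and are dropped with a warning.  Clusters come
    from cutting the dendrogram at ``cut_height``, or into ``n_clusters``
    groups when no height is given.
    """
    mat = meta_z_mat.fillna(0.0)
    constant = mat.index[mat.std(axis=1, ddof=0) == 0]
    if len(constant):
        logger.warning("cluster_meta_z: dropping %d constant rows", len(constant))
        mat = mat.drop(index=constant)
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 non-constant communities to cluster")
    dist = pdist(mat.to_numpy(), metric="correlation")
    linkage = average(dist)
    if cut_height is not None:
        labels = fcluster(linkage, t=cut_height, criterion="distance")
    else:
        labels = fcluster(linkage, t=n_clusters, criterion="maxclust")
    return {"labels": pd.Series(labels, index=mat.index, name="cluster"),
            "linkage": linkage, "dropped": list(constant)}
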