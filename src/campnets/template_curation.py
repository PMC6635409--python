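"""Curation of PPI templates: evidence counting, the direct-PPI reliability
filter, the RSS-based negative set, and the per-MP leave-out rule.

A template is one curated interaction record annotated with PSI-MI
detection-method and interaction-type codes plus PubMed references.  Each
experimental detection method carries a reliability score from 0 (lowest
confidence, e.g. genetic interference) to 10 (highest, e.g. X-ray
crystallography); high-throughput screens score at most 5.  Direct physical
templates are those annotated under experimental interaction detection
(MI:0045) and direct interaction (MI:0407) whose representative method
scores sum to at least 6 — a single high-throughput screen never suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .io_formats import RawInteraction, ValidationError

MI_EXPERIMENTAL = "MI:0045"   # experimental interaction detection
MI_DIRECT = "MI:0407"         # direct interaction

#: Raw evidence counts saturate here (more evidence adds no further quality).
EVIDENCE_CAP = 2


@dataclass(frozen=True)
class PPITemplate:
    """A curated interaction record used as an interolog template."""

    protein_a: str
    protein_b: str
    species: tuple[str, ...]
    detection_methods: frozenset[str] = frozenset()
    interaction_types: frozenset[str] = frozenset()
    references: frozenset[str] = frozenset()

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.protein_a, self.protein_b))

    @classmethod
    def from_raw(cls, raw: RawInteraction) -> "PPITemplate":
        return cls(protein_a=raw.protein_a, protein_b=raw.protein_b,
                   species=raw.species, detection_methods=raw.detection_methods,
                   interaction_types=raw.interaction_types,
                   references=raw.references)


@dataclass
class ReliabilityMap:
    """Per-MI-term reliability scores with parent-link inheritance.

    A term without an assigned score inherits the score of its nearest
    scored ancestor.  The parent structure must be acyclic.
    """

    scores: dict[str, int] = field(default_factory=dict)
    parents: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, score in self.scores.items():
            if not 0 <= score <= 10:
                raise ValidationError(f"reliability score {score} for {code} outside [0,10]")
        for child in self.parents:
            seen = {child}
            node = child
            while node in self.parents:
                node = self.parents[node]
                if node in seen:
                    raise ValidationError(f"cycle in MI parent links at {node}")
                seen.add(node)

    def score(self, code: str) -> int:
        """Resolve a score, walking parent links for unscored terms."""
        node: str | None = code
        while node is not None:
            if node in self.scores:
                return self.scores[node]
            node = self.parents.get(node)
        raise ValidationError(f"unresolvable MI code {code!r} (no score on any ancestor)")

    def is_descendant(self, code: str, ancestor: str) -> bool:
        """True if ``code`` equals ``ancestor`` or lies below it."""
        node: str | None = code
        while node is not None:
            if node == ancestor:
                return True
            node = self.parents.get(node)
        return False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReliabilityMap":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(scores=dict(data.get("mi_scores", {})),
                   parents=dict(data.get("mi_parents", {})))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"mi_scores": dict(self.scores),
                            "mi_parents": dict(self.parents)}, fh)


@dataclass(frozen=True)
class RSSRecord:
    """GO-derived relative specificity similarities for a protein pair."""

    pair: frozenset[str]
    rss_bp: float | None = None
    rss_cc: float | None = None

    def __post_init__(self) -> None:
        for v in (self.rss_bp, self.rss_cc):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"RSS value {v} outside [0,1]")


def representative_terms(codes: Iterable[str], rmap: ReliabilityMap) -> frozenset[str]:
    """Drop any term that is a strict ancestor of another term in the set.

    When one term is a subclass of another, the child is the
    representative and the parent is not counted.
    """
    codes = set(codes)
    keep = set()
    for c in codes:
        if any(other != c and rmap.is_descendant(other, c) for other in codes):
            continue
        keep.add(c)
    return frozenset(keep)


def count_evidence(template: PPITemplate,
                   rmap: ReliabilityMap | None = None) -> tuple[int, int, int]:
    """Capped evidence counts (x_m, x_t, x_r) for a template.

    Counts of detection methods, interaction types, and references each
    saturate at :data:`EVIDENCE_CAP`.  With a reliability map, the
    representative-term rule collapses parent/child MI pairs first.
    """
    methods = template.detection_methods
    types = template.interaction_types
    if rmap is not None:
        methods = representative_terms(methods, rmap)
        types = representative_terms(types, rmap)
    cap = EVIDENCE_CAP
    return (min(len(methods), cap), min(len(types), cap),
            min(len(template.references), cap))


def select_direct_templates(templates: Iterable[PPITemplate],
                            rmap: ReliabilityMap,
                            min_score_sum: int = 6) -> set[PPITemplate]:
    """Filter templates down to well-evidenced direct physical interactions.

    A template is kept iff (a) it has at least one detection method under
    experimental interaction detection (MI:0045); (b) at least one
    interaction type is direct interaction (MI:0407) or a descendant; and
    (c) the reliability scores of its representative experimental methods
    sum to at least ``min_score_sum``.
    """
    kept: set[PPITemplate] = set()
    for t in templates:
        experimental = {m for m in t.detection_methods
                        if rmap.is_descendant(m, MI_EXPERIMENTAL)}
        if not experimental:
            continue
        if not any(rmap.is_descendant(ty, MI_DIRECT) for ty in t.interaction_types):
            continue
        reps = representative_terms(experimental, rmap)
        if sum(rmap.score(m) for m in reps) < min_score_sum:
            continue
        kept.add(t)
    return kept


def build_negative_set(candidate_pairs: Iterable[frozenset[str]],
                       rss_records: Mapping[frozenset[str], RSSRecord],
                       reported_pairs: Iterable[frozenset[str]],
                       mode: str = "or",
                       cutoff: float = 0.4) -> set[frozenset[str]]:
    """Select negative pairs by low GO relative specificity similarity.

    A candidate pair is negative iff it is not a reported interaction and
    its RSS values satisfy the mode-combined ``< cutoff`` condition
    (``or``: either below; ``and``: both below).  Pairs missing either
    RSS value are excluded.
    """
    if mode not in ("or", "and"):
        raise ValueError(f"mode must be 'or' or 'and', got {mode!r}")
    reported = set(reported_pairs)
    negatives: set[frozenset[str]] = set()
    for pair in candidate_pairs:
        if pair in reported:
            continue
        rec = rss_records.get(pair)
        if rec is None or rec.rss_bp is None or rec.rss_cc is None:
            continue
        below_bp = rec.rss_bp < cutoff
        below_cc = rec.rss_cc < cutoff
        negative = (below_bp or below_cc) if mode == "or" else (below_bp and below_cc)
        if negative:
            negatives.add(pair)
    return negatives


def exclude_self_templates(mp: str,
                           templates: Iterable[PPITemplate]) -> set[PPITemplate]:
    """Drop every template involving the query MP itself.

    Applied before template selection so a protein's own reported
    interactions never serve as its prediction templates.
    """
    return {t for t in templates if mp not in t.pair}


def default_reliability_map() -> ReliabilityMap:
    """A small editable reliability map seeded with the anchor scores.

    Crystallography scores 10, genetic interference 0, high-throughput
    screens at most 5; remaining terms carry mid-range scores and inherit
    through the MI parent links.
    """
    scores = {
        MI_EXPERIMENTAL: 5,      # fallback for unscored experimental children
        "MI:0114": 10,           # x-ray crystallography
        "MI:0208": 0,            # genetic interference
        "MI:0018": 4,            # two-hybrid (high-throughput <= 5)
        "MI:0019": 5,            # coimmunoprecipitation
        "MI:0006": 5,            # anti-bait coip
        "MI:0096": 5,            # pull down
        "MI:0416": 6,            # fluorescence microscopy
        "MI:0055": 7,            # fluorescent resonance energy transfer
        "MI:0943": 5,            # detection by mass spectrometry
        "MI:0071": 8,            # molecular sieving
        "MI:0077": 9,            # nmr
    }
    parents = {
        "MI:0114": MI_EXPERIMENTAL,
        "MI:0208": MI_EXPERIMENTAL,
        "MI:0018": MI_EXPERIMENTAL,
        "MI:0019": MI_EXPERIMENTAL,
        "MI:0006": "MI:0019",
        "MI:0096": MI_EXPERIMENTAL,
        "MI:0416": MI_EXPERIMENTAL,
        "MI:0055": "MI:0416",
        "MI:0943": MI_EXPERIMENTAL,
        "MI:0071": MI_EXPERIMENTAL,
        "MI:0077": MI_EXPERIMENTAL,
        # interaction types
        "MI:0195": MI_DIRECT,    # covalent binding
        "MI:0407": "MI:0915",    # direct interaction under physical association
        "MI:0915": "MI:0190",
    }
    return ReliabilityMap(scores=scores, parents=parents)
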