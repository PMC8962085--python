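"""HPO semantic similarity between a patient and disease profiles.

The score is an asymmetric best-match average of Lin term similarity,
scaled to [0, 10]: for each patient term the best-matching disease-profile
term is found, the term-pair Lin similarities are averaged, and the mean is
multiplied by 10.  A score >= 5 (i.e. mean term-level similarity >= 0.5)
flags a candidate disease for review.

Information content uses add-one smoothing over the disease corpus,
IC(t) = -ln((n_t + 1) / (N + 1)) with n_t the number of distinct diseases
annotated to t or any of its descendants, so the root of a fully annotated
corpus has IC 0 and leaves stay finite on tiny toy corpora.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TYPE_CHECKING

import networkx as nx
import obonet

from .config import EmptyPhenotypeError, SchemaError, UnknownTermError

if TYPE_CHECKING:  # pragma: no cover
    from .knowledge_base import GeneDiseaseEntry, Snapshot

logger = logging.getLogger(__name__)


class Ontology:
    """A DAG of phenotype terms with disease annotations.

    ``graph`` holds child->parent edges (so graph-descendants of a node are
    its ontological ancestors).  Annotations are disease -> set of terms;
    they are propagated to ancestors once, so each term knows the distinct
    diseases annotated in its subtree.
    """

    def __init__(
        self,
        graph: nx.DiGraph,
        annotations: Mapping[str, Iterable[str]] | None = None,
    ) -> None:
        if not nx.is_directed_acyclic_graph(graph):
            raise SchemaError("ontology graph contains a cycle")
        roots = [n for n in graph.nodes if graph.out_degree(n) == 0]
        if len(roots) != 1:
            raise SchemaError(f"ontology must have a single root, found {len(roots)}")
        self.graph = graph
        self.root: str = roots[0]
        self._diseases_at: dict[str, set[str]] = {t: set() for t in graph.nodes}
        self.diseases: dict[str, frozenset[str]] = {}
        for disease_id, terms in (annotations or {}).items():
            known = {t for t in terms if t in graph}
            missing = set(terms) - known
            if missing:
                raise SchemaError(
                    f"disease {disease_id}: annotated to unknown terms {sorted(missing)}"
                )
            self.diseases[disease_id] = frozenset(known)
            for t in known:
                self._diseases_at[t].add(disease_id)
                for anc in nx.descendants(graph, t):  # ontological ancestors
                    self._diseases_at[anc].add(disease_id)
        self.total_diseases = len(self.diseases)
        self.annotation_counts: dict[str, int] = {
            t: len(d) for t, d in self._diseases_at.items()
        }
        self._ic_cache: dict[str, float] = {}
        self._anc_cache: dict[str, frozenset[str]] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def ancestors(self, term: str) -> frozenset[str]:
        """The term itself plus all its ontological ancestors."""
        cached = self._anc_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term)) | {term}
            self._anc_cache[term] = cached
        return cached

    def information_content(self, term: str) -> float:
        if term not in self.graph:
            raise UnknownTermError(f"term {term!r} not in ontology")
        ic = self._ic_cache.get(term)
        if ic is None:
            n_t = self.annotation_counts[term]
            ic = -math.log((n_t + 1) / (self.total_diseases + 1))
            self._ic_cache[term] = ic
        return ic


def information_content(term: str, ontology: Ontology) -> float:
    """IC(t) = -ln((n_t + 1) / (N + 1)); 0 at a root covering all diseases."""
    return ontology.information_content(term)


def lin_similarity(a: str, b: str, ontology: Ontology) -> float:
    """Lin measure 2*IC(MICA)/(IC(a)+IC(b)); 0 when both ICs are 0."""
    ic_a = ontology.information_content(a)
    ic_b = ontology.information_content(b)
    if ic_a + ic_b == 0.0:
        return 0.0
    common = ontology.ancestors(a) & ontology.ancestors(b)
    ic_mica = max(ontology.information_content(t) for t in common)
    return 2.0 * ic_mica / (ic_a + ic_b)


@dataclass
class SimilarityResult:
    score: float
    per_term_best_matches: dict[str, tuple[str, float]] = field(default_factory=dict)
    dropped_terms: tuple[str, ...] = ()

    def flagged(self, threshold: float = 5.0) -> bool:
        return self.score >= threshold


def similarity_score(
    patient_terms: Iterable[str],
    disease_profile: Iterable[str],
    ontology: Ontology,
) -> SimilarityResult:
    """Asymmetric best-match average Lin similarity, scaled to [0, 10].

    Unknown terms on either side are dropped with a warning; an empty
    patient set after dropping raises :class:`EmptyPhenotypeError`.
    """
    patient = sorted(set(patient_terms))
    profile = sorted(set(disease_profile))
    dropped = tuple(t for t in patient + profile if t not in ontology)
    if dropped:
        logger.warning("dropping unknown ontology terms: %s", sorted(set(dropped)))
    patient = [t for t in patient if t in ontology]
    profile = [t for t in profile if t in ontology]
    if not patient:
        raise EmptyPhenotypeError("no known patient phenotype terms")
    if not profile:
        raise EmptyPhenotypeError("no known disease profile terms")

    matches: dict[str, tuple[str, float]] = {}
    for t in patient:
        best_term, best_sim = profile[0], -1.0
        for d in profile:
            sim = lin_similarity(t, d, ontology)
            if sim > best_sim:
                best_term, best_sim = d, sim
        matches[t] = (best_term, best_sim)
    score = 10.0 * sum(sim for _, sim in matches.values()) / len(matches)
    return SimilarityResult(
        score=score, per_term_best_matches=matches, dropped_terms=dropped
    )


def best_disease_matches(
    patient_terms: Iterable[str],
    snapshot: "Snapshot",
    ontology: Ontology,
    k: int = 10,
) -> list[tuple["GeneDiseaseEntry", float]]:
    """Rank snapshot entries by similarity to the patient, descending.

    Ties break by disease_id ascending; the top ``k`` are returned.
    Entries whose profile has no known terms are skipped.
    """
    scored: list[tuple["GeneDiseaseEntry", float]] = []
    for entry in snapshot.entries.values():
        try:
            result = similarity_score(patient_terms, entry.hpo_profile, ontology)
        except EmptyPhenotypeError:
            continue
        scored.append((entry, result.score))
    scored.sort(key=lambda pair: (-pair[1], pair[0].disease_id))
    return scored[: max(k, 0)]


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def load_ontology(
    obo_path: str | Path, corpus_path: str | Path | None = None
) -> Ontology:
    """Read an OBO file (is_a edges only) and an optional disease-corpus TSV.

    The corpus sidecar has two tab-separated columns: disease_id and a
    ';'-joined list of term ids ('#' lines are comments).
    """
    multigraph = obonet.read_obo(str(obo_path))
    graph = nx.DiGraph()
    graph.add_nodes_from(multigraph.nodes)
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    annotations = load_corpus(corpus_path) if corpus_path else {}
    return Ontology(graph, annotations)


def load_corpus(path: str | Path) -> dict[str, frozenset[str]]:
    annotations: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SchemaError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        disease_id, terms = parts
        annotations[disease_id.strip()] = frozenset(
            t.strip() for t in terms.split(";") if t.strip()
        )
    return annotations
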