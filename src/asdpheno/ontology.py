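"""Five-level phenotype ontology assembly, validation and serialization.

Structure (single ``is_a`` hierarchy in the OBO Foundry style):

- level 1: the unique root, labeled "ASD";
- level 2: three domain nodes — "social interaction" (criterion A),
  "repetitive behavior" (criterion B), "ASD and comorbidities" (E);
- level 3: the DSM-5 sub-criteria A1-A3, B1-B4 and E;
- level 4: descriptor phrases of each criterion (the packaged, replaceable
  guideline-phrase fixture);
- level 5: the validated terminology, each term attached to the level-4
  phrase it scored highest against (many-to-many links allowed; every link
  spans exactly one level).

Terminology nodes carry the CUI, a UMLS standard name, semantic types, the
DSM-5 category, and both case-control odds ratios. Output formats: RDF/XML
and OWL2 (rdflib; loadable by standard ontology editors) and a canonical
JSON schema documented by ``serialize``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from rdflib import OWL, RDF, RDFS, Graph, Literal, Namespace, URIRef

from .dsm5 import CRITERIA, DISPLAY_NAMES, CriterionLexicon
from .embedding import EmbeddingProvider, TrigramHashEmbedding, cosine
from .validation import ValidatedTerm

NS = Namespace("http://purl.example.org/asd-phenotype#")

ROOT_ID = "ASD"
DOMAIN_IDS = {"A": "domain_A", "B": "domain_B", "E": "domain_E"}
DOMAIN_LABELS = {
    "domain_A": "social interaction",
    "domain_B": "repetitive behavior",
    "domain_E": "ASD and comorbidities",
}
LEVEL2_LABELS = set(DOMAIN_LABELS.values())


@dataclass
class OntologyNode:
    node_id: str
    label: str
    level: int
    parents: tuple[str, ...] = ()
    cui: str | None = None
    umls_name: str | None = None
    semantic_types: frozenset[str] = frozenset()
    dsm5_category: str | None = None
    or_vs_nonpsych: float | None = None
    or_vs_psych: float | None = None
    extras: dict[str, str] = field(default_factory=dict)


@dataclass
class Ontology:
    """Node table plus child->parent ``is_a`` edges and build metadata."""

    nodes: dict[str, OntologyNode]
    metadata: dict = field(default_factory=dict)

    def children(self, node_id: str) -> list[str]:
        return [n.node_id for n in self.nodes.values() if node_id in n.parents]

    def descendants(self, node_id: str) -> set[str]:
        out: set[str] = set()
        stack = [node_id]
        while stack:
            for c in self.children(stack.pop()):
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    def level_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for n in self.nodes.values():
            counts[n.level] = counts.get(n.level, 0) + 1
        return dict(sorted(counts.items()))

    def criteria_for_cui(self, cui: str) -> set[str]:
        """DSM-5 criteria whose subtree contains a terminology node with ``cui``."""
        crits: set[str] = set()
        for n in self.nodes.values():
            if n.level == 5 and n.cui == cui and n.dsm5_category:
                crits.add(n.dsm5_category)
        return crits


def build_ontology(
    validated_terms: Sequence[ValidatedTerm],
    criterion_mappings: pd.DataFrame,
    term_stats: pd.DataFrame,
    lexicons: Sequence[CriterionLexicon],
    provider: EmbeddingProvider | None = None,
    metadata: Mapping | None = None,
) -> Ontology:
    """Assemble the 5-level ontology.

    ``criterion_mappings`` must cover every validated term (``term_key``
    column keyed by CUI, plus ``criterion``); ``term_stats`` supplies the
    odds ratios and surface/semantic-type information. Each terminology
    node is attached to the level-4 phrase of its criterion that it scores
    highest against in embedding space.
    """
    if provider is None:
        provider = TrigramHashEmbedding()
    nodes: dict[str, OntologyNode] = {}
    nodes[ROOT_ID] = OntologyNode(ROOT_ID, "ASD", 1)
    for dom, nid in DOMAIN_IDS.items():
        nodes[nid] = OntologyNode(nid, DOMAIN_LABELS[nid], 2, parents=(ROOT_ID,))
    lex_by_crit = {lex.criterion: lex for lex in lexicons}
    phrase_ids: dict[str, dict[str, str]] = {}
    counter = 0
    for crit in CRITERIA:
        if crit not in lex_by_crit:
            continue
        domain = DOMAIN_IDS[crit[0]] if crit[0] in ("A", "B") else DOMAIN_IDS["E"]
        crit_id = f"crit_{crit}"
        nodes[crit_id] = OntologyNode(
            crit_id, DISPLAY_NAMES[crit], 3, parents=(domain,), dsm5_category=crit
        )
        phrase_ids[crit] = {}
        for phrase in lex_by_crit[crit].phrases:
            counter += 1
            pid = f"phrase_{counter:04d}"
            nodes[pid] = OntologyNode(pid, phrase, 4, parents=(crit_id,), dsm5_category=crit)
            phrase_ids[crit][phrase] = pid

    mapping = criterion_mappings.set_index("term_key")
    stats = term_stats.set_index("cui") if len(term_stats) else None
    missing = [t.term_id for t in validated_terms
               if (t.cui or t.surface_form) not in mapping.index]
    if missing:
        raise ValueError(f"validated terms without a criterion mapping: {missing}")
    for t in validated_terms:
        key = t.cui or t.surface_form
        crit = mapping.loc[key, "criterion"]
        if isinstance(crit, pd.Series):
            crit = crit.iloc[0]
        if not crit or crit not in phrase_ids:
            raise ValueError(f"term {t.term_id} maps to unknown criterion {crit!r}")
        vec = provider.embed(t.surface_form)
        scored = [
            (cosine(vec, provider.embed(ph)), pid)
            for ph, pid in phrase_ids[crit].items()
        ]
        best = max(s for s, _ in scored)
        parents = tuple(pid for s, pid in scored if s >= best - 1e-12)
        kwargs: dict = {"semantic_types": frozenset()}
        if stats is not None and t.cui in stats.index:
            row = stats.loc[t.cui]
            kwargs = {
                "umls_name": str(row.get("surface_form", t.surface_form)),
                "semantic_types": frozenset(
                    x for x in str(row.get("tuis", "")).split("|") if x
                ),
                "or_vs_nonpsych": float(row["or_vs_nonpsych"]),
                "or_vs_psych": float(row["or_vs_psych"]),
            }
        nodes[t.term_id] = OntologyNode(
            t.term_id, t.surface_form, 5, parents=parents,
            cui=t.cui, dsm5_category=crit, **kwargs,
        )
    meta = {"n_terms": len(validated_terms), **(dict(metadata) if metadata else {})}
    onto = Ontology(nodes=nodes, metadata=meta)
    onto.metadata["level_counts"] = onto.level_counts()
    return onto


def validate_ontology(ontology: Ontology) -> list[str]:
    """Check the structural invariants; returns a list of violations."""
    violations: list[str] = []
    roots = [n for n in ontology.nodes.values() if n.level == 1]
    if len(roots) != 1 or roots[0].label != "ASD":
        violations.append("root: expected a unique level-1 node labeled 'ASD'")
    level2 = [n for n in ontology.nodes.values() if n.level == 2]
    if len(level2) != 3 or {n.label for n in level2} != LEVEL2_LABELS:
        violations.append(f"level 2: expected the 3 domain nodes, got {[n.label for n in level2]}")
    g = nx.DiGraph()
    g.add_nodes_from(ontology.nodes)
    for n in ontology.nodes.values():
        for p in n.parents:
            if p not in ontology.nodes:
                violations.append(f"{n.node_id}: unknown parent {p}")
                continue
            if ontology.nodes[p].level != n.level - 1:
                violations.append(
                    f"{n.node_id} (level {n.level}): parent {p} is at level "
                    f"{ontology.nodes[p].level}, links must span exactly one level"
                )
            g.add_edge(n.node_id, p)
    if not nx.is_directed_acyclic_graph(g):
        violations.append("cycle detected in is_a hierarchy")
    else:
        root_ids = {n.node_id for n in roots}
        for n in ontology.nodes.values():
            if n.level > 1:
                if not n.parents:
                    violations.append(f"{n.node_id}: non-root node without parents")
                elif not (nx.descendants(g, n.node_id) & root_ids):
                    violations.append(f"{n.node_id}: cannot reach the root")
    for n in ontology.nodes.values():
        if n.level == 5:
            if n.cui is None:
                violations.append(f"{n.node_id}: terminology node without a CUI")
            if n.or_vs_nonpsych is None or n.or_vs_psych is None:
                violations.append(f"{n.node_id}: terminology node without odds ratios")
    if not any(n.level == 5 for n in ontology.nodes.values()):
        violations.append("level 5 is empty (degenerate build)")
    return violations


# --- serialization ---------------------------------------------------------

_ANNOTATIONS = (
    "level", "cui", "umlsName", "semanticType", "dsm5Category",
    "orVsNonpsych", "orVsPsych",
)


def _node_to_json(n: OntologyNode) -> dict:
    d: dict = {"id": n.node_id, "label": n.label, "level": n.level,
               "parents": sorted(n.parents)}
    if n.cui:
        d["cui"] = n.cui
    if n.umls_name:
        d["umls_name"] = n.umls_name
    if n.semantic_types:
        d["semantic_types"] = sorted(n.semantic_types)
    if n.dsm5_category:
        d["dsm5_category"] = n.dsm5_category
    if n.or_vs_nonpsych is not None:
        d["or_vs_nonpsych"] = n.or_vs_nonpsych
    if n.or_vs_psych is not None:
        d["or_vs_psych"] = n.or_vs_psych
    if n.extras:
        d["extras"] = dict(sorted(n.extras.items()))
    return d


def serialize(ontology: Ontology, path: str | Path, format: str = "rdfxml") -> None:
    """Write the ontology: ``rdfxml``, ``owl`` (OWL2 RDF/XML) or ``json``.

    The JSON schema is ``{"metadata": {...}, "nodes": [{id, label, level,
    parents, cui?, umls_name?, semantic_types?, dsm5_category?,
    or_vs_nonpsych?, or_vs_psych?, extras?}, ...]}`` with nodes sorted by
    id and keys sorted — serialize/parse/serialize is byte-stable.
    """
    path = Path(path)
    if format == "json":
        doc = {
            "metadata": ontology.metadata,
            "nodes": [_node_to_json(n) for n in sorted(ontology.nodes.values(),
                                                       key=lambda n: n.node_id)],
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True, default=str) + "\n")
        return
    if format not in ("rdfxml", "owl"):
        raise ValueError(f"unknown format {format!r}")
    g = Graph()
    g.bind("asd", NS)
    g.bind("owl", OWL)
    if format == "owl":
        onto_iri = URIRef(str(NS).rstrip("#"))
        g.add((onto_iri, RDF.type, OWL.Ontology))
        for ann in _ANNOTATIONS:
            g.add((NS[ann], RDF.type, OWL.AnnotationProperty))
    for n in ontology.nodes.values():
        iri = NS[n.node_id]
        g.add((iri, RDF.type, OWL.Class))
        g.add((iri, RDFS.label, Literal(n.label)))
        g.add((iri, NS.level, Literal(n.level)))
        for p in n.parents:
            g.add((iri, RDFS.subClassOf, NS[p]))
        if n.cui:
            g.add((iri, NS.cui, Literal(n.cui)))
        if n.umls_name:
            g.add((iri, NS.umlsName, Literal(n.umls_name)))
        for t in sorted(n.semantic_types):
            g.add((iri, NS.semanticType, Literal(t)))
        if n.dsm5_category:
            g.add((iri, NS.dsm5Category, Literal(n.dsm5_category)))
        if n.or_vs_nonpsych is not None:
            g.add((iri, NS.orVsNonpsych, Literal(float(n.or_vs_nonpsych))))
        if n.or_vs_psych is not None:
            g.add((iri, NS.orVsPsych, Literal(float(n.or_vs_psych))))
        for k, v in n.extras.items():
            g.add((iri, NS[k], Literal(v)))
    g.serialize(destination=str(path), format="xml")


def parse(path: str | Path, format: str = "rdfxml") -> Ontology:
    """Read an ontology file back; unknown annotation properties land in extras."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"{path}: empty or missing ontology file")
    if format == "json":
        doc = json.loads(path.read_text())
        nodes = {}
        for d in doc["nodes"]:
            known = {"id", "label", "level", "parents", "cui", "umls_name",
                     "semantic_types", "dsm5_category", "or_vs_nonpsych",
                     "or_vs_psych", "extras"}
            extras = dict(d.get("extras", {}))
            extras.update({k: str(v) for k, v in d.items() if k not in known})
            nodes[d["id"]] = OntologyNode(
                node_id=d["id"], label=d["label"], level=int(d["level"]),
                parents=tuple(d["parents"]), cui=d.get("cui"),
                umls_name=d.get("umls_name"),
                semantic_types=frozenset(d.get("semantic_types", [])),
                dsm5_category=d.get("dsm5_category"),
                or_vs_nonpsych=d.get("or_vs_nonpsych"),
                or_vs_psych=d.get("or_vs_psych"),
                extras=extras,
            )
        return Ontology(nodes=nodes, metadata=doc.get("metadata", {}))
    if format not in ("rdfxml", "owl"):
        raise ValueError(f"unknown format {format!r}")
    g = Graph()
    try:
        g.parse(str(path), format="xml")
    except Exception as exc:
        raise ValueError(f"{path}: not parseable as RDF/XML: {exc}") from exc
    prefix = str(NS)
    nodes: dict[str, OntologyNode] = {}
    for s in g.subjects(RDF.type, OWL.Class):
        nid = str(s)[len(prefix):]
        label = str(g.value(s, RDFS.label) or nid)
        level = int(g.value(s, NS.level) or 0)
        parents = tuple(sorted(str(o)[len(prefix):] for o in g.objects(s, RDFS.subClassOf)))
        sem = frozenset(str(o) for o in g.objects(s, NS.semanticType))
        known_preds = {RDF.type, RDFS.label, RDFS.subClassOf} | {NS[a] for a in _ANNOTATIONS}
        extras = {}
        for pred, obj in g.predicate_objects(s):
            if pred not in known_preds and str(pred).startswith(prefix):
                extras[str(pred)[len(prefix):]] = str(obj)
        def _num(pred):
            v = g.value(s, pred)
            return float(v) if v is not None else None
        nodes[nid] = OntologyNode(
            node_id=nid, label=label, level=level, parents=parents,
            cui=str(g.value(s, NS.cui)) if g.value(s, NS.cui) else None,
            umls_name=str(g.value(s, NS.umlsName)) if g.value(s, NS.umlsName) else None,
            semantic_types=sem,
            dsm5_category=str(g.value(s, NS.dsm5Category)) if g.value(s, NS.dsm5Category) else None,
            or_vs_nonpsych=_num(NS.orVsNonpsych),
            or_vs_psych=_num(NS.orVsPsych),
            extras=extras,
        )
    if not nodes:
        raise ValueError(f"{path}: no ontology classes found")
    return Ontology(nodes=nodes)


def isomorphic(a: Ontology, b: Ontology, properties: bool = True) -> bool:
    """Same node set, edge set and (optionally) node properties."""
    if set(a.nodes) != set(b.nodes):
        return False
    for nid, na in a.nodes.items():
        nb = b.nodes[nid]
        if sorted(na.parents) != sorted(nb.parents) or na.level != nb.level:
            return False
        if properties:
            def _close(x, y):
                if x is None or y is None:
                    return x == y
                return abs(x - y) <= 1e-9 * max(1.0, abs(x))
            if (na.label != nb.label or na.cui != nb.cui
                    or na.umls_name != nb.umls_name
                    or na.semantic_types != nb.semantic_types
                    or na.dsm5_category != nb.dsm5_category
                    or not _close(na.or_vs_nonpsych, nb.or_vs_nonpsych)
                    or not _close(na.or_vs_psych, nb.or_vs_psych)):
                return False
    return True
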