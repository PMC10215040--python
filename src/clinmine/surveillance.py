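"""Surveillance aggregations over extracted entities and relations.

These are the downstream epidemiological summaries: percentage
distributions of entity mentions, document-level prevalence of canonical
terms (a document counts once no matter how often it mentions a term),
prevalence broken down by clinical category, frequency-thresholded
"conditions following a disorder" tables, and per-drug adverse-effect
lists. Denominators are always recorded explicitly in the output, since
"percentage of patients" claims are meaningless without them.

Surface forms are canonicalized by case-folding plus an optional synonym
map; no external ontology is consulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .corpus import Corpus


class SurveillanceError(ValueError):
    pass


@dataclass
class SynonymMap:
    """Case-folded surface-form -> canonical-term map.

    Canonical terms map to themselves; unknown forms canonicalize to their
    case-folded self.
    """

    mapping: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        folded = {}
        for k, v in self.mapping.items():
            folded[k.casefold()] = v.casefold()
        for v in list(folded.values()):
            folded.setdefault(v, v)
        for v in folded.values():
            if folded[v] != v:
                raise SurveillanceError(
                    f"canonical term {v!r} must map to itself"
                )
        self.mapping = folded

    def canonical(self, surface: str) -> str:
        s = surface.casefold()
        return self.mapping.get(s, s)


@dataclass
class SurveillanceTable:
    """Rows of (key, optional subkey, count, percentage) plus an explicit
    denominator description."""

    rows: list
    denominator: str
    denominator_value: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["key", "subkey", "count", "percentage"]
        )

    def __len__(self) -> int:
        return len(self.rows)


def entity_records(corpus: Corpus, span_sets: Sequence) -> list:
    """Flatten per-sentence span sets into (doc_id, term, label) records."""
    records = []
    for sent, spans in zip(corpus, span_sets):
        for sp in sorted(spans):
            records.append(
                {"doc_id": sent.doc_id, "term": sent.span_text(sp),
                 "label": sp.label}
            )
    return records


def entity_distribution(
    entities: Iterable[dict],
    label: str,
    synonyms: Optional[SynonymMap] = None,
    denominator: str = "doc",
    total_docs: Optional[int] = None,
) -> SurveillanceTable:
    """Distribution of canonical terms of one entity type.

    ``denominator="doc"`` reports document prevalence: each canonical term
    counts once per document, and the percentage base is the number of
    documents (``total_docs`` if given, else the number of distinct
    documents among the records). ``denominator="mention"`` reports raw
    mention shares. Rows sort by count descending, ties alphabetical.
    """
    if denominator not in ("doc", "mention"):
        raise SurveillanceError(f"unknown denominator mode {denominator!r}")
    syn = synonyms or SynonymMap()
    recs = [r for r in entities if r["label"] == label]
    if denominator == "doc":
        pairs = {(r["doc_id"], syn.canonical(r["term"])) for r in recs}
        counts: dict = {}
        for _doc, term in pairs:
            counts[term] = counts.get(term, 0) + 1
        base = total_docs if total_docs is not None else len(
            {r["doc_id"] for r in recs}
        )
        denom_desc = "documents"
    else:
        counts = {}
        for r in recs:
            term = syn.canonical(r["term"])
            counts[term] = counts.get(term, 0) + 1
        base = sum(counts.values())
        denom_desc = "mentions"
    rows = [
        (term, None, c, 100.0 * c / base if base else 0.0)
        for term, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return SurveillanceTable(rows, denom_desc, int(base))


def prevalence_by_category(
    entities: Iterable[dict],
    category_map: dict,
    synonyms: Optional[SynonymMap] = None,
    label: str = "Symptom",
    total_docs: Optional[int] = None,
) -> SurveillanceTable:
    """Document prevalence of terms grouped by clinical category.

    ``category_map`` assigns canonical terms to syndrome categories
    (e.g. pulmonary, cardiovascular); unmapped terms fall into "Other".
    Percentages are per-term document prevalences over all documents.
    """
    syn = synonyms or SynonymMap()
    cat_map = {k.casefold(): v for k, v in category_map.items()}
    recs = [r for r in entities if r["label"] == label]
    pairs = {(r["doc_id"], syn.canonical(r["term"])) for r in recs}
    base = total_docs if total_docs is not None else len(
        {r["doc_id"] for r in recs}
    )
    counts: dict = {}
    for _doc, term in pairs:
        counts[term] = counts.get(term, 0) + 1
    rows = []
    for term, c in counts.items():
        cat = cat_map.get(term, "Other")
        rows.append((cat, term, c, 100.0 * c / base if base else 0.0))
    rows.sort(key=lambda r: (r[0], -r[2], r[1]))
    return SurveillanceTable(rows, "documents", int(base))


def relation_frequency_table(
    relations: Iterable[dict],
    head_type: str,
    min_head_prevalence: float = 0.70,
    top_k: int = 5,
    synonyms: Optional[SynonymMap] = None,
) -> SurveillanceTable:
    """Heads above a document-prevalence threshold with their top tails.

    Prevalence of a head term is computed among the documents containing
    at least one relation whose head has type ``head_type``; the strict
    ``> min_head_prevalence`` rule keeps only dominant heads. For each
    surviving head the ``top_k`` tail terms by co-occurrence count are
    listed (ties alphabetical).
    """
    syn = synonyms or SynonymMap()
    recs = [r for r in relations if r["head"][2] == head_type]
    docs_with_type = {r["doc_id"] for r in recs}
    n_docs = len(docs_with_type)
    head_docs: dict = {}
    tail_counts: dict = {}
    for r in recs:
        h = syn.canonical(r["head_text"])
        t = syn.canonical(r["tail_text"])
        head_docs.setdefault(h, set()).add(r["doc_id"])
        tail_counts.setdefault(h, {})
        tail_counts[h][t] = tail_counts[h].get(t, 0) + 1
    rows = []
    for head in sorted(head_docs,
                       key=lambda h: (-len(head_docs[h]), h)):
        prevalence = len(head_docs[head]) / n_docs if n_docs else 0.0
        if prevalence > min_head_prevalence:
            tails = sorted(tail_counts[head].items(),
                           key=lambda kv: (-kv[1], kv[0]))[:top_k]
            for tail, c in tails:
                rows.append((head, tail, c, 100.0 * prevalence))
    return SurveillanceTable(rows, f"documents with a {head_type} head",
                             n_docs)


def drug_effect_table(
    relations: Iterable[dict],
    relation_label: str = "drug-causes-effect",
    synonyms: Optional[SynonymMap] = None,
) -> SurveillanceTable:
    """Per-drug deduplicated adverse-effect lists.

    Keeps relations with the given label; for each canonical drug the
    effects are ordered by frequency descending then alphabetically.
    """
    syn = synonyms or SynonymMap()
    recs = [r for r in relations if r["label"] == relation_label]
    per_drug: dict = {}
    for r in recs:
        drug = syn.canonical(r["head_text"])
        effect = syn.canonical(r["tail_text"])
        per_drug.setdefault(drug, {})
        per_drug[drug][effect] = per_drug[drug].get(effect, 0) + 1
    n_rel = len(recs)
    rows = []
    for drug in sorted(per_drug):
        for effect, c in sorted(per_drug[drug].items(),
                                key=lambda kv: (-kv[1], kv[0])):
            rows.append((drug, effect, c,
                         100.0 * c / n_rel if n_rel else 0.0))
    return SurveillanceTable(rows, "extracted relations of the label", n_rel)
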