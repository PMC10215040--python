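"""Surveillance aggregations: symptom distributions, prevalence by
syndrome, conditions following a disorder, drug adverse effects.

Document prevalence counts a term once per document; denominators are
recorded explicitly in every table.
"""

from clinmine import (
    SynonymMap,
    drug_effect_table,
    entity_distribution,
    entity_records,
    generate_corpus,
    prevalence_by_category,
    preset,
    relation_frequency_table,
)

corpus = generate_corpus(preset("medium"), seed=13)
records = entity_records(corpus, [s.spans for s in corpus])
n_docs = len(corpus.doc_ids)
synonyms = SynonymMap({"SOB": "shortness of breath"})

table = entity_distribution(records, "Symptom", synonyms, "doc", n_docs)
print(f"symptom document prevalence (n = {table.denominator_value} docs):")
for term, _, count, pct in table.rows[:6]:
    print(f"  {term:22s} {count:4d} docs  {pct:5.1f}%")
# The medium preset plants fever/cough/shortness-of-breath at fixed
# document rates, so those terms dominate the top of the table.

categories = {"fever": "Pulmonary", "cough": "Pulmonary",
              "shortness of breath": "Pulmonary",
              "chest pain": "Cardiovascular", "dizziness": "Cardiovascular",
              "headache": "Cerebrovascular", "nausea": "Gastrointestinal"}
nested = prevalence_by_category(records, categories, synonyms,
                                total_docs=n_docs)
print("\nprevalence by syndrome category (top rows):")
for cat, term, count, pct in nested.rows[:8]:
    print(f"  {cat:16s} {term:22s} {pct:5.1f}%")

relations = [
    {"doc_id": f"d{i}", "sent_id": 0, "head": [0, 1, "Disease"],
     "head_text": "covid-19", "tail": [2, 3, "Symptom"],
     "tail_text": tail, "label": "symptom-follows-disease", "distance": 0.2}
    for i in range(10) for tail in (["fever"] * 3 + ["cough"])
]
freq = relation_frequency_table(relations, "Disease",
                                min_head_prevalence=0.70, top_k=5)
print("\nconditions following dominant disorders (>70% of disease docs):")
for head, tail, count, pct in freq.rows:
    print(f"  {head} -> {tail}  ({count} co-occurrences, head in {pct:.0f}%"
          " of docs)")

adverse = [
    {"doc_id": "d1", "sent_id": 0, "head": [0, 1, "Drug"],
     "head_text": "remdesivir", "tail": [2, 3, "Symptom"],
     "tail_text": t, "label": "drug-causes-effect", "distance": 0.1}
    for t in ("nausea", "nausea", "vomiting")
]
print("\ndrug adverse-effect table:")
for drug, effect, count, _ in drug_effect_table(adverse).rows:
    print(f"  {drug}: {effect} (x{count})")
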