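"""Generate a seeded synthetic clinical corpus and inspect it.

The generator emulates an annotated case-report corpus: sentences with
typed entity mentions (Disease, Symptom, Drug, SDOH), IOB2 tags consistent
with the spans, and cue-marked relations. A config plus a seed fully
determines the output.
"""

from clinmine import generate_corpus, preset, write_conll, write_docs_jsonl

corpus = generate_corpus(preset("tiny"), seed=7)

print(f"{len(corpus)} sentences across {len(corpus.doc_ids)} documents")
print(f"entity labels: {corpus.labels()}")
for sentence in corpus.sentences[:3]:
    print()
    print(" ".join(sentence.texts))
    print("  tags :", " ".join(sentence.tags))
    for span in sentence.spans:
        print(f"  span : {sentence.span_text(span)!r} -> {span.label}")
    for rel in sentence.relations:
        print(f"  rel  : {sentence.span_text(rel.head)!r} "
              f"--{rel.label}--> {sentence.span_text(rel.tail)!r}")

write_docs_jsonl(corpus, "tiny_corpus.jsonl")
write_conll(corpus, "tiny_corpus.conll")
print("\nwrote tiny_corpus.jsonl and tiny_corpus.conll")
# Each printed sentence shows the token sequence, its IOB2 tag row, the
# decoded entity spans, and any planted relation with its direction.
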