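"""Seeded synthetic clinical corpora with known ground truth.

The generator emulates the statistical structure of an annotated
case-report corpus — sentences with typed entity mentions (Disease,
Symptom, Drug, SDOH), controllable entity density, sentence-level typed
relations marked by lexical cue tokens, and document-level symptom
prevalences — without any clinical-language realism. Entity lexicons are
pairwise disjoint and disjoint from the filler vocabulary by default, so a
Bayes-optimal tagger with entity F1 = 1 exists; an ``ambiguity`` knob can
inject label-ambiguous surface forms to make the task harder.

Everything is driven by one :class:`numpy.random.Generator`, so a config
plus a seed fully determines the corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus import AnnotatedSentence, Corpus, EntitySpan, Relation
from .tagging import encode_iob


class GenError(ValueError):
    pass


@dataclass(frozen=True)
class RelationRule:
    """Plant (head, cue token, tail) patterns with a given probability."""

    head_label: str
    tail_label: str
    relation: str
    probability: float
    cue: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise GenError(f"probability must be in [0,1], got {self.probability}")


# Default clinical vocabulary. Surface forms may be multi-token; all entity
# tokens are unique to their label and absent from the filler vocabulary.
DEFAULT_LEXICONS = {
    "Disease": [
        "covid-19", "influenza", "pneumonia", "hypertension", "diabetes",
        "ards", "sepsis", "asthma", "copd", "myocarditis",
        "acute kidney injury", "heart failure",
    ],
    "Symptom": [
        "fever", "cough", "fatigue", "dyspnea", "headache", "nausea",
        "vomiting", "diarrhea", "anosmia", "myalgia", "dizziness",
        "chest pain", "sore throat", "shortness of breath",
    ],
    "Drug": [
        "remdesivir", "dexamethasone", "azithromycin", "tocilizumab",
        "hydroxychloroquine", "amoxicillin", "ivermectin", "pirfenidone",
        "heparin", "paracetamol",
    ],
    "SDOH": [
        "unemployed", "homeless", "uninsured", "smoker", "retired",
        "healthcare-worker", "rural-resident", "nursing-home",
    ],
}

DEFAULT_FILLER = [
    "patient", "the", "a", "was", "admitted", "to", "hospital", "with",
    "presented", "reported", "on", "day", "examination", "showed",
    "history", "and", "after", "treatment", "developed", "course",
    "clinical", "findings", "noted", "discharged", "stable", "condition",
]

DEFAULT_RELATION_RULES = (
    RelationRule("Disease", "Symptom", "symptom-follows-disease", 0.15,
                 "followed-by"),
    RelationRule("Drug", "Symptom", "drug-causes-effect", 0.15, "caused"),
)


@dataclass
class GenConfig:
    """Knobs of the corpus generator.

    ``entity_density`` is the expected number of entity mentions per
    ordinary sentence (Poisson). ``symptom_doc_rates`` plants canonical
    Symptom terms at fixed document-level prevalences, independently per
    document, for prevalence-recovery experiments. ``label_noise_rate``
    flips each gold tag to O with the given probability (annotation noise).
    ``ambiguity`` moves that fraction of each lexicon into a shared
    ambiguous pool usable by any label, breaking separability on purpose.
    """

    n_docs: int = 20
    sentences_per_doc: tuple = (3, 6)
    lexicons: dict = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_LEXICONS.items()
    })
    filler_vocab: list = field(default_factory=lambda: list(DEFAULT_FILLER))
    entity_density: float = 1.0
    relation_rules: tuple = DEFAULT_RELATION_RULES
    symptom_doc_rates: dict = field(default_factory=dict)
    label_noise_rate: float = 0.0
    ambiguity: float = 0.0
    doc_prefix: str = "doc"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise GenError("n_docs must be >= 1")
        lo, hi = self.sentences_per_doc
        if not (1 <= lo <= hi):
            raise GenError("sentences_per_doc must be a (lo, hi) range, lo >= 1")
        if self.entity_density < 0:
            raise GenError("entity_density must be >= 0")
        if not (0 <= self.label_noise_rate <= 1):
            raise GenError("label_noise_rate must be in [0,1]")
        self._validate_disjoint()

    def _validate_disjoint(self) -> None:
        token_owner: dict = {}
        for label, forms in self.lexicons.items():
            for form in forms:
                for tok in form.split():
                    prev = token_owner.get(tok)
                    if prev is not None and prev != label:
                        raise GenError(
                            f"lexicons not disjoint: token {tok!r} in both "
                            f"{prev} and {label}"
                        )
                    token_owner[tok] = label
        filler_clash = set(self.filler_vocab) & set(token_owner)
        if filler_clash:
            raise GenError(
                f"filler vocabulary overlaps entity lexicons: {sorted(filler_clash)}"
            )
        cues = {r.cue for r in self.relation_rules}
        if cues & set(token_owner):
            raise GenError("relation cue tokens must not be entity tokens")


def preset(name: str) -> GenConfig:
    """Named fixture configurations: ``tiny`` (unit tests), ``small``
    (integration / learnability), ``medium`` (aggregate statistics)."""
    if name == "tiny":
        return GenConfig(n_docs=6, sentences_per_doc=(2, 3), entity_density=1.0)
    if name == "small":
        return GenConfig(n_docs=40, sentences_per_doc=(3, 6), entity_density=1.2)
    if name == "medium":
        return GenConfig(
            n_docs=200,
            sentences_per_doc=(3, 6),
            entity_density=1.2,
            symptom_doc_rates={"fever": 0.5, "cough": 0.35,
                               "shortness of breath": 0.45},
        )
    raise GenError(f"unknown preset {name!r}")


def _pick_form(rng: np.random.Generator, forms: Sequence[str]) -> list:
    return forms[int(rng.integers(len(forms)))].split()


def _effective_lexicons(cfg: GenConfig, rng: np.random.Generator) -> dict:
    """Apply the ambiguity knob: a seeded fraction of forms becomes shared."""
    if cfg.ambiguity <= 0:
        return {k: list(v) for k, v in cfg.lexicons.items()}
    shared: list = []
    out: dict = {}
    for label in sorted(cfg.lexicons):
        forms = list(cfg.lexicons[label])
        k = int(round(cfg.ambiguity * len(forms)))
        idx = rng.permutation(len(forms))[:k]
        shared.extend(forms[i] for i in idx)
        out[label] = forms
    for label in out:
        out[label] = out[label] + shared
    return out


def _build_sentence(rng, cfg, lexicons, n_entities, planted=None, rule=None):
    """Assemble tokens/spans/relations for one sentence.

    ``planted`` is an optional (surface_form, label) mention that must
    appear; ``rule`` an optional RelationRule to realize.
    """
    pieces: list = []  # (tokens, label or None)
    labels = sorted(lexicons)
    if planted is not None:
        pieces.append((planted[0].split(), planted[1]))
    if rule is not None:
        head_form = _pick_form(rng, lexicons[rule.head_label])
        tail_form = _pick_form(rng, lexicons[rule.tail_label])
    for _ in range(n_entities):
        lab = labels[int(rng.integers(len(labels)))]
        pieces.append((_pick_form(rng, lexicons[lab]), lab))

    tokens: list = []
    spans: list = []
    relations: list = []

    def emit_filler(k: int) -> None:
        for _ in range(k):
            tokens.append(cfg.filler_vocab[int(rng.integers(len(cfg.filler_vocab)))])

    def emit_entity(form_tokens: list, label: str) -> EntitySpan:
        start = len(tokens)
        tokens.extend(form_tokens)
        sp = EntitySpan(start, len(tokens), label)
        spans.append(sp)
        return sp

    emit_filler(int(rng.integers(1, 4)))
    if rule is not None:
        head_sp = emit_entity(head_form, rule.head_label)
        tokens.append(rule.cue)
        tail_sp = emit_entity(tail_form, rule.tail_label)
        relations.append(Relation(head_sp, tail_sp, rule.relation))
        emit_filler(int(rng.integers(1, 3)))
    for form_tokens, lab in pieces:
        emit_entity(form_tokens, lab)
        emit_filler(int(rng.integers(1, 3)))
    return tokens, spans, relations


def generate_corpus(config: GenConfig, seed: Optional[int] = None) -> Corpus:
    """Generate a fully annotated corpus (spans, IOB tags, relations).

    ``seed`` overrides ``config.seed`` when given. Relation gold is stored
    on the sentences themselves (``AnnotatedSentence.relations``).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    # separate stream for annotation noise so the noise knob never changes
    # the generated text itself
    noise_rng = np.random.default_rng([seed, 7919])
    lexicons = _effective_lexicons(config, rng)
    lo, hi = config.sentences_per_doc
    tagset_labels = sorted(lexicons)
    sentences: list = []
    for di in range(config.n_docs):
        doc_id = f"{config.doc_prefix}{di:04d}"
        n_sent = int(rng.integers(lo, hi + 1))
        planted_terms = [
            term for term, rate in sorted(config.symptom_doc_rates.items())
            if rng.random() < rate
        ]
        sent_id = 0
        for si in range(n_sent):
            n_entities = int(rng.poisson(config.entity_density))
            rule = None
            for r in config.relation_rules:
                if rng.random() < r.probability:
                    rule = r
                    break
            tokens, spans, relations = _build_sentence(
                rng, config, lexicons, n_entities, rule=rule
            )
            sentences.append(_finish_sentence(
                noise_rng, config, doc_id, sent_id, tokens, spans, relations))
            sent_id += 1
        # one dedicated sentence per planted prevalence term
        for term in planted_terms:
            tokens, spans, relations = _build_sentence(
                rng, config, lexicons, 0, planted=(term, "Symptom")
            )
            sentences.append(_finish_sentence(
                noise_rng, config, doc_id, sent_id, tokens, spans, relations))
            sent_id += 1
    corpus = Corpus(sentences, {"generator_seed": seed,
                                "labels": tagset_labels})
    return corpus


def _finish_sentence(rng, config, doc_id, sent_id, tokens, spans, relations):
    tags = list(encode_iob(len(tokens), spans))
    if config.label_noise_rate > 0:
        noisy = [
            "O" if (t != "O" and rng.random() < config.label_noise_rate) else t
            for t in tags
        ]
        tags = noisy
        # spans stay gold; noise affects only the tag channel
        return AnnotatedSentence(doc_id, sent_id, tuple(tokens), tuple(spans),
                                 tuple(tags), tuple(relations))
    return AnnotatedSentence(doc_id, sent_id, tuple(tokens), tuple(spans),
                             tuple(tags), tuple(relations))


@dataclass
class HiddenGold:
    """Sealed side-channel of gold tags for an unlabeled pool.

    Only the simulated oracle (and test assertions) should read this.
    """

    _tags: dict = field(default_factory=dict, repr=False)

    def lookup(self, doc_id: str, sent_id: int) -> tuple:
        return self._tags[(doc_id, sent_id)]

    def __len__(self) -> int:
        return len(self._tags)


def generate_pool(config: GenConfig, seed: Optional[int] = None):
    """Unlabeled sentences plus their hidden gold, for self-training.

    Returns ``(pool_corpus, hidden_gold)``: the pool carries no tags or
    spans; the gold stays in a :class:`HiddenGold` readable by the
    simulated oracle.
    """
    full = generate_corpus(config, seed)
    hidden = HiddenGold({(s.doc_id, s.sent_id): s.tags for s in full})
    stripped = Corpus(
        [
            AnnotatedSentence(s.doc_id, s.sent_id, s.tokens)
            for s in full
        ],
        dict(full.metadata),
    )
    return stripped, hidden


def relation_instances(corpus: Corpus) -> list:
    """Flatten sentence-level gold relations into
    (sentence, relation) pairs."""
    out = []
    for s in corpus:
        for rel in s.relations:
            out.append((s, rel))
    return out
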