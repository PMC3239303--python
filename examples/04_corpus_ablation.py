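"""Run the full pipeline on a synthetic corpus, with and without inference.

Generates a seeded gold-annotated corpus, extracts records both ways and
scores them against the gold in unique-event mode.  Recall collapses
without the inference module while precision stays at 1.0 -- the
qualitative signature of inference-dependent extraction.
"""

import io

import regevents as rg
from regevents.fixtures import FixtureConfig, corpus_conllu, dictionary_rows, generate, gold_to_records

ont = rg.default_ontology()
patterns, rules, templates = rg.default_patterns(ont), rg.default_rules(ont), rg.default_templates(ont)

docs = generate(FixtureConfig(seed=11, n_docs=40))
graphs = rg.parse_conll(corpus_conllu(docs))
dictionary = rg.load_dictionary(
    io.StringIO("\n".join("\t".join(r) for r in dictionary_rows(docs))), ont
)
gold = gold_to_records(docs)
print(f"{len(docs)} documents, {len(gold)} gold records")

for infer in (True, False):
    results = rg.process_corpus(graphs, dictionary, patterns, rules, templates, ont, infer=infer)
    predicted = [r for res in results for r in res.records]
    m = rg.evaluate(predicted, gold, mode="unique", ont=ont)
    label = "with inference   " if infer else "without inference"
    print(f"{label}: TP={m.tp:3d} FP={m.fp} FN={m.fn:3d} precision={m.precision:.3f} recall={m.recall:.3f}")

# Typical output: precision 1.000 in both runs; recall 1.000 with
# inference vs ~0.3 without, because cascade, coordination and
# cross-sentence gold records are only reachable through the rules.
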