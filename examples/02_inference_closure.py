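"""Deduce implicit events by forward chaining.

Applies the shipped flattening/specialization rules to the cascade event
of example 01: the two NXOR-composed negative polarities cancel, so the
deduced database-shaped event says himA *positively* regulates fimA
expression.
"""

import io

import regevents as rg

ont = rg.default_ontology()
patterns = rg.default_patterns(ont)
rules = rg.default_rules(ont)

doc = rg.worked_cascade_document()
graph = rg.parse_conll(doc.conllu)[0]
dictionary = rg.load_dictionary(io.StringIO("\n".join("\t".join(r) for r in doc.dict_rows)), ont)
events = rg.compose(graph, rg.recognize(graph, dictionary), patterns, ont)

closed = rg.closure(events, rules, ont)
print(f"{len(events)} explicit event -> {len(closed)} events after closure\n")
for event in closed:
    if event.origin == "inferred":
        print(f"  [{event.source_id}] {event.struct}")

# The final flattened event is
#   <RegulationOfGeneExpression hasAgent=himA
#      hasPatient=<GeneExpression hasPatient=fimA> hasPolarity="positive">
# i.e. agent and patient in database shape, polarity negative*negative =
# positive, derived purely by modus ponens over the explicit event.
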