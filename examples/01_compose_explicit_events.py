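"""Compose an explicit compositional event from one parsed sentence.

The worked example "Lesions in himA cause a reduction in expression of
fimA." is shipped as a pre-parsed dependency tree.  Bottom-up pattern
matching stacks phrase semantics (lesion -> negative regulation,
expression-of -> gene expression, reduction-in -> negative regulation)
into a single sentential event.
"""

import io

import regevents as rg
from regevents.semantics import count_basic_instances

ont = rg.default_ontology()
patterns = rg.default_patterns(ont)

doc = rg.worked_cascade_document()
graph = rg.parse_conll(doc.conllu)[0]
dictionary = rg.load_dictionary(
    io.StringIO("\n".join("\t".join(r) for r in doc.dict_rows)), ont
)

print("sentence:", graph.text())
mentions = rg.recognize(graph, dictionary)
print("mentions:", ", ".join(f"{m.surface} [{m.grounding_id}: {'/'.join(m.concepts)}]" for m in mentions))

events = rg.compose(graph, mentions, patterns, ont)
for event in events:
    print("explicit event:", event.struct)
    print("basic event instances:", count_basic_instances(event.struct))

# One explicit event: a cascade of 4 basic instances (3 RegulatoryProcess,
# 1 GeneExpression).  Both the 'lesions in himA' phrase and the 'reduction
# in expression' phrase contribute a negative polarity.
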