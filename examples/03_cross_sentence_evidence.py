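"""Combine evidence across sentences.

"himA regulates expression of fimA." states expression regulation;
"The regulatory region of fimA contains a himA binding site." adds
binding-site evidence.  Neither sentence alone licenses a direct
transcription-regulation event; the two-condition rule combines them and
marks the result with hasPhysicalContact="yes".
"""

import io

import regevents as rg

ont = rg.default_ontology()
doc = rg.worked_binding_document()
graphs = rg.parse_conll(doc.conllu)
dictionary = rg.load_dictionary(io.StringIO("\n".join("\t".join(r) for r in doc.dict_rows)), ont)

for graph in graphs:
    print("sentence:", graph.text())

result = rg.process_document(
    graphs, dictionary, rg.default_patterns(ont), rg.default_rules(ont), rg.default_templates(ont), ont
)
print()
for event in result.events:
    print(f"  {event.origin:9s} {event.struct}  (sentences {event.sentences})")
print()
for record in result.records:
    print(
        f"record: template={record.template_id} agent={record.agent_id} "
        f"patient={record.patient_id} contact={record.physical_contact}"
    )

# The RegulationOfTranscription event spans sentences (0, 1): its two
# supports come from different sentences, merged at the document level.
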