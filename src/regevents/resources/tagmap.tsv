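# Default tag normalization: pos <TAG> <CoarsePOS> / rel <LABEL> <Role>
pos VERB Verb
pos AUX Verb
pos NOUN Noun
pos PROPN Noun
pos PRON Noun
pos ADP Prep
pos ADJ Adj
rel nsubj Subject
rel nsubjpass Subject
rel csubj Subject
rel obj Object
rel dobj Object
rel pobj PrepObject
rel obl PrepObject
rel nmod PrepObject
rel iobj PrepObject
rel conj Conj
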