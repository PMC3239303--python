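# Sample entity dictionary for the worked examples: surface <TAB> grounding <TAB> labels
# (E. coli IHF subunits himA/himD, both gene and DNA-binding protein, and
# the fimbrial subunit gene fimA.)
himA	P0A6X7	Gene,TranscriptionFactor
himD	P0A6Y1	Gene,TranscriptionFactor
fimA	P04128	Gene
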