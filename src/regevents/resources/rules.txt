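# Inference rules: RULEID: <Cond1> + <Cond2> ... => <Conclusion>
#
# A conclusion inherits the unmentioned top-level slots of the event
# matched by the rule's first condition, then applies its own overrides;
# polarity_sum composes polarities as NXOR (positive = identity).
#
# R1/R2 flatten compositional regulation structures (agent side / patient
# side); R3 specializes a regulatory process over a gene-expression
# patient; R4 combines an expression-regulation event with binding-site
# evidence (possibly from another sentence) into direct transcriptional
# regulation.
R1: <RegulatoryProcess hasPolarity=Polarity2 hasAgent=<RegulatoryProcess hasPatient=Patient hasPolarity=Polarity1>> => <RegulatoryProcess hasAgent=Patient hasPolarity=polarity_sum(Polarity1,Polarity2)>
R2: <RegulatoryProcess hasPolarity=Polarity2 hasPatient=<RegulatoryProcess hasPatient=Patient hasPolarity=Polarity1>> => <RegulatoryProcess hasPatient=Patient hasPolarity=polarity_sum(Polarity1,Polarity2)>
R3: <RegulatoryProcess hasPatient=GeneExpression> => <RegulationOfGeneExpression hasPatient=GeneExpression>
R4: <RegulationOfGeneExpression hasAgent=TranscriptionFactor hasPatient=<GeneExpression hasPatient=Gene>> + <RegulatoryDNARegion hasAgent=Gene hasPart=<TFBS hasAgent=TranscriptionFactor>> => <RegulationOfTranscription hasAgent=TranscriptionFactor hasPatient=<Transcription hasPatient=Gene> hasPhysicalContact="yes">
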