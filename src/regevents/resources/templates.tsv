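# Database-style semantic templates: ID <TAB> TEMPLATE <TAB> label
# '?Concept' marks a variable that must bind an entity whose label is the
# concept or a sub-concept; non-variable parts are fixed restrictions.
RGE	<RegulationOfGeneExpression hasAgent=?Protein hasPatient=<GeneExpression hasPatient=?Gene>>	GO:0010468 regulation of gene expression
RT	<RegulationOfTranscription hasAgent=?Protein hasPatient=<Transcription hasPatient=?Gene>>	GO:0045449 regulation of transcription
TFB	<BindingOfTFToTFBindingSiteOfDNA hasAgent=?TranscriptionFactor hasPatient=<RegulatoryDNARegion hasPatient=?Gene>>	GO:0008134 transcription factor binding
RCG	<RegulatoryProcess hasAgent=?MolecularEntity hasPatient=<CellGrowth hasAgent=?Cell>>	GO:0001558 regulation of cell growth
RCD	<RegulatoryProcess hasAgent=?MolecularEntity hasPatient=<CellDeath hasAgent=?Cell>>	GO:0031341 regulation of cell killing
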