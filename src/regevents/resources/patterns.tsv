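# Syntactic-semantic paired patterns: ID <TAB> SYNTACTIC <TAB> SEMANTIC
#
# Worked-example patterns (nominalized cascade vocabulary: lesion / cause /
# reduction / expression).
exp-of	(expression_Noun (of_Prep Object:Gene))	<GeneExpression hasPatient=Gene>
reduction-in	(reduction_Noun (in_Prep Object:Patient))	<RegulatoryProcess hasPatient=Patient hasPolarity="negative">
lesion-obj	(lesion_Noun Object:Patient)	<RegulatoryProcess hasPatient=Patient hasPolarity="negative">
cause-svo	(cause_Verb Subject:Agent Object:Patient)	<RegulatoryProcess hasAgent=Agent hasPatient=Patient>
#
# Direct regulation verbs (activate / repress / regulate + "expression of X").
activate-exp	(activate_Verb Subject:Agent (expression_Noun (of_Prep Object:Gene)))	<RegulationOfGeneExpression hasAgent=Agent hasPatient=<GeneExpression hasPatient=Gene> hasPolarity="positive">
repress-exp	(repress_Verb Subject:Agent (expression_Noun (of_Prep Object:Gene)))	<RegulationOfGeneExpression hasAgent=Agent hasPatient=<GeneExpression hasPatient=Gene> hasPolarity="negative">
regulate-exp	(regulate_Verb Subject:Agent (expression_Noun (of_Prep Object:Gene)))	<RegulationOfGeneExpression hasAgent=Agent hasPatient=<GeneExpression hasPatient=Gene>>
#
# Binding-site vocabulary ("the regulatory region of X contains a Y binding site").
tf-binding-site	(site_Noun binding_Noun TranscriptionFactor)	<TranscriptionFactorBindingSiteOfDNA hasAgent=TranscriptionFactor>
region-contains-site	(contain_Verb (region_Noun (of_Prep Object:Gene)) Object:TranscriptionFactorBindingSiteOfDNA)	<RegulatoryDNARegion hasAgent=Gene hasPart=TranscriptionFactorBindingSiteOfDNA>
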