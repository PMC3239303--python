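# Miniature Gene Regulation Ontology: the concept and property vocabulary
# used by the shipped patterns, inference rules and extraction templates.
#
# Entities
concept MolecularEntity
concept Gene
concept Protein
concept Operon
concept TranscriptionFactor
concept Cell
concept RegulatoryDNARegion
concept TranscriptionFactorBindingSiteOfDNA

isa Gene MolecularEntity
isa Protein MolecularEntity
isa Operon MolecularEntity
isa TranscriptionFactor Protein
isa TranscriptionFactorBindingSiteOfDNA RegulatoryDNARegion

# Processes
concept RegulatoryProcess
concept PositiveRegulation
concept NegativeRegulation
concept RegulationOfGeneExpression
concept RegulationOfTranscription
concept GeneExpression
concept Transcription
concept BindingOfTFToTFBindingSiteOfDNA
concept CellActivity
concept CellGrowth
concept CellDeath

isa PositiveRegulation RegulatoryProcess
isa NegativeRegulation RegulatoryProcess
isa RegulationOfGeneExpression RegulatoryProcess
isa RegulationOfTranscription RegulationOfGeneExpression
isa Transcription GeneExpression
isa CellGrowth CellActivity
isa CellDeath CellActivity

# Properties
property hasAgent
property hasPatient
property hasPolarity
property hasPhysicalContact
property hasPart

alias TFBS TranscriptionFactorBindingSiteOfDNA
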