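code	class	description
EXP	experimental	Inferred from Experiment
IDA	experimental	Inferred from Direct Assay
IPI	experimental	Inferred from Physical Interaction
IMP	experimental	Inferred from Mutant Phenotype
IGI	experimental	Inferred from Genetic Interaction
IEP	experimental	Inferred from Expression Pattern
HTP	high_throughput	Inferred from High Throughput Experiment
HDA	high_throughput	Inferred from High Throughput Direct Assay
HMP	high_throughput	Inferred from High Throughput Mutant Phenotype
HGI	high_throughput	Inferred from High Throughput Genetic Interaction
HEP	high_throughput	Inferred from High Throughput Expression Pattern
IBA	phylogenetic	Inferred from Biological aspect of Ancestor
IBD	phylogenetic	Inferred from Biological aspect of Descendant
IKR	phylogenetic	Inferred from Key Residues
IRD	phylogenetic	Inferred from Rapid Divergence
ISS	computational	Inferred from Sequence or structural Similarity
ISO	computational	Inferred from Sequence Orthology
ISA	computational	Inferred from Sequence Alignment
ISM	computational	Inferred from Sequence Model
IGC	computational	Inferred from Genomic Context
RCA	computational	Inferred from Reviewed Computational Analysis
TAS	author	Traceable Author Statement
NAS	author	Non-traceable Author Statement
IC	curator	Inferred by Curator
ND	curator	No biological Data available
IEA	electronic	Inferred from Electronic Annotation
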