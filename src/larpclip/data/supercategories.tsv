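# term_id	super_category	term_name
GO:0006412	translation	translation
GO:0006413	translation	translational initiation
GO:0006414	translation	translational elongation
GO:0006415	translation	translational termination
GO:0003735	translation	structural constituent of ribosome
GO:0005840	translation	ribosome
GO:0042254	translation	ribosome biogenesis
GO:0030154	cell differentiation and development	cell differentiation
GO:0032502	cell differentiation and development	developmental process
GO:0045047	protein localization to the ER	protein targeting to ER
GO:0009966	regulation of signaling response	regulation of signal transduction
GO:0050896	response to stimulus	response to stimulus
GO:0002377	antibody production	immunoglobulin production
GO:0008152	metabolism	metabolic process
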