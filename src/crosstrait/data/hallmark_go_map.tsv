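go_id	hallmark
GO:0006281	genomic_instability
GO:0006974	genomic_instability
GO:0000723	telomere_attrition
GO:0032200	telomere_attrition
GO:0040029	epigenetic_alterations
GO:0016570	epigenetic_alterations
GO:0006457	loss_of_proteostasis
GO:0030163	loss_of_proteostasis
GO:0031667	deregulated_nutrient_sensing
GO:0008286	deregulated_nutrient_sensing
GO:0007005	mitochondrial_dysfunction
GO:0006119	mitochondrial_dysfunction
GO:0090398	cellular_senescence
GO:2000772	cellular_senescence
GO:0019827	stem_cell_exhaustion
GO:0072089	stem_cell_exhaustion
GO:0006954	altered_intercellular_communication
GO:0019221	altered_intercellular_communication
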