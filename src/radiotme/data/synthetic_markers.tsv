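population	gene
T_cells	T_cells_MK1
T_cells	T_cells_MK2
T_cells	T_cells_MK3
T_cells	T_cells_MK4
T_cells	T_cells_MK5
CD8_T_cells	CD8_T_cells_MK1
CD8_T_cells	CD8_T_cells_MK2
CD8_T_cells	CD8_T_cells_MK3
CD8_T_cells	CD8_T_cells_MK4
CD8_T_cells	CD8_T_cells_MK5
Cytotoxic_lymphocytes	Cytotoxic_lymphocytes_MK1
Cytotoxic_lymphocytes	Cytotoxic_lymphocytes_MK2
Cytotoxic_lymphocytes	Cytotoxic_lymphocytes_MK3
Cytotoxic_lymphocytes	Cytotoxic_lymphocytes_MK4
Cytotoxic_lymphocytes	Cytotoxic_lymphocytes_MK5
NK_cells	NK_cells_MK1
NK_cells	NK_cells_MK2
NK_cells	NK_cells_MK3
NK_cells	NK_cells_MK4
NK_cells	NK_cells_MK5
B_lineage	B_lineage_MK1
B_lineage	B_lineage_MK2
B_lineage	B_lineage_MK3
B_lineage	B_lineage_MK4
B_lineage	B_lineage_MK5
Monocytic_lineage	Monocytic_lineage_MK1
Monocytic_lineage	Monocytic_lineage_MK2
Monocytic_lineage	Monocytic_lineage_MK3
Monocytic_lineage	Monocytic_lineage_MK4
Monocytic_lineage	Monocytic_lineage_MK5
Myeloid_dendritic_cells	Myeloid_dendritic_cells_MK1
Myeloid_dendritic_cells	Myeloid_dendritic_cells_MK2
Myeloid_dendritic_cells	Myeloid_dendritic_cells_MK3
Myeloid_dendritic_cells	Myeloid_dendritic_cells_MK4
Myeloid_dendritic_cells	Myeloid_dendritic_cells_MK5
Neutrophils	Neutrophils_MK1
Neutrophils	Neutrophils_MK2
Neutrophils	Neutrophils_MK3
Neutrophils	Neutrophils_MK4
Neutrophils	Neutrophils_MK5
Endothelial_cells	Endothelial_cells_MK1
Endothelial_cells	Endothelial_cells_MK2
Endothelial_cells	Endothelial_cells_MK3
Endothelial_cells	Endothelial_cells_MK4
Endothelial_cells	Endothelial_cells_MK5
Fibroblasts	Fibroblasts_MK1
Fibroblasts	Fibroblasts_MK2
Fibroblasts	Fibroblasts_MK3
Fibroblasts	Fibroblasts_MK4
Fibroblasts	Fibroblasts_MK5
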