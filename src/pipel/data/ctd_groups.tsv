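# Three-class residue partitions for the seven CTD attributes
# (Dubchak-style groupings as propagated by standard descriptor suites).
# columns: attribute, group1_name, group1_residues, group2_name, group2_residues, group3_name, group3_residues
hydrophobicity	polar	RKEDQN	neutral	GASTPHY	hydrophobic	CLVIMFW
normalized_vdw_volume	small	GASTPDC	medium	NVEQIL	large	MHKFRYW
polarity	low	LIFWCMVY	medium	PATGS	high	HQRKNED
polarizability	low	GASDT	medium	CPNVEQIL	high	KMHFRYW
charge	positive	KR	neutral	ANCQGHILMFPSTWYV	negative	DE
secondary_structure	helix	EALMQKRH	strand	VIYCWFT	coil	GNPSD
solvent_accessibility	buried	ALFCGIVW	exposed	RKQEND	intermediate	MSPTHY
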