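# Raman peak assignment library for human skin measured with the lensed
# (zero-offset) and 1.5 mm spatially offset fiber configurations.
# Columns: center (cm^-1), tentative biomolecule, vibrational mode,
# presence flags per fiber configuration (1 = observed).
center_cm1	biomolecule	vibrational_mode	lensed	offset_1p5
718	Lipid/nucleic acid	C-N (membrane phospholipid head)/nucleotide	0	1
733	Lipid	Phosphatidylserine	1	0
854	Protein	Ring breathing tyrosine (proteins)	1	1
903	Nucleic acid	Phosphodiester, deoxyribose	0	1
937	Protein	C-C backbone (collagen assignment)	1	0
980	Protein/lipid	C-C stretching b-sheet (proteins) = CH bending (lipids)	0	1
1002	Protein	C-C aromatic ring stretching of Phenylalanine	1	0
1043	Protein	Proline (collagen assignment)	1	1
1089	Nucleic acid	Symmetric PO2- stretching vibration of the DNA	0	1
1175	Nucleic acid	Cytosine, guanine	1	1
1221	Protein	Amide III (b-sheet)	0	1
1305	Lipid, nucleic acid	CH2 deformation (lipid), adenine, cytosine	0	1
1339	Protein/nucleic acid	CH2/CH3 wagging & twisting mode in collagen, nucleic acid & tryptophan	1	1
1380	Melanin	Linear stretching of the C-C bonds within the rings	1	0
1404	Protein	n(C=O)O- (aspartic & glutamic acid)	0	1
1458	Lipid/protein	CH2/CH3 deformation of lipids & collagen	1	1
1510	Nucleic acid	A (ring breathing modes in the DNA bases)	1	1
1580	Melanin	In-plane stretching of the aromatic rings	1	0
1645	Protein	Amide I (a-helix)	1	1
1736	Lipid	C=O ester (lipids)	0	1
1755	Lipid	C=O stretching	1	0
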