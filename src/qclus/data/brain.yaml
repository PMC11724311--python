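# Default gene-set configuration for human brain snRNA-seq QC.
#
# Brain runs exclude the cardiomyocyte-specific metrics, so no cm_nuclear /
# cm_cytoplasmic sets are declared. The cell-type marker sets are
# package-chosen canonical markers for major brain cell types (synthetic
# stand-ins in the style of Azimuth reference sets); replace them with sets
# matched to your reference atlas.
tissue: brain
sets:
  mitochondrial:
    role: mitochondrial
    genes: [MT-ND1, MT-ND2, MT-CO1, MT-CO2, MT-ATP8, MT-ATP6, MT-CO3, MT-ND3,
            MT-ND4L, MT-ND4, MT-ND5, MT-ND6, MT-CYB]
  nuclear_enriched:
    role: nuclear_enriched
    genes: [MALAT1, NEAT1, FTX, FOXP1, RBMS3, ZBTB20, LRMDA, PBX1, ITPR2,
            AUTS2, TTC28, BNC2, EXOC4, RORA, PRKG1, ARID1B, PARD3B, GPHN,
            N4BP2L2, PKHD1L1, EXOC6B, FBXL7, MED13L, TBC1D5, IMMP2L, SYNE1,
            RERE, MBD5, EXT1, WWOX]
  excitatory_neuron:
    role: celltype_marker
    genes: [SLC17A7, SATB2, RBFOX3, CUX2, RORB, TSHZ2]
  inhibitory_neuron:
    role: celltype_marker
    genes: [GAD1, GAD2, SLC32A1, ADARB2, LHX6, VIP]
  astrocyte:
    role: celltype_marker
    genes: [AQP4, GFAP, SLC1A2, GJA1, ALDH1L1, FGFR3]
  oligodendrocyte:
    role: celltype_marker
    genes: [PLP1, MBP, MOG, MOBP, ST18, CNP]
  opc:
    role: celltype_marker
    genes: [PDGFRA, CSPG4, OLIG1, OLIG2, SOX10, LHFPL3]
  microglia:
    role: celltype_marker
    genes: [P2RY12, CX3CR1, CSF1R, C1QA, ITGAM, TMEM119]
  endothelial:
    role: celltype_marker
    genes: [CLDN5, FLT1, PECAM1, VWF, ABCB1, SLC2A1]
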