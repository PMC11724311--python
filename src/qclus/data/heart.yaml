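# Default gene-set configuration for human heart snRNA-seq QC.
#
# The mitochondrial, nuclear_enriched, cm_nuclear and cm_cytoplasmic lists
# are the method's published defaults. The 11 non-CM cell-type marker sets
# below are package-chosen canonical markers for the major cardiac cell
# types (synthetic stand-ins for study-specific marker-discovery output);
# replace them wholesale with markers derived from your own reference.
tissue: heart
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
  cm_nuclear:
    role: cm_nuclear
    genes: [RBM20, TECRL, MLIP, CHRM2, TRDN, PALLD, SGCD, CMYA5, MYOM2, TBX5,
            ESRRG, LINC02248, KCNJ3, TACC2, CORIN, DPY19L2, WNK2, MITF, OBSCN,
            FHOD3, MYLK3, DAPK2, NEXN]
  cm_cytoplasmic:
    role: cm_cytoplasmic
    genes: [TTN, RYR2, PAM, TNNT2, RABGAP1L, PDLIM5, MYL7, MYH6]
  endothelial:
    role: celltype_marker
    genes: [VWF, PECAM1, CDH5, EGFL7, FLT1, PTPRB]
  fibroblast:
    role: celltype_marker
    genes: [DCN, GSN, PDGFRA, ABCA8, NEGR1, FBLN1]
  pericyte:
    role: celltype_marker
    genes: [RGS5, ABCC9, KCNJ8, PDGFRB, EGFLAM, GUCY1A2]
  smooth_muscle:
    role: celltype_marker
    genes: [MYH11, ACTA2, TAGLN, ITGA8, CARMN, NTRK3]
  myeloid:
    role: celltype_marker
    genes: [CD163, MRC1, CSF1R, F13A1, RBPJ, MSR1]
  lymphoid:
    role: celltype_marker
    genes: [CD3E, IL7R, SKAP1, THEMIS, CD2, CCL5]
  adipocyte:
    role: celltype_marker
    genes: [ADIPOQ, PLIN1, GPAM, LEP, PPARG, CIDEC]
  neuronal:
    role: celltype_marker
    genes: [NRXN1, NRXN3, XKR4, CADM2, PLP1, SOX10]
  lymphatic_endothelial:
    role: celltype_marker
    genes: [PROX1, PDPN, MMRN1, CCL21, FLT4, RELN]
  mast_cell:
    role: celltype_marker
    genes: [KIT, CPA3, TPSAB1, MS4A2, HPGD, SLC24A3]
  mesothelial:
    role: celltype_marker
    genes: [MSLN, WT1, BNC1, PRG4, ITLN1, UPK3B]
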