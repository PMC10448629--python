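# Tolerance-related gene panels used for dot-plot scoring.
version: 1
panels:
  egress_residency:
    genes: [Ccr7, S1pr1, Sell]
  activation_migration_cd8:
    genes: [Cxcr6, Ccr5, Slamf7, Adgre5, S100a4, S100a6, Ctsw]
  cytotoxicity_cytokines:
    genes: [Cst7, Gzmb, Gzmk, Gzmm, Ifng, Nkg7, Prf1, Efhd2, Ccl5, Ccl4]
  activation_migration_cd4:
    genes: [Cxcr6, Ccr5, Slamf7, Adgre5, S100a4, S100a6, H2-D1]
  cd4_tf_cytokines:
    genes: [Ifng, Lta, Tbx21, Il5, Il4, Il13, Gata3, Il17a, Rorc]
  exhaustion_receptors_cd8:
    genes: [Pdcd1, Tigit, Lag3, Havcr2]
  exhaustion_receptors_cd4:
    genes: [Pdcd1, Tigit, Lag3, Ctla4]
  exhaustion_signaling:
    genes: [Ptpn6, Ptpn11, Ptpn2]
  exhaustion_tf:
    genes: [Irf4, Nr4a1, Gata3, Tox, Batf, Prdm1, Eomes]
  treg_maintenance:
    genes: [Foxp3, Il2ra, Stat5a]
  treg_suppression:
    genes: [Il10, Nrp1, Ctla4, Cd83]
  th17:
    genes: [Rorc, Rora, Il17a]
  trm:
    genes: [Itga1, Itgae, Cd101, Cd69, Sell, S1pr1, S1pr5, Klf2, Klf3, Ccr7]
    direction:
      high: [Itga1, Itgae, Cd101, Cd69]
      low: [Sell, S1pr1, S1pr5, Klf2, Klf3, Ccr7]
  apc_costimulatory:
    genes: [Cd80, Cd86, Cd83, Cd40]
  apc_checkpoint_inhibitor:
    genes: [Cd274, Pdcd1lg2, Fas, Icosl, Lgals3, Cd200]
  plaque_inducible:
    genes: [Cxcr6, Cd8b1, S100a6, Lgals1, S100a4, H2-D1, Reep5,
            mt-Atp8, mt-Co3, mt-Co1]
    direction:
      up: [Cxcr6, Cd8b1, S100a6, Lgals1, S100a4, H2-D1, Reep5]
      down: [mt-Atp8, mt-Co3, mt-Co1]
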