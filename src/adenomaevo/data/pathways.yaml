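# The ten canonical oncogenic signaling pathways (TCGA pan-cancer curation),
# trimmed to representative member genes. Editable data, not code: pathway
# membership is a modelling choice that ships as configuration.
WNT:
  - APC
  - CTNNB1
  - AXIN1
  - AXIN2
  - AMER1
  - SOX9
  - RNF43
  - TCF7L2
  - LRP5
RTK-RAS:
  - KRAS
  - NRAS
  - HRAS
  - BRAF
  - EGFR
  - ERBB2
  - ERBB3
  - ERBB4
  - MAP2K1
  - MAP2K4
  - NF1
  - PTPN11
  - NTRK3
PI3K:
  - PIK3CA
  - PIK3R1
  - PTEN
  - AKT1
  - MTOR
  - TSC1
  - TSC2
  - STK11
TP53:
  - TP53
  - MDM2
  - MDM4
  - ATM
  - CHEK2
  - RPS6KA3
Cell-Cycle:
  - CDKN2A
  - CDKN2B
  - CCND1
  - CCNE1
  - CDK4
  - CDK6
  - RB1
MYC:
  - MYC
  - MYCN
  - MXD1
  - MAX
  - MGA
NOTCH:
  - NOTCH1
  - NOTCH2
  - NOTCH3
  - NOTCH4
  - FBXW7
  - SPEN
  - CREBBP
  - EP300
Hippo:
  - NF2
  - LATS1
  - LATS2
  - FAT1
  - YAP1
  - TAOK1
  - TAOK2
TGF-Beta:
  - TGFBR1
  - TGFBR2
  - SMAD2
  - SMAD3
  - SMAD4
  - ACVR2A
NRF2:
  - NFE2L2
  - KEAP1
  - CUL3
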