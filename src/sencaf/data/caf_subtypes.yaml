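# Editable stub of CAF subtype signatures (iCAF / myCAF / apCAF).
# These are placeholder marker panels of commonly cited subtype markers;
# replace them with the marker lists appropriate to your dataset before
# running on real data.  The synthetic pipeline writes its own planted
# marker signatures and does not use this file.
iCAF:
  - IL6
  - CXCL1
  - CXCL2
  - CXCL12
  - CCL2
  - LIF
  - PDGFRA
  - CFD
  - LMNA
  - HAS1
myCAF:
  - ACTA2
  - TAGLN
  - MYL9
  - TPM1
  - TPM2
  - POSTN
  - MMP11
  - COL12A1
  - THY1
  - PDGFRB
apCAF:
  - CD74
  - HLA-DRA
  - HLA-DRB1
  - HLA-DPA1
  - HLA-DQA1
  - SLPI
  - SAA3
  - CAV1
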