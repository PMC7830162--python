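# Default conserved-feature pattern library for the depolymerase screen.
# Grammar: uppercase letters literal, X wildcard, [..] alternation (commas
# decorative). Lipase-box patterns must contain exactly one S-only position
# (the catalytic serine).
- name: PXXXXHG
  role: oxyanion
  spec: PXXXXHG
  provenance: canonical oxyanion pocket of extracellular PHA depolymerases and related lipases
- name: HGC
  role: oxyanion
  spec: HGC
  provenance: alternative short oxyanion motif
- name: GXSXG
  role: lipase_box
  spec: GXSXG
  provenance: canonical serine-hydrolase pentapeptide
- name: AHSMGV
  role: lipase_box
  spec: AHSMGV
  provenance: depolymerase lipase-box variant
- name: AITSSTG
  role: lipase_box
  spec: "A[I,T]S[S,T]G"
  provenance: depolymerase lipase-box variant
- name: AHSXG
  role: lipase_box
  spec: AHSXG
  provenance: lipase-box variant of Bacillus-type depolymerase candidates
- name: GHSXH
  role: lipase_box
  spec: GHSXH
  provenance: observed-variant; triacylglycerol-lipase-like box carried by Vibrio candidates
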