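# Atomistic CHARMM-like naming for DNA, POPC, TIP3P water and NaCl.
# Pattern rules (regexes, tried in order) keep the table compact; radii are
# per-element van-der-Waals probe radii in nm.
name: at-charmm-like
radii:
  default: 0.17
  C: 0.17
  N: 0.155
  O: 0.152
  P: 0.18
  H: 0.12
residues:
  DA: &atnuc
    _patterns:
      - {match: "^(P$|O[12]P|OP[12]|O[35]'|C[12345]'|O4'|H[12345]')", role: DNA_BB}
      - {match: "^(C7E|H7E)", role: ETHYL, radius_class: C}
      - {match: "^[NCOH][0-9]", role: DNA_BASE}
  DT: *atnuc
  DG: *atnuc
  DC: *atnuc
  POPC:
    _patterns:
      - {match: "^(N$|C1[1-5])", role: LIPID_NC3, radius_class: N}
      - {match: "^(P$|O1[1-4]|OP[1-4])", role: LIPID_PO4, radius_class: P}
      - {match: "^(C[123]$|O2[12]|O3[12]|HA|HB|HS|HX|HY)", role: LIPID_GLY}
      - {match: "^C3([2-9]|1[0-6])$", role: LIPID_TAIL_SN1}
      - {match: "^C2([2-9]|1[0-8])$", role: LIPID_TAIL_SN2}
      - {match: "^H", role: OTHER, radius_class: H}
  TIP3:
    _patterns:
      - {match: "^(OH2|OW|H[12]|HW[12])", role: WATER, radius_class: O}
  SOD:
    SOD: {role: ION_NA, bead_radius: 0.227}
  NA:
    NA: {role: ION_NA, bead_radius: 0.227}
  CLA:
    CLA: {role: ION_CL, bead_radius: 0.227}
  CL:
    CL: {role: ION_CL, bead_radius: 0.227}
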