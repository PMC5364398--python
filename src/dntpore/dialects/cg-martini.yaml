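# Coarse-grained MARTINI-style naming for a POPC bilayer, CG water/ions and
# CG nucleic-acid beads.  POPC chain "A" (the unsaturated oleoyl chain) is the
# sn-2 chain; chain "B" (palmitoyl) is sn-1.  Radii are probe radii in nm for
# pore profiling: regular beads 0.26 nm, small (S-class) beads 0.23 nm.
name: cg-martini
radii:
  default: 0.26
  small: 0.23
residues:
  POPC:
    NC3: {role: LIPID_NC3}
    PO4: {role: LIPID_PO4}
    GL1: {role: LIPID_GLY}
    GL2: {role: LIPID_GLY}
    C1A: {role: LIPID_TAIL_SN2, tail_position: 1}
    D2A: {role: LIPID_TAIL_SN2, tail_position: 2}
    C3A: {role: LIPID_TAIL_SN2, tail_position: 3}
    C4A: {role: LIPID_TAIL_SN2, tail_position: 4}
    C1B: {role: LIPID_TAIL_SN1, tail_position: 1}
    C2B: {role: LIPID_TAIL_SN1, tail_position: 2}
    C3B: {role: LIPID_TAIL_SN1, tail_position: 3}
    C4B: {role: LIPID_TAIL_SN1, tail_position: 4}
  W:
    W: {role: WATER}
  WN:
    W: {role: WATER}
  ION:
    NA: {role: ION_NA}
    NA+: {role: ION_NA}
    CL: {role: ION_CL}
    CL-: {role: ION_CL}
  NA:
    NA: {role: ION_NA}
  CL:
    CL: {role: ION_CL}
  # CG nucleotides: backbone beads BB1-BB3, base side-chain beads SC1-SC4
  # (small bead class).
  DA: &cgnuc
    BB1: {role: DNA_BB}
    BB2: {role: DNA_BB}
    BB3: {role: DNA_BB}
    SC1: {role: DNA_BASE, radius_class: small}
    SC2: {role: DNA_BASE, radius_class: small}
    SC3: {role: DNA_BASE, radius_class: small}
    SC4: {role: DNA_BASE, radius_class: small}
    ET:  {role: ETHYL, radius_class: small}
  DT: *cgnuc
  DG: *cgnuc
  DC: *cgnuc
  # One-bead-per-nucleotide pseudo-particles written by the model builder.
  DNT:
    BB: {role: DNA_BB}
    SC: {role: DNA_BASE, radius_class: small}
    ET: {role: ETHYL, radius_class: small}
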