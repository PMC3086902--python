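# Hydrogen-bond donor/acceptor roster per residue type (side chains).
# Backbone N-H donor and C=O acceptor are implicit for every residue.
# Entries: donors = atom names of donor heavy atoms, acceptors = acceptor
# heavy atoms. Protonation follows pH 7 unless `ph` is overridden: at acidic
# pH (<4) glutamate/aspartate carboxyls and the C-terminus are protonated
# and additionally act as donors.
ph: 7.0
nterm_donor: N        # NH3+ at both pH conditions
cterm_acceptors: [O, OXT]
residues:
  ALA: {donors: [], acceptors: []}
  VAL: {donors: [], acceptors: []}
  LEU: {donors: [], acceptors: []}
  ILE: {donors: [], acceptors: []}
  PHE: {donors: [], acceptors: []}
  PRO: {donors: [], acceptors: []}
  GLY: {donors: [], acceptors: []}
  MET: {donors: [], acceptors: []}
  CYS: {donors: [SG], acceptors: [SG]}
  SER: {donors: [OG], acceptors: [OG]}
  THR: {donors: [OG1], acceptors: [OG1]}
  TYR: {donors: [OH], acceptors: [OH]}
  TRP: {donors: [NE1], acceptors: []}
  ASN: {donors: [ND2], acceptors: [OD1]}
  GLN: {donors: [NE2], acceptors: [OE1]}
  ASP: {donors: [], acceptors: [OD1, OD2], acidic_donors: [OD2]}
  GLU: {donors: [], acceptors: [OE1, OE2], acidic_donors: [OE2]}
  LYS: {donors: [NZ], acceptors: []}
  ARG: {donors: [NE, NH1, NH2], acceptors: []}
  HIS: {donors: [ND1, NE2], acceptors: [ND1, NE2]}
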