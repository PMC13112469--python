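# Bundled charge/radius/H-bond-role template table.
#
# Schema:
#   residues:
#     <RES>:
#       formal_charge: <int>           # partial charges must sum to this
#       atoms:
#         <NAME>: {charge: <e>, radius: <Å>, role: donor|acceptor|both|none}
#
# Partial charges are Gasteiger-like values normalized so each residue sums
# exactly to its formal charge; radii are Bondi-type van der Waals radii with
# nonpolar hydrogens folded into heavy atoms (polar hydrogens explicit).
# The table is swappable: pass any file with this schema to the CLI/--charges.
#
# Residues:
#   GAL - one fully protonated gallic-acid unit of the PGAL oligomer (net 0)
#   HIE - zwitterionic histidine: NH3+/COO-, neutral imidazole (net 0)
#   HIP - protonated histidine: NH3+/COO-, imidazolium ring (net +1)
residues:
  GAL:
    formal_charge: 0
    atoms:
      C1:  {charge:  0.08, radius: 1.70, role: none}
      C2:  {charge: -0.06, radius: 1.70, role: none}
      C3:  {charge:  0.14, radius: 1.70, role: none}
      C4:  {charge:  0.12, radius: 1.70, role: none}
      C5:  {charge:  0.14, radius: 1.70, role: none}
      C6:  {charge: -0.06, radius: 1.70, role: none}
      C7:  {charge:  0.34, radius: 1.70, role: none}
      O1:  {charge: -0.28, radius: 1.52, role: acceptor}
      O2:  {charge: -0.31, radius: 1.52, role: both}
      HO2: {charge:  0.22, radius: 1.05, role: none}
      O3:  {charge: -0.36, radius: 1.52, role: both}
      HO3: {charge:  0.25, radius: 1.05, role: none}
      O4:  {charge: -0.36, radius: 1.52, role: both}
      HO4: {charge:  0.25, radius: 1.05, role: none}
      O5:  {charge: -0.36, radius: 1.52, role: both}
      HO5: {charge:  0.25, radius: 1.05, role: none}
  HIE:
    formal_charge: 0
    atoms:
      N:   {charge: -0.30, radius: 1.55, role: donor}
      H1:  {charge:  0.33, radius: 1.05, role: none}
      H2:  {charge:  0.33, radius: 1.05, role: none}
      H3:  {charge:  0.33, radius: 1.05, role: none}
      CA:  {charge:  0.21, radius: 1.70, role: none}
      C:   {charge:  0.36, radius: 1.70, role: none}
      O:   {charge: -0.63, radius: 1.52, role: acceptor}
      OXT: {charge: -0.63, radius: 1.52, role: acceptor}
      CB:  {charge: -0.05, radius: 1.70, role: none}
      CG:  {charge:  0.02, radius: 1.70, role: none}
      ND1: {charge: -0.40, radius: 1.55, role: acceptor}
      CE1: {charge:  0.25, radius: 1.70, role: none}
      NE2: {charge: -0.28, radius: 1.55, role: donor}
      HE2: {charge:  0.31, radius: 1.05, role: none}
      CD2: {charge:  0.15, radius: 1.70, role: none}
  HIP:
    formal_charge: 1
    atoms:
      N:   {charge: -0.30, radius: 1.55, role: donor}
      H1:  {charge:  0.33, radius: 1.05, role: none}
      H2:  {charge:  0.33, radius: 1.05, role: none}
      H3:  {charge:  0.33, radius: 1.05, role: none}
      CA:  {charge:  0.21, radius: 1.70, role: none}
      C:   {charge:  0.36, radius: 1.70, role: none}
      O:   {charge: -0.58, radius: 1.52, role: acceptor}
      OXT: {charge: -0.58, radius: 1.52, role: acceptor}
      CB:  {charge: -0.05, radius: 1.70, role: none}
      CG:  {charge:  0.05, radius: 1.70, role: none}
      ND1: {charge: -0.10, radius: 1.55, role: donor}
      HD1: {charge:  0.35, radius: 1.05, role: none}
      CE1: {charge:  0.35, radius: 1.70, role: none}
      NE2: {charge: -0.10, radius: 1.55, role: donor}
      HE2: {charge:  0.35, radius: 1.05, role: none}
      CD2: {charge:  0.05, radius: 1.70, role: none}
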