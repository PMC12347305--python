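# Simplified united-atom residue topology with rigid covalent geometry.
# Backbone per residue: N, H (amide), CA, C, O.  Side chains are linear chains
# of united pseudo-atoms (class CS); a residue with c rotatable side-chain
# torsions carries c+1 side atoms so every rotatable bond moves a dependent
# atom.  Ring side chains (His, Phe, Tyr, Trp, Pro) are approximated by short
# linear chains; proline keeps an amide H for topological uniformity.  The
# table is illustrative, not a reproduction of any published force-field
# geometry; it is pluggable via this file format.

[bonds]
# classA classB length_A
N  CA 1.47
CA C  1.53
C  N  1.32
C  O  1.24
N  H  1.00
CA CS 1.53
CS CS 1.53

[angles]
# classA classB classC angle_deg  (B is the apex)
N  CA C  110.0
CA C  N  114.0
C  N  CA 123.0
CA C  O  121.0
C  N  H  119.0
CA N  H  119.0
N  CA CS 110.0
CA CS CS 114.0
CS CS CS 114.0

[residues]
# one_letter name chi_count side_atom_names (comma separated, '-' if none)
G GLY 0 -
A ALA 1 CB,CG
V VAL 2 CB,CG,CD
L LEU 3 CB,CG,CD,CE
I ILE 3 CB,CG,CD,CE
P PRO 0 -
F PHE 2 CB,CG,CD
W TRP 2 CB,CG,CD
M MET 3 CB,CG,CD,CE
S SER 2 CB,CG,CD
T THR 2 CB,CG,CD
C CYS 2 CB,CG,CD
Y TYR 2 CB,CG,CD
N ASN 2 CB,CG,CD
Q GLN 3 CB,CG,CD,CE
D ASP 2 CB,CG,CD
E GLU 3 CB,CG,CD,CE
K LYS 4 CB,CG,CD,CE,CZ
R ARG 4 CB,CG,CD,CE,CZ
H HIS 2 CB,CG,CD
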