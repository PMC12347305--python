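# Reduced illustrative parameter set for the torsion-space empirical potential.
# Units: A [kcal*A^12/mol], B [kcal*A^6/mol], C [kcal*A^12/mol], D [kcal*A^10/mol],
# charges [e], barriers U [kcal/mol].  The table is explicit: no combining rules
# are applied at load time; a missing entry is a configuration error.

[options]
dielectric = 2.0
coulomb_constant = 332

[charges]
N  -0.35
H   0.25
CA  0.10
C   0.45
O  -0.45
CS  0.00

[pairs]
# classA classB A_ij B_ij
N  N  381827       494.337
N  H  13136.2      54.5197
N  CA 599363       550.687
N  C  506758       506.361
N  O  298361       462.05
N  CS 774756       655.296
H  H  257.1        4.5352
H  CA 23766.8      65.2037
H  C  19425.8      58.9491
H  O  9492.82      49.0052
H  CS 31747.1      78.8741
CA CA 906574       602.187
CA C  773348       556.183
CA O  477894       519.94
CA CS 1.16177e+06  713.485
C  C  658295       513.145
C  O  402109       476.935
C  CS 993102       659.663
O  O  230584       429.497
O  CS 620649       620.163
CS CS 1.48579e+06  844.499

[hbond]
# donor-H class, acceptor class, C_ij, D_ij  (12-10 well at ~1.9 A, depth ~2 kcal/mol)
H O 22133.0 7357.3

[torsions]
# kind U_n k_n sign
phi   1.0  3 +
psi   1.0  3 +
omega 20.0 2 -
chi   2.8  3 +
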