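; Palmitoyl tail fragment (Martini 2.2 dialect), linear four-bead chain.
; Synthetic template data shipped with lolkit; used for the third,
; amide-linked acyl chain of triacylcysteine.
[ moleculetype ]
; molname  nrexcl
PALM  1

[ atoms ]
; nr  type  resnr  residue  atom  cgnr  charge ; fragment_role
   1   C1      1     PALM   C1P     1     0.0 ; tail
   2   C1      1     PALM   C2P     2     0.0 ; tail
   3   C1      1     PALM   C3P     3     0.0 ; tail
   4   C1      1     PALM   C4P     4     0.0 ; tail

[ bonds ]
; i  j  length(nm)  force(kJ/mol/nm^2)
  1   2   0.47   1250.0
  2   3   0.47   1250.0
  3   4   0.47   1250.0

[ angles ]
; i  j  k  angle(deg)  force(kJ/mol)
  1   2   3   180.0   25.0
  2   3   4   180.0   25.0
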