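; Cysteine coarse-grained template (Martini 3 amino-acid dialect).
; Synthetic template data shipped with lolkit.
[ moleculetype ]
; molname  nrexcl
CYS  1

[ atoms ]
; nr  type  resnr  residue  atom  cgnr  charge ; fragment_role
   1   P2      1     CYS     BB     1     0.0 ; backbone
   2   C6      1     CYS    SC1     2     0.0 ; sidechain

[ bonds ]
; i  j  length(nm)  force(kJ/mol/nm^2)
  1   2   0.34   7500.0
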