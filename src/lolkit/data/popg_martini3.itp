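; POPG coarse-grained template (Martini 3 lipid dialect).
; Synthetic template data shipped with lolkit (see popg_martini22.itp).
[ moleculetype ]
; molname  nrexcl
POPG  1

[ atoms ]
; nr  type  resnr  residue  atom  cgnr  charge ; fragment_role
   1   SP4r    1     POPG   GL0     1     0.0 ; headgroup
   2   Q5      1     POPG   PO4     2    -1.0 ; phosphate
   3   SN4a    1     POPG   GL1     3     0.0 ; glycerol
   4   N4a     1     POPG   GL2     4     0.0 ; glycerol
   5   C1      1     POPG   C1A     5     0.0 ; tail
   6   C4h     1     POPG   D2A     6     0.0 ; tail
   7   C1      1     POPG   C3A     7     0.0 ; tail
   8   C1      1     POPG   C4A     8     0.0 ; tail
   9   C1      1     POPG   C1B     9     0.0 ; tail
  10   C1      1     POPG   C2B    10     0.0 ; tail
  11   C1      1     POPG   C3B    11     0.0 ; tail
  12   C1      1     POPG   C4B    12     0.0 ; tail

[ bonds ]
; i  j  length(nm)  force(kJ/mol/nm^2)
  1   2   0.44   1250.0
  2   3   0.42   1350.0
  3   4   0.31   2500.0
  3   5   0.47   5000.0
  5   6   0.47   3800.0
  6   7   0.47   3800.0
  7   8   0.47   3800.0
  4   9   0.47   3600.0
  9  10   0.47   3800.0
 10  11   0.47   3800.0
 11  12   0.47   3800.0

[ angles ]
; i  j  k  angle(deg)  force(kJ/mol)
  2   3   4   108.0   21.5
  2   3   5   139.1   31.2
  3   5   6   180.0   35.0
  5   6   7   120.0   35.0
  6   7   8   180.0   35.0
  4   9  10   180.0   35.0
  9  10  11   180.0   35.0
 10  11  12   180.0   35.0
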