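ATOM      1  CD1 LEU A 104       0.000   0.000   0.000  1.00  0.00           C  
ATOM      2 HD11 LEU A 104       1.090   0.000   0.000  1.00  0.00           H  
ATOM      3 HD12 LEU A 104      -0.363  -1.028   0.000  1.00  0.00           H  
ATOM      4 HD13 LEU A 104      -0.363   0.514  -0.890  1.00  0.00           H  
ATOM      5 HD14 LEU A 104      -0.363   0.514   0.890  1.00  0.00           H  
ATOM      6  CG1 VAL A 110       3.960   0.000   0.000  1.00  0.00           C  
ATOM      7 HG11 VAL A 110       2.870   0.000   0.000  1.00  0.00           H  
ATOM      8 HG12 VAL A 110       4.323   1.028   0.000  1.00  0.00           H  
ATOM      9 HG13 VAL A 110       4.323  -0.514  -0.890  1.00  0.00           H  
ATOM     10 HG14 VAL A 110       4.323  -0.514   0.890  1.00  0.00           H  
ATOM     11  O1  LEU A 104       0.000   4.000   0.000  1.00  0.00           O  
ATOM     12  O2  VAL A 110       3.100   4.000   0.000  1.00  0.00           O  
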