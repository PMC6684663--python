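ATOM      1  N   ARG A   1      -1.200   0.800   0.200  1.00  0.00           N
ATOM      2  CA  ARG A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ARG A   1       0.550   1.420  -0.300  1.00  0.00           C
ATOM      4  O   ARG A   1       0.600   2.600  -0.350  1.00  0.00           O
ATOM      5  CB  ARG A   1       0.640  -1.020   1.010  1.00  0.00           C
ATOM      6  CG  ARG A   1       1.000  -1.600   2.200  1.00  0.00           C
ATOM      7  CD  ARG A   1       1.800  -2.400   2.600  1.00  0.00           C
ATOM      8  CE  ARG A   1       2.700  -2.700   3.400  1.00  0.00           C
ATOM      9  N   GLY A   2       0.356   1.399  -2.369  1.00  0.00           N
ATOM     10  CA  GLY A   2       0.012   2.800  -2.569  1.00  0.00           C
ATOM     11  C   GLY A   2      -1.353   2.124  -2.869  1.00  0.00           C
ATOM     12  O   GLY A   2      -2.187   1.288  -2.919  1.00  0.00           O
ATOM     13  N   TYR A   3      -1.700   2.838  -5.045  1.00  0.00           N
ATOM     14  CA  TYR A   3      -2.392   1.573  -5.245  1.00  0.00           C
ATOM     15  C   TYR A   3      -0.929   1.149  -5.545  1.00  0.00           C
ATOM     16  O   TYR A   3       0.251   1.203  -5.595  1.00  0.00           O
ATOM     17  CB  TYR A   3      -3.352   0.846  -4.235  1.00  0.00           C
ATOM     18  CG  TYR A   3      -3.898   0.437  -3.045  1.00  0.00           C
ATOM     19  CD  TYR A   3      -4.625  -0.430  -2.645  1.00  0.00           C
ATOM     20  CE  TYR A   3      -4.845  -1.353  -1.845  1.00  0.00           C
ATOM     21  N   LYS A   4      -3.597   4.671  -6.354  1.00  0.00           N
ATOM     22  CA  LYS A   4      -2.232   5.137  -6.554  1.00  0.00           C
ATOM     23  C   LYS A   4      -3.024   6.437  -6.854  1.00  0.00           C
ATOM     24  O   LYS A   4      -3.930   7.195  -6.904  1.00  0.00           O
ATOM     25  CB  LYS A   4      -1.033   5.024  -5.544  1.00  0.00           C
ATOM     26  CG  LYS A   4      -0.353   4.957  -4.354  1.00  0.00           C
ATOM     27  CD  LYS A   4       0.768   5.105  -3.954  1.00  0.00           C
ATOM     28  CE  LYS A   4       1.554   5.637  -3.154  1.00  0.00           C
ATOM     29  N   LEU A   5      -3.629   6.704  -4.790  1.00  0.00           N
ATOM     30  CA  LEU A   5      -4.950   7.283  -4.990  1.00  0.00           C
ATOM     31  C   LEU A   5      -5.244   5.789  -5.290  1.00  0.00           C
ATOM     32  O   LEU A   5      -5.088   4.618  -5.340  1.00  0.00           O
ATOM     33  CB  LEU A   5      -5.758   8.176  -3.980  1.00  0.00           C
ATOM     34  CG  LEU A   5      -6.213   8.684  -2.790  1.00  0.00           C
ATOM     35  CD  LEU A   5      -7.141   9.333  -2.390  1.00  0.00           C
ATOM     36  CE  LEU A   5      -8.079   9.471  -1.590  1.00  0.00           C
END
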