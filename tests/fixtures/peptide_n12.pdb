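ATOM      1  N   MET A   1      -1.200   0.800   0.200  1.00  0.00           N
ATOM      2  CA  MET A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   MET A   1       0.550   1.420  -0.300  1.00  0.00           C
ATOM      4  O   MET A   1       0.600   2.600  -0.350  1.00  0.00           O
ATOM      5  CB  MET A   1       0.640  -1.020   1.010  1.00  0.00           C
ATOM      6  CG  MET A   1       1.000  -1.600   2.200  1.00  0.00           C
ATOM      7  CD  MET A   1       1.800  -2.400   2.600  1.00  0.00           C
ATOM      8  CE  MET A   1       2.700  -2.700   3.400  1.00  0.00           C
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
ATOM     21  N   VAL A   4      -3.597   4.671  -6.354  1.00  0.00           N
ATOM     22  CA  VAL A   4      -2.232   5.137  -6.554  1.00  0.00           C
ATOM     23  C   VAL A   4      -3.024   6.437  -6.854  1.00  0.00           C
ATOM     24  O   VAL A   4      -3.930   7.195  -6.904  1.00  0.00           O
ATOM     25  CB  VAL A   4      -1.033   5.024  -5.544  1.00  0.00           C
ATOM     26  CG  VAL A   4      -0.353   4.957  -4.354  1.00  0.00           C
ATOM     27  CD  VAL A   4       0.768   5.105  -3.954  1.00  0.00           C
ATOM     28  CE  VAL A   4       1.554   5.637  -3.154  1.00  0.00           C
ATOM     29  N   GLU A   5      -3.629   6.704  -4.790  1.00  0.00           N
ATOM     30  CA  GLU A   5      -4.950   7.283  -4.990  1.00  0.00           C
ATOM     31  C   GLU A   5      -5.244   5.789  -5.290  1.00  0.00           C
ATOM     32  O   GLU A   5      -5.088   4.618  -5.340  1.00  0.00           O
ATOM     33  CB  GLU A   5      -5.758   8.176  -3.980  1.00  0.00           C
ATOM     34  CG  GLU A   5      -6.213   8.684  -2.790  1.00  0.00           C
ATOM     35  CD  GLU A   5      -7.141   9.333  -2.390  1.00  0.00           C
ATOM     36  CE  GLU A   5      -8.079   9.471  -1.590  1.00  0.00           C
ATOM     37  N   MET A   6      -7.987   6.938  -7.167  1.00  0.00           N
ATOM     38  CA  MET A   6      -7.404   5.619  -7.367  1.00  0.00           C
ATOM     39  C   MET A   6      -6.178   6.522  -7.667  1.00  0.00           C
ATOM     40  O   MET A   6      -5.502   7.490  -7.717  1.00  0.00           O
ATOM     41  CB  MET A   6      -7.411   4.415  -6.357  1.00  0.00           C
ATOM     42  CG  MET A   6      -7.419   3.732  -5.167  1.00  0.00           C
ATOM     43  CD  MET A   6      -7.173   2.628  -4.767  1.00  0.00           C
ATOM     44  CE  MET A   6      -6.575   1.891  -3.967  1.00  0.00           C
ATOM     45  N   TRP A   7      -8.543   0.596  -6.385  1.00  0.00           N
ATOM     46  CA  TRP A   7      -8.082   1.962  -6.585  1.00  0.00           C
ATOM     47  C   TRP A   7      -9.596   2.125  -6.885  1.00  0.00           C
ATOM     48  O   TRP A   7     -10.749   1.867  -6.935  1.00  0.00           O
ATOM     49  CB  TRP A   7      -7.263   2.845  -5.575  1.00  0.00           C
ATOM     50  CG  TRP A   7      -6.796   3.344  -4.385  1.00  0.00           C
ATOM     51  CD  TRP A   7      -6.231   4.324  -3.985  1.00  0.00           C
ATOM     52  CE  TRP A   7      -6.175   5.271  -3.185  1.00  0.00           C
ATOM     53  N   THR A   8      -6.583   2.378 -10.167  1.00  0.00           N
ATOM     54  CA  THR A   8      -7.846   1.682 -10.367  1.00  0.00           C
ATOM     55  C   THR A   8      -6.840   0.539 -10.667  1.00  0.00           C
ATOM     56  O   THR A   8      -5.815  -0.049 -10.717  1.00  0.00           O
ATOM     57  CB  THR A   8      -9.046   1.584  -9.357  1.00  0.00           C
ATOM     58  CG  THR A   8      -9.727   1.532  -8.167  1.00  0.00           C
ATOM     59  CD  THR A   8     -10.806   1.190  -7.767  1.00  0.00           C
ATOM     60  CE  THR A   8     -11.487   0.530  -6.967  1.00  0.00           C
ATOM     61  N   ARG A   9     -12.952   1.688  -9.388  1.00  0.00           N
ATOM     62  CA  ARG A   9     -11.551   1.348  -9.588  1.00  0.00           C
ATOM     63  C   ARG A   9     -11.521   2.871  -9.888  1.00  0.00           C
ATOM     64  O   ARG A   9     -11.879   3.996  -9.938  1.00  0.00           O
ATOM     65  CB  ARG A   9     -10.600   0.609  -8.578  1.00  0.00           C
ATOM     66  CG  ARG A   9     -10.062   0.188  -7.388  1.00  0.00           C
ATOM     67  CD  ARG A   9      -9.037  -0.289  -6.988  1.00  0.00           C
ATOM     68  CE  ARG A   9      -8.088  -0.262  -6.188  1.00  0.00           C
ATOM     69  N   PRO A  10     -13.843  -0.816 -11.368  1.00  0.00           N
ATOM     70  CA  PRO A  10     -14.647   0.381 -11.568  1.00  0.00           C
ATOM     71  C   PRO A  10     -15.697  -0.721 -11.868  1.00  0.00           C
ATOM     72  O   PRO A  10     -16.193  -1.793 -11.918  1.00  0.00           O
ATOM     73  CB  PRO A  10     -14.849   1.568 -10.558  1.00  0.00           C
ATOM     74  CG  PRO A  10     -14.960   2.242  -9.368  1.00  0.00           C
ATOM     75  CD  PRO A  10     -15.395   3.287  -8.968  1.00  0.00           C
ATOM     76  CE  PRO A  10     -16.112   3.907  -8.168  1.00  0.00           C
ATOM     77  N   ALA A  11     -16.402   4.393 -13.336  1.00  0.00           N
ATOM     78  CA  ALA A  11     -16.618   2.967 -13.536  1.00  0.00           C
ATOM     79  C   ALA A  11     -15.098   3.070 -13.836  1.00  0.00           C
ATOM     80  O   ALA A  11     -14.008   3.525 -13.886  1.00  0.00           O
ATOM     81  CB  ALA A  11     -17.270   1.955 -12.526  1.00  0.00           C
ATOM     82  CG  ALA A  11     -17.643   1.383 -11.336  1.00  0.00           C
ATOM     83  CD  ALA A  11     -18.028   0.319 -10.936  1.00  0.00           C
ATOM     84  CE  ALA A  11     -17.919  -0.623 -10.136  1.00  0.00           C
ATOM     85  N   ARG A  12     -17.857   5.231 -15.427  1.00  0.00           N
ATOM     86  CA  ARG A  12     -16.734   6.137 -15.627  1.00  0.00           C
ATOM     87  C   ARG A  12     -17.924   7.086 -15.927  1.00  0.00           C
ATOM     88  O   ARG A  12     -19.035   7.487 -15.977  1.00  0.00           O
ATOM     89  CB  ARG A  12     -15.569   6.442 -14.618  1.00  0.00           C
ATOM     90  CG  ARG A  12     -14.908   6.612 -13.427  1.00  0.00           C
ATOM     91  CD  ARG A  12     -13.905   7.136 -13.027  1.00  0.00           C
ATOM     92  CE  ARG A  12     -13.350   7.905 -12.227  1.00  0.00           C
END
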