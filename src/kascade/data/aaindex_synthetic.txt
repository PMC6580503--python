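H SYNH490101
D Synthetic hydropathy-like scale (generated fixture, not a published index)
R none
A synthetic
T fixture
J none
C none
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.80   -4.50   -3.50   -3.50    2.50   -3.50   -3.50   -0.40   -3.20    4.50
    3.80   -3.90    1.90    2.80   -1.60   -0.80   -0.70   -0.90   -1.30    4.20
//
H SYNG890102
D Synthetic unfolding activation energy-like scale (generated fixture)
R none
A synthetic
T fixture
J none
C none
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   10.04    6.18    5.63    5.76    8.89    5.41    5.37    7.99    7.49    8.72
    8.79    5.58    8.16    7.98    7.79    7.08    7.44    9.90    8.82    9.44
//
H SYNF900103
D Synthetic backbone flexibility-like B-value scale (generated fixture)
R none
A synthetic
T fixture
J none
C none
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.98    1.04    1.05    1.07    0.91    1.04    1.09    1.04    0.95    0.88
    0.93    1.10    0.94    0.92    1.05    1.06    1.00    0.90    0.92    0.89
//
H SYNT910104
D Synthetic transmembrane turn propensity-like scale (generated fixture)
R none
A synthetic
T fixture
J none
C none
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.70    1.52    1.38    1.53    0.65    1.44    1.61    1.13    1.00    0.78
    0.62    1.66    0.68    0.59    1.83    1.20    1.08    0.79    0.99    0.71
//
H SYNA000105
D Synthetic incomplete scale with missing values (fixture for NA rejection)
R none
A synthetic
T fixture
J none
C none
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.10      NA    0.30    0.40    0.50    0.60    0.70    0.80    0.90    1.00
    1.10    1.20      NA    1.40    1.50    1.60    1.70    1.80    1.90    2.00
//
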