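# IUPAC 2013 isotopic masses and abundances for the peptide-relevant elements.
# Rows per element are ordered by mass; the first row is the monoisotopic (lightest) species.
element,mass,abundance
C,12.0,0.9893
C,13.0033548378,0.0107
H,1.0078250319,0.999885
H,2.014101778,0.000115
N,14.0030740052,0.99636
N,15.0001088984,0.00364
O,15.9949146221,0.99757
O,16.9991315,0.00038
O,17.9991604,0.00205
S,31.97207069,0.9499
S,32.9714585,0.0075
S,33.96786683,0.0425
S,35.96708088,0.0001
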