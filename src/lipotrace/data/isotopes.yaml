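# Natural terrestrial isotope abundances at unit (nominal-mass) resolution.
# Per element: list of [nominal mass shift relative to the lightest isotope,
# abundance]. Abundances sum to 1 per element. Values are the standard IUPAC
# representative abundances.
C:
  - [0, 0.9893]
  - [1, 0.0107]
H:
  - [0, 0.999885]
  - [1, 0.000115]
N:
  - [0, 0.99636]
  - [1, 0.00364]
O:
  - [0, 0.99757]
  - [1, 0.00038]
  - [2, 0.00205]
Si:
  - [0, 0.92223]
  - [1, 0.04685]
  - [2, 0.03092]
S:
  - [0, 0.9499]
  - [1, 0.0075]
  - [2, 0.0425]
  - [4, 0.0001]
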