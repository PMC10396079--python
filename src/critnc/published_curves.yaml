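# Published critical-N dilution curve constants for winter wheat,
# kept as comparison references (provenance strings name the source study).
- basis: leaf
  A1: 3.06
  A2: 0.15
  source: winter wheat leaf biomass (Yao et al.)
- basis: shoot
  A1: 5.35
  A2: 0.442
  source: winter wheat shoot biomass (Justes et al. 1994)
- basis: shoot
  A1: 4.15
  A2: 0.38
  source: winter wheat shoot biomass, eastern China (Yue et al.)
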