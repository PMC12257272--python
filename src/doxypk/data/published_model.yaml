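# Final population model for oral doxycycline in pigs: typical disposition
# at the 50-kg reference, body-weight power-model exponents, four oral
# absorption submodels, between-subject variability (CV%) and route-specific
# additive + proportional residual error.
reference_bw: 50.0
disposition:
  cl: 0.259      # L/kg/h
  cl2: 1.179
  cl3: 0.072
  vc: 0.192      # L/kg
  v2: 0.595
  v3: 0.536
covariates:
  - {parameter: cl, exponent: 0.299}
  - {parameter: cl2, exponent: -0.224}
  - {parameter: cl3, exponent: -0.544}
  - {parameter: v3, exponent: 0.376}
absorption:
  FEED_TLS: {ka: 0.072, f: 0.501}       # in-feed, field conditions
  FEED_OTHERS: {ka: 0.144, f: 0.340}    # in-feed, laboratory conditions
  SOL_DW: {ka: 0.689, f: 0.307}         # drinking water, spontaneous intake
  SOL_TUBING: {ka: 0.725, f: 0.258}     # solution by stomach tube
bsv_percent:
  vc: 107.8
  v2: 63.4
  v3: 47.5
  cl: 27.1
  cl2: 80.0
  cl3: 245.5
  ka_FEED_TLS: 16.9
  f_FEED_TLS: 84.8
  ka_FEED_OTHERS: 51.4
  f_FEED_OTHERS: 36.4
  ka_SOL_DW: 27.6
  f_SOL_DW: 34.3
  ka_SOL_TUBING: 54.0
  f_SOL_TUBING: 29.3
residual:
  IV: {stdev0: 0.013, cmult: 0.139}
  FEED_TLS: {stdev0: 0.113, cmult: 0.228}
  FEED_OTHERS: {stdev0: 0.019, cmult: 0.184}
  SOL_TUBING: {stdev0: 0.003, cmult: 0.275}
  SOL_DW: {stdev0: 0.006, cmult: 0.293}
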