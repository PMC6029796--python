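# Baseline parameter set of the HiNH cost analysis (AU$, 2011 prices).
# Program costs are per annum; utilisation rates are per 1,000 RACF beds per
# month; lengths of stay are hours; j is catchment RACF beds in thousands.
# The deterministic base case treats the equipment as useful for one year
# with no discounting; the `distributions` block defines how each uncertain
# parameter is varied in the probabilistic sensitivity analysis.
program_costs:
  hinh_staff: 361943        # program nursing staff incl. on-costs
  in_kind: 77294            # time in kind from other health professionals
  travel: 6835
  admin_training: 10858
  stationery: 720
  telephone: 2136
  equipment_price: 19100    # computers, laptop, printer, fax, phones
  office_space: 9230
equipment_life: 1.0         # years (deterministic base case)
discount_rate: 0.0          # per year (deterministic base case)
utilisation:
  a: 63.19                  # ED presentation rate, without intervention
  b: 49.77                  # inpatient admission rate, without intervention
  c: 13.09                  # ED LOS per presentation, hours
  d: 80.22                  # inpatient LOS per admission, hours
  e: -10.47                 # change in ED presentation rate
  f: -23.48                 # change in admission rate
  g: -6.14                  # change in ED LOS, hours
  h: -15.27                 # change in inpatient LOS, hours
  i: 0.5                    # fraction arriving by ambulance
  j: 2.485                  # thousands of RACF beds in the catchment
unit_costs:
  k: 193                    # AU$ per ED bed-hour
  l: 70                     # AU$ per inpatient bed-hour
  m: 679                    # AU$ per ambulance incident
distributions:
  a: {kind: poisson, se: 6.58}     # se used only by the alternative normal sampler
  b: {kind: poisson, se: 7.11}
  c: {kind: gamma_mom, se: 1.06}
  d: {kind: gamma_mom, se: 23.28}
  e: {kind: normal, se: 7.09}
  f: {kind: normal, se: 7.35}
  g: {kind: normal, se: 0.99}
  h: {kind: normal, se: 17.09}
  i: {kind: uniform, rel: 0.25}
  k: {kind: triangular, rel: 0.25}
  l: {kind: triangular, rel: 0.25}
  m: {kind: triangular, rel: 0.25}
  equipment_life: {kind: uniform, lo: 0.0, hi: 10.0}
  discount_rate: {kind: uniform, lo: 0.0, hi: 0.05}
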