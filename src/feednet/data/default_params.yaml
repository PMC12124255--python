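# Default parameterization for the feedlot net-return simulation.
#
# Distribution means/SDs are on the natural scale of each variable.
# Ordinal (cumulative-logit) entries are [location, scale] pairs on the
# log-odds scale, ordered from the highest-grade threshold downward
# (YG5..YG2 thresholds; Prime..Select thresholds).
# Health incidence rates are events per animal-day (reported per-1,000
# rates divided by 1,000).
parameters:
  corn_price: {mean: 6.00, sd: 1.10}        # $/bushel, log-normal
  live_price: {mean: 152.00, sd: 25.10}     # $/cwt, log-normal
  dmi: {mean: 10.5, sd: 0.58}               # kg/animal/day, normal
  ep1_fbw: {mean: 667.0, sd: 11.4}          # kg, normal
  ep1_hcw: {mean: 431.0, sd: 8.8}           # kg, normal
  live_gain: {mean: 1.32, sd: 0.06}         # kg/day, normal
  carcass_gain: {mean: 1.00, sd: 0.04}      # kg/day, normal
  within_pen_hcw_sd: 38.6                   # kg, fixed across pens and EPs
  heavy_threshold: 476.0                    # kg carcass weight
  mort_rate: 0.00009                        # per animal-day
  rem_rate: 0.00018                         # per animal-day
  morb_rate: 0.00029                        # per animal-day
  yg_intercepts:                            # EP1 thresholds: YG5, YG4, YG3, YG2
    - [-3.59, 0.170]
    - [-1.72, 0.167]
    - [0.15, 0.166]
    - [2.29, 0.170]
  yg_betas:                                 # proportional-odds shifts: EP2, EP3, EP4
    - [0.43, 0.081]
    - [0.73, 0.081]
    - [1.31, 0.081]
  qg_intercepts:                            # EP1 thresholds: Prime, Choice, Select
    - [-3.67, 0.332]
    - [0.82, 0.322]
    - [4.62, 0.362]
  qg_betas:                                 # shifts: EP2, EP3, EP4
    - [0.31, 0.067]
    - [0.52, 0.067]
    - [0.73, 0.067]
  dress_ratio: 0.63
  cwt_kg: 45.4                              # hundredweight in kg
  ton_kg: 907.0                             # dry US ton in kg
  dof_step: 14                              # days between endpoints
  pen_size: 200
  yg_grid: [-14.00, -10.00, 0.00, 2.00, 5.00]   # $/cwt, order YG5, YG4, YG3, YG2, YG1
  heavy_discount: -16.50                    # $/cwt for carcasses over heavy_threshold
  qg_grids:                                 # $/cwt, order Prime, Choice, Select, sub-Select
    - [15.75, 0.00, -5.00, -19.50]
    - [16.50, 0.00, -17.50, -31.00]
    - [22.75, 0.00, -30.00, -41.00]
  interest_rates: [0.05, 0.07, 0.09]        # yearly, simple interest
  treat_cost: 23.60                         # $ per morbidity event
  render_cost: 40.50                        # $ per mortality
  fyp_coeffs: [26.80, 71.64, -2.97]         # feed+yardage $/ton as quadratic in corn $/bu
  cow_coeffs: [-27.18, 1.30]                # cull cow $/cwt as linear in live price
  cull_factor: 0.92                         # removal price = cull cow price x 0.92
  prime_coeffs: [17.05, 0.35, 0.02]         # Prime premium as quadratic in Select discount
  subselect_coeffs: [-14.61, 1.00, 0.004]   # sub-Select discount as quadratic in Select discount

# PLACEHOLDER correlation matrices.  The published within-variable matrices
# (live prices across endpoints, grade intercepts, grade shift coefficients)
# live in the source study's supplementary material and are not shipped here;
# these stand-ins encode the qualitative structure only (adjacent endpoints /
# thresholds most correlated, decaying with distance).  Override them with the
# published values for a faithful reproduction of tail spreads.
correlations:
  placeholder: true
  fbw_hcw_ep1:
    - [1.0, 0.9]
    - [0.9, 1.0]
  gains:
    - [1.0, 0.9]
    - [0.9, 1.0]
  live_price_eps:                           # AR(1), adjacent rho = 0.95
    - [1.0, 0.95, 0.9025, 0.857375]
    - [0.95, 1.0, 0.95, 0.9025]
    - [0.9025, 0.95, 1.0, 0.95]
    - [0.857375, 0.9025, 0.95, 1.0]
  yg_intercepts:                            # decay, adjacent rho = 0.8
    - [1.0, 0.8, 0.64, 0.512]
    - [0.8, 1.0, 0.8, 0.64]
    - [0.64, 0.8, 1.0, 0.8]
    - [0.512, 0.64, 0.8, 1.0]
  qg_intercepts:
    - [1.0, 0.8, 0.64]
    - [0.8, 1.0, 0.8]
    - [0.64, 0.8, 1.0]
  yg_betas:
    - [1.0, 0.8, 0.64]
    - [0.8, 1.0, 0.8]
    - [0.64, 0.8, 1.0]
  qg_betas:
    - [1.0, 0.8, 0.64]
    - [0.8, 1.0, 0.8]
    - [0.64, 0.8, 1.0]
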