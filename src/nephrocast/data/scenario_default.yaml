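# Default projection scenario: 2016 baseline, 16-year horizon, 18.7% of
# patients glycemically controlled (lower-bound rates), remainder at
# upper-bound rates; cohort sizes default to the shipped national series.
start_year: 2016
horizon_years: 16
control_fraction: 0.187
rate_policy_controlled: min
rate_policy_uncontrolled: max
n_sim: auto
error_bound: 10000
seed: 20160101
init_mode: carry_deaths
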