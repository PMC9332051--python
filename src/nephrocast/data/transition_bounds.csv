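# Annual nephropathy transition probabilities (percent), UKPDS 95% CI bounds
from_state,to_state,p_min_pct,p_max_pct
NORMO,MICRO,1.9,2.2
MICRO,MACRO,2.5,3.2
MACRO,ESRD,1.5,3.0
NORMO,DEATH_CV,1.3,1.5
MICRO,DEATH_CV,2.6,3.4
MACRO,DEATH_CV,3.6,5.7
ESRD,DEATH_CV,14.0,24.4
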