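# Synthetic-truth parameter set shipped with the package.
# Rates per day, volumes mm^3, Km in uM.  dG encodes a 3-day Gem
# half-life (ln 2 / 3).  This set generates every synthetic cohort used
# by the tests and analysis scripts.
pC: 0.32
Cmax: 1000.0
kTC: 0.05
kGC: 0.25
Km: 160.0
nCT: 0.003
sMT: 0.04
dT: 0.10
kGT: 0.10
rCM: 0.10
sTM: 0.01
dM: 2.0
kGM: 0.5
dG: 0.23104906018664842
T0: 0.05
M0: 0.5
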