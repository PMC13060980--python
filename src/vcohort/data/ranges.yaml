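# Sampling and fitting ranges (lower, upper) per parameter.
# rCM spans 0-0.5, wider than the 0.088-0.176 range measured in vitro
# for bladder-cancer-mediated MDSC recruitment, so the accept-or-reject
# screen (not the prior) decides which recruitment rates are plausible.
pC: [0.05, 1.0]
Cmax: [200.0, 3000.0]
kTC: [0.0, 0.3]
kGC: [0.0, 1.0]
Km: [50.0, 500.0]
nCT: [0.0, 0.01]
sMT: [0.0, 0.2]
dT: [0.01, 0.5]
kGT: [0.0, 0.5]
rCM: [0.0, 0.5]
sTM: [0.0, 0.1]
dM: [0.5, 5.0]
kGM: [0.0, 1.0]
dG: [0.1, 0.5]
T0: [0.0, 0.5]
M0: [0.0, 2.0]
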