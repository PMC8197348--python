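feature,nca_rank,p_value,published_decision
BSR,18,0.0005,excluded
Magnitude,11,0.0005,selected
SynchFastSlow,17,0.264,excluded
BetaR,4,0.864,excluded_after_ttest
DeltaR,5,0.0005,selected
DAR,7,0.0005,selected
DTABR,6,0.0005,selected
BcSEF,1,0.0005,selected
ExtraPR,19,0.675,excluded
AlphaPR,12,0.439,excluded
BetaPR,16,0.0005,excluded
DeltaPR,3,0.014,selected
ThetaPR,15,0.0005,excluded
GammaPR,13,0.001,excluded
ShannonEntropy,14,0.607,excluded
LogEnergyEntropy,10,0.0005,selected
SpectralEntropy,2,0.013,selected
RenyiEntropy,8,0.0005,selected
Ratio05,20,0.0005,excluded
BG_AlphaPlus,9,0.0005,selected
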