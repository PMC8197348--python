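model,accuracy,sensitivity,specificity,precision,f1,auc
LR,0.840,0.782,0.906,0.903,0.838,0.933
SVM,0.853,0.807,0.906,0.906,0.853,0.909
KNN,0.813,0.689,0.953,0.943,0.796,0.934
RF,0.827,0.748,0.915,0.908,0.820,0.915
MLP,0.836,0.798,0.877,0.880,0.837,0.924
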