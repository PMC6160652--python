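channel,mni_x,mni_y,mni_z,region,probability
CH01,50,43,26,45 - pars triangularis Broca's area,0.88
CH02,42,51,27,46 - Dorsolateral prefrontal cortex,0.74
CH03,32,57,29,46 - Dorsolateral prefrontal cortex,0.86
CH04,50,50,7,46 - Dorsolateral prefrontal cortex,0.80
CH05,44,59,9,46 - Dorsolateral prefrontal cortex; 10 - Frontopolar area,0.56
CH06,36,65,11,10 - Frontopolar area,0.89
CH07,-18,62,32,10 - Frontopolar area; 46 - Dorsolateral prefrontal cortex,0.48
CH08,-29,56,30,46 - Dorsolateral prefrontal cortex,0.91
CH09,-42,49,27,46 - Dorsolateral prefrontal cortex,0.61
CH10,-20,71,13,10 - Frontopolar area,1
CH11,-32,65,10,10 - Frontopolar area,0.86
CH12,-43,56,7,46 - Dorsolateral prefrontal cortex,0.71
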