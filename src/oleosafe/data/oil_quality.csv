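name,value,sd,units
peroxide_index,16.61,0.2,mEq/kg
iodine_index,131.53,0.1,g I2/100 g
acidity_index,0.54,0.0,mg KOH/g
saponification_index,141.80,1.92,mg KOH/g
relative_density,0.92,0.1,20C
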