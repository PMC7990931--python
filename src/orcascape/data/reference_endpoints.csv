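label,mean_d18o_p,sd_d18o_p
ECA-beluga,17.38,0.69
GoM-dolphin,18.82,0.86
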