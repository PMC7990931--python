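specimen_id,d18o_marine,se,d13c_sc_suess,suess_swapped,suess_excluded
ECA-AB-1948,-2.27,0.79,-14.66,0,0
ECA-CS-1977-1,-3.35,1.06,-12.36,0,0
ECA-CS-1977-2,-1.80,0.69,-14.75,0,0
ECA-CS-1977-3,1.11,0.56,-15.02,0,0
ECA-BL-1978,-1.56,0.64,-14.12,0,0
ECA-RB-2009,-0.33,0.47,-13.47,0,0
ECA-CH-2011,-3.44,1.08,-13.64,0,0
ECA-SQ-2016-1,-2.46,0.84,-14.56,0,0
ECA-SQ-2016-2,-2.52,0.85,-15.09,0,0
ECA-SQ-2016-3,-2.16,0.77,-14.80,0,0
NWA-CB-1971-2,-0.35,0.47,-13.40,0,0
NWA-CB-1971-1,-0.32,0.47,-13.80,0,0
NWA-SC-1975-1,-1.37,0.60,-14.34,0,0
NWA-SC-1975-2,-1.37,0.60,-13.35,0,0
NWA-SI-1977,-1.74,0.67,-14.45,0,0
NWA-BB-2002,-1.79,0.69,-11.47,1,0
NWA-BP-1998,4.53,1.37,-13.90,1,0
GRL-M1647,-1.37,0.60,-14.96,0,1
GRL-M1648,-1.98,0.72,-14.06,0,1
DNK-CN89,-2.16,0.77,-15.80,0,1
DNK-MCE1068,-1.19,0.57,-14.81,0,1
DNK-M1646,-1.77,0.68,-15.13,0,1
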