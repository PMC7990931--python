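specimen_id,region,tissue,year_of_death,age_years,d18O_p,d13C_sc,stranding_group
ECA-AB-1948,ECA,dentine,1948,17,16.89,-12.97,
ECA-CS-1977-1,ECA,dentine,1977,4,16.02,-11.49,CS-1977
ECA-CS-1977-2,ECA,dentine,1977,18,17.27,-13.71,CS-1977
ECA-CS-1977-3,ECA,dentine,1977,,19.63,-14.19,CS-1977
ECA-BL-1978,ECA,dentine,1978,17,17.47,-13.12,
ECA-RB-2009,ECA,dentine,2009,28,18.46,-13.06,
ECA-CH-2011,ECA,dentine,2011,35,15.94,-13.19,
ECA-SQ-2016-1,ECA,dentine,2016,6,16.74,-14.56,SQ-2016
ECA-SQ-2016-2,ECA,dentine,2016,34,16.69,-14.77,SQ-2016
ECA-SQ-2016-3,ECA,dentine,2016,8,16.98,-14.78,SQ-2016
NWA-CB-1971-2,NWA,dentine,1971,29,18.45,-12.10,CB-1971
NWA-CB-1971-1,NWA,dentine,1971,31,18.47,-12.48,CB-1971
NWA-SC-1975-1,NWA,dentine,1975,20,17.62,-13.24,SC-1975
NWA-SC-1975-2,NWA,dentine,1975,23,17.62,-12.21,SC-1975
NWA-SI-1977,NWA,dentine,1977,13,17.32,-13.47,
NWA-BB-2002,NWA,dentine,2002,3,17.28,-13.61,
NWA-BP-1998,NWA,dentine,1998,5,22.40,-11.07,
GRL-M1647,Greenland,bone,2014,,17.62,-13.80,
GRL-M1648,Greenland,bone,2014,,17.13,-14.70,
DNK-CN89,Denmark,bone,1980,,16.98,-14.03,
DNK-MCE1068,Denmark,bone,1995,,17.77,-14.11,
DNK-M1646,Denmark,bone,2007,,17.30,-14.70,
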