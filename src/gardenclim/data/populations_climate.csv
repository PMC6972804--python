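population,climate_zone,latitude,longitude,T_MAX,P_MA,AI_inv,P_DM,ds1_families,ds1_total,ds2_families,ds2_total
HRI,warm-dry,-30.3114,115.2016,31.7,563,2.56,4,9,110,9,36
MOG,warm-dry,-31.0986,116.0509,33.3,579,2.56,10,,,10,40
LUP,warm-dry,-32.5207,116.4990,31.6,635,2.22,12,,,9,40
SER,warm-wet,-32.3527,116.0764,30.5,1173,1.12,12,11,123,11,44
CHID,warm-wet,-31.8682,116.2229,32.2,900,1.54,12,,,10,40
PEE,warm-wet,-32.6846,115.7427,30.4,885,1.49,10,,,8,40
CRI,cool-dry,-34.6015,118.7427,26.2,579,2.08,20,8,99,8,32
KIN,cool-dry,-34.0812,116.3304,27.7,820,1.49,19,,,10,40
PLA,cool-dry,-34.6534,117.4991,26.7,733,1.59,25,,,10,40
BOO,cool-wet,-34.6389,116.1238,25.6,1159,0.95,24,11,136,10,40
CAR,cool-wet,-34.4196,115.8213,25.9,1106,1.02,20,,,10,40
BRA,cool-wet,-33.9164,115.0833,26.1,1072,1.04,11,,,9,40
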