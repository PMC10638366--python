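location,nitrate_umol_kg,water_depth_m,salinity,oxygen_umol_kg,temperature_c
Costa Rica (SO206-43-MUC),39.1,568,34.69,9.53,7.47
Sagami Bay push core (Japan),42.2,1410,34.50,56.40,2.30
M77/1-455/MUC-21 (OMZ Peru),34.0,465,34.64,2.42,8.12
M77/1-565/MUC-60 (OMZ Peru),40.1,640,34.56,8.17,6.70
M77/1-445/MUC-15 (OMZ Peru),40.8,928,34.56,36.77,4.76
M77/1-487/MUC-39 (OMZ Peru),38.8,579,34.55,3.70,7.21
M77/1-459/MUC-25 (OMZ Peru),41.0,698,34.57,12.55,6.68
M77/1-604/MUC-74 (OMZ Peru),40.8,878,34.53,34.23,5.72
M77/1-516/MUC-40 (OMZ Peru),36.1,513,34.60,2.40,8.05
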