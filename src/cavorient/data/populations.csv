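site,state,latitude_deg,longitude_deg,mean_dir_deg,r
Three Lakes,FL,27.95,-81.14,255,0.47
Osceola,FL,28.06,-80.97,242,0.45
Baker,FL,30.66,-84.21,243,0.39
Lay,TX,31.45,-95.43,265,0.29
Jones and Ott,GA,32.89,-84.18,250,0.54
Hopkins and Lynn,SC,33.8,-80.72,271,0.34
Dennis,SC,33.82,-78.68,279,0.55
Wood,OK,34.5,-94.64,290,0.45
Lejeune,NC,34.6,-77.37,265,0.42
Sandhills,NC,35.22,-79.41,269,0.27
Kalisz and Boettcher,KY,36.8,-84.3,285,0.28
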