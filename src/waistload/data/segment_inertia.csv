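segment,centroid_position_mm,relative_position_pct,relative_mass_pct
Neck,117.8,46.9,8.62
Upper trunk,115.6,53.6,16.82
Lower trunk,177.8,40.3,27.23
Thigh,254.5,45.3,14.19
A lower leg,224.1,39.3,3.67
Upper arm,163.3,47.8,2.43
Forearm,136.6,42.4,1.25
Hand,114.2,36.6,0.64
Foot,38.2,48.6,1.48
Whole,734.2,43.8,
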