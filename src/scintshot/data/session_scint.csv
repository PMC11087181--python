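label,radius_mm,laser_dx_mm,laser_dy_mm,imaging_dx_mm,imaging_dy_mm,calibrated
1,0.21,-0.83,-0.42,-0.36,0.27,false
2,0.55,-0.77,-0.61,0.11,0.11,false
3,0.16,-0.97,-0.44,-0.16,-0.12,false
4,0.28,-0.87,-0.17,-0.52,0.13,false
5,0.23,-1.09,-0.32,-0.21,0.33,false
1,0.20,-0.90,-0.43,-0.43,0.25,true
2,0.54,-0.81,-0.61,0.07,0.15,true
3,0.12,-1.01,-0.38,-0.22,-0.05,true
4,0.24,-0.91,-0.10,-0.54,0.15,true
5,0.20,-1.11,-0.28,-0.21,0.36,true
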