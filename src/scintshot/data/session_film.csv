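label,radius_mm,laser_dx_mm,laser_dy_mm,imaging_dx_mm,imaging_dy_mm,calibrated
1,0.57,-0.65,-0.85,,,false
2,0.42,-0.23,-1.11,,,false
3,0.40,-0.65,-0.95,,,false
4,0.41,-0.65,-0.98,,,false
5,0.26,-0.17,-0.95,,,false
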