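label,sigma,eps_r,rho,c,k,q_m,w
muscle,0.61,203,1090,3421,0.49,0.91,36.7
fat_subcutaneous,0.05,33,911,2348,0.21,0.51,32.7
fat_other,0.05,33,911,2348,0.21,0.51,32.7
bone,0.04,43,1908,1312,0.32,0.15,10.0
tumor,0.61,203,1090,3421,0.49,0.91,36.7
igc_bolus,6.31,82,1000,4180,6,0,0
air,0,1,1.2,,,,
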