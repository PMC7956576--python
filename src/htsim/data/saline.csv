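concentration_pct,temperature_c,sigma,eps_r,rho
5,10,6.31,82,1000
0.1,5,0.11,85,1000
0.5,5,0.57,85,1000
1,5,1.10,85,1000
5,5,5.58,84,1000
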