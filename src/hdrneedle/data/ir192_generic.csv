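# Generic Ir-192 HDR source, 1-D point-source TG-43 data.
# Values rounded from published consensus data for common Ir-192 HDR
# sources (AAPM TG-43U1, Rivard et al., Med Phys 31:633-674, 2004);
# adequate for a generic engine, not a commissioning dataset.
# dose_rate_constant_cgy_per_h_u = 1.109
# reference_r0_mm = 10.0
# columns: r_mm, radial_dose_g, anisotropy_phi
r_mm,g,phi
2.5,0.994,0.932
5.0,0.998,0.952
10.0,1.000,0.962
15.0,1.001,0.967
20.0,1.001,0.971
30.0,0.999,0.975
40.0,0.996,0.978
50.0,0.990,0.980
60.0,0.982,0.982
80.0,0.958,0.984
100.0,0.925,0.985
120.0,0.885,0.986
150.0,0.815,0.987
200.0,0.675,0.988
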