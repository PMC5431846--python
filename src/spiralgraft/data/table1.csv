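config,group,shape,L1_over_D,L2_over_D,orientations_deg,count,H_over_D,is_reference,pressure_drop_Pa,vyz_plane3_mm_per_s,wss_mean_Pa,recirculation_plane1_pct,recirculation_plane2_pct
elliptical_height,cross_section,elliptical,0.3,0.197,180,1,14.42,0,565.68,5.95,2.307,7.38,8.71
circular,cross_section,circular,0.25,0.25,180,1,14.42,1,550.34,5.01,2.295,7.63,12.07
elliptical_width,cross_section,elliptical,0.2,0.385,180,1,14.42,0,535.49,5.41,2.290,7.78,13.51
teo_0,orientation,circular,0.25,0.25,0,1,14.42,0,531.13,9.37,2.283,4.59,5.03
teo_90,orientation,circular,0.25,0.25,90,1,14.42,0,543.05,9.58,2.374,6.25,3.82
teo_180,orientation,circular,0.25,0.25,180,1,14.42,0,550.34,5.01,2.295,7.63,12.07
teo_270,orientation,circular,0.25,0.25,270,1,14.42,0,545.86,22.00,2.432,5.31,3.52
single,count,circular,0.25,0.25,180,1,14.42,0,550.34,5.01,2.295,7.63,12.07
double,count,circular,0.174,0.174,0;180,2,14.42,0,546.29,6.87,2.276,6.70,10.83
triple,count,circular,0.141,0.141,60;180;300,3,14.42,0,547.32,11.46,2.256,6.40,4.71
pitch_plus20,pitch,circular,0.25,0.25,180,1,17.31,0,559.31,5.24,2.310,7.47,11.35
pitch_ref,pitch,circular,0.25,0.25,180,1,14.42,0,550.34,5.01,2.295,7.63,12.07
pitch_minus20,pitch,circular,0.25,0.25,180,1,11.54,0,537.99,6.45,2.281,7.56,11.76
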