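patient_id,mitral_e_vel_cm_s,mitral_a_vel_cm_s,e_a_ratio,septal_e_prime_cm_s,lateral_e_prime_cm_s,e_over_e_prime_mean,tr_peak_vel_m_s,la_volume_index_ml_m2,las_r_pct,lv_gls_pct,lvef_pct,pcwp_mmhg
FIX000,45.0,64.0,,8.0,11.0,,2.5,30.0,25.0,18.0,62.0,17.0
FIX001,45.0,64.0,,8.0,11.0,,2.5,30.0,25.0,18.0,62.0,9.0
FIX002,45.0,64.0,,8.0,11.0,,2.5,30.0,25.0,18.0,62.0,
FIX003,50.0,,0.8,6.0,9.0,,3.0,40.0,15.0,14.0,60.0,17.0
FIX004,50.0,,0.8,6.0,9.0,,3.0,40.0,15.0,14.0,60.0,9.0
FIX005,50.0,,0.8,6.0,9.0,,3.0,40.0,15.0,14.0,60.0,
FIX006,60.0,,0.7,,,15.0,2.7,40.0,25.0,17.0,63.0,17.0
FIX007,60.0,,0.7,,,15.0,2.7,40.0,25.0,17.0,63.0,9.0
FIX008,60.0,,0.7,,,15.0,2.7,40.0,25.0,17.0,63.0,
FIX009,,,0.7,,,10.0,2.0,20.0,30.0,21.0,66.0,17.0
FIX010,,,0.7,,,10.0,2.0,20.0,30.0,21.0,66.0,9.0
FIX011,,,0.7,,,10.0,2.0,20.0,30.0,21.0,66.0,
FIX012,100.0,,2.0,7.0,10.0,10.0,2.0,20.0,30.0,19.0,64.0,17.0
FIX013,100.0,,2.0,7.0,10.0,10.0,2.0,20.0,30.0,19.0,64.0,9.0
FIX014,100.0,,2.0,7.0,10.0,10.0,2.0,20.0,30.0,19.0,64.0,
FIX015,120.0,48.0,,5.0,8.0,,3.5,45.0,10.0,12.0,55.0,17.0
FIX016,120.0,48.0,,5.0,8.0,,3.5,45.0,10.0,12.0,55.0,9.0
FIX017,120.0,48.0,,5.0,8.0,,3.5,45.0,10.0,12.0,55.0,
FIX018,80.0,,,6.0,9.0,,3.0,40.0,20.0,16.0,61.0,17.0
FIX019,80.0,,,6.0,9.0,,3.0,40.0,20.0,16.0,61.0,9.0
FIX020,80.0,,,6.0,9.0,,3.0,40.0,20.0,16.0,61.0,
FIX021,78.0,65.0,,6.6,9.2,,2.9,30.0,22.0,18.0,62.0,17.0
FIX022,78.0,65.0,,6.6,9.2,,2.9,30.0,22.0,18.0,62.0,9.0
FIX023,78.0,65.0,,6.6,9.2,,2.9,30.0,22.0,18.0,62.0,
FIX024,78.0,60.0,,6.6,9.2,,2.9,40.0,15.0,15.0,58.0,17.0
FIX025,78.0,60.0,,6.6,9.2,,2.9,40.0,15.0,15.0,58.0,9.0
FIX026,78.0,60.0,,6.6,9.2,,2.9,40.0,15.0,15.0,58.0,
FIX027,100.0,80.0,,5.0,7.0,,,40.0,15.0,13.0,57.0,17.0
FIX028,100.0,80.0,,5.0,7.0,,,40.0,15.0,13.0,57.0,9.0
FIX029,100.0,80.0,,5.0,7.0,,,40.0,15.0,13.0,57.0,
FIX030,100.0,80.0,,5.0,7.0,,,30.0,15.0,14.0,59.0,17.0
FIX031,100.0,80.0,,5.0,7.0,,,30.0,15.0,14.0,59.0,9.0
FIX032,100.0,80.0,,5.0,7.0,,,30.0,15.0,14.0,59.0,
FIX033,100.0,80.0,,5.0,7.0,,,30.0,25.0,20.0,65.0,17.0
FIX034,100.0,80.0,,5.0,7.0,,,30.0,25.0,20.0,65.0,9.0
FIX035,100.0,80.0,,5.0,7.0,,,30.0,25.0,20.0,65.0,
FIX036,100.0,80.0,,5.0,7.0,,,30.0,,18.0,62.0,17.0
FIX037,100.0,80.0,,5.0,7.0,,,30.0,,18.0,62.0,9.0
FIX038,100.0,80.0,,5.0,7.0,,,30.0,,18.0,62.0,
FIX039,90.0,70.0,,,,,,,15.0,,60.0,17.0
FIX040,90.0,70.0,,,,,,,15.0,,60.0,9.0
FIX041,90.0,70.0,,,,,,,15.0,,60.0,
FIX042,90.0,70.0,,,,16.0,,,15.0,15.0,58.0,17.0
FIX043,90.0,70.0,,,,16.0,,,15.0,15.0,58.0,9.0
FIX044,90.0,70.0,,,,16.0,,,15.0,15.0,58.0,
FIX045,60.0,80.0,,6.0,11.0,,2.8,34.0,18.0,17.0,62.0,17.0
FIX046,60.0,80.0,,6.0,11.0,,2.8,34.0,18.0,17.0,62.0,9.0
FIX047,60.0,80.0,,6.0,11.0,,2.8,34.0,18.0,17.0,62.0,
FIX048,85.0,75.0,,6.0,9.0,,3.0,40.0,25.0,19.0,64.0,17.0
FIX049,85.0,75.0,,6.0,9.0,,3.0,40.0,25.0,19.0,64.0,9.0
FIX050,85.0,75.0,,6.0,9.0,,3.0,40.0,25.0,19.0,64.0,
FIX051,70.0,60.0,,8.0,9.5,,2.7,36.0,17.0,18.0,63.0,17.0
FIX052,70.0,60.0,,8.0,9.5,,2.7,36.0,17.0,18.0,63.0,9.0
FIX053,70.0,60.0,,8.0,9.5,,2.7,36.0,17.0,18.0,63.0,
FIX054,55.0,70.0,,7.2,10.5,,,,,19.0,65.0,17.0
FIX055,55.0,70.0,,7.2,10.5,,,,,19.0,65.0,9.0
FIX056,55.0,70.0,,7.2,10.5,,,,,19.0,65.0,
FIX057,95.0,50.0,,4.0,6.0,,3.1,50.0,8.0,10.0,52.0,17.0
FIX058,95.0,50.0,,4.0,6.0,,3.1,50.0,8.0,10.0,52.0,9.0
FIX059,95.0,50.0,,4.0,6.0,,3.1,50.0,8.0,10.0,52.0,
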