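# Synthetic default muscle parameter table for the 15-actuator planar
# upper-extremity model. Magnitudes are literature-plausible for a 50th
# percentile adult male (Saul/Holzbaur scale) but are NOT reproduced from
# any published model; moment arms are constant in-plane equivalents.
# Moment-arm sign: positive = muscle shortens as the joint angle increases.
name,F_iso_max_N,L_opt_m,L_slack_m,penn_deg,r_shoulder_m,r_elbow_m,r_wrist_m
Delt1,1100.0,0.098,0.093,22.0,0.019,0.0,0.0
Delt2,1140.0,0.108,0.095,15.0,0.006,0.0,0.0
Delt3,260.0,0.137,0.038,18.0,-0.019,0.0,0.0
BicLong,625.0,0.116,0.272,0.0,0.015,0.036,0.0
BicShort,435.0,0.132,0.192,0.0,0.010,0.036,0.0
TriLong,800.0,0.134,0.143,12.0,-0.015,-0.021,0.0
TriLat,625.0,0.114,0.098,9.0,0.0,-0.021,0.0
Bracs,990.0,0.086,0.054,0.0,0.0,0.018,0.0
FCR,74.0,0.063,0.244,3.0,0.0,0.008,0.015
FCU,129.0,0.051,0.265,12.0,0.0,0.006,0.016
PecM,1180.0,0.140,0.090,17.0,0.020,0.0,0.0
SUPRA,500.0,0.068,0.040,7.0,0.005,0.0,0.0
SUBSC,1000.0,0.087,0.033,20.0,-0.005,0.0,0.0
INFRA,900.0,0.076,0.031,19.0,-0.006,0.0,0.0
TMIN,270.0,0.074,0.070,24.0,-0.004,0.0,0.0
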