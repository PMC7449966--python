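# Liver optical properties, 10-nm nodes, 360-1000 nm.
# Pinned reference table assembled from published liver compilations:
# absorption reflects an in-vivo well-perfused liver (hemoglobin
# Soret/Q bands damped by vessel packaging, NIR plateau ~1.3 1/cm,
# water rise past 950 nm); reduced scattering
# follows the power law 13*(lambda/500)^-1.2 1/cm; anisotropy rises
# from 0.88 to 0.95 across the band; refractive index 1.40->1.37.
# Columns: wavelength_nm, mua_1_cm, mus_1_cm, g, n (mus is the full
# scattering coefficient; reduced scattering = mus*(1-g)).
wavelength_nm,mua_1_cm,mus_1_cm,g,n
360,45,154.67,0.8753,1.4020
370,47.495,151.08,0.8765,1.4015
380,50,147.71,0.8777,1.4010
390,52.158,144.56,0.8788,1.4005
400,55,141.6,0.8800,1.4000
410,62,138.81,0.8812,1.3995
420,58,136.19,0.8823,1.3990
430,48,133.73,0.8835,1.3985
440,36,131.4,0.8847,1.3980
450,30,129.22,0.8858,1.3975
460,24,127.15,0.8870,1.3970
470,19,125.2,0.8882,1.3965
480,15,123.37,0.8893,1.3960
490,13,121.63,0.8905,1.3955
500,12,120,0.8917,1.3950
510,12.3,118.46,0.8928,1.3945
520,13,117,0.8940,1.3940
530,15,115.63,0.8952,1.3935
540,17,114.34,0.8963,1.3930
550,16,113.12,0.8975,1.3925
560,14.5,111.98,0.8987,1.3920
570,16.5,110.9,0.8998,1.3915
580,17,109.89,0.9010,1.3910
590,10,108.94,0.9022,1.3905
600,5.5,108.06,0.9033,1.3900
610,4.5,107.23,0.9045,1.3895
620,3.8,106.46,0.9057,1.3890
630,3.4,105.74,0.9068,1.3885
640,3.1,105.08,0.9080,1.3880
650,2.8,104.46,0.9092,1.3875
660,2.5,103.9,0.9103,1.3870
670,2.3,103.39,0.9115,1.3865
680,2.1,102.92,0.9127,1.3860
690,1.9,102.51,0.9138,1.3855
700,1.7,102.13,0.9150,1.3850
710,1.608,101.81,0.9162,1.3845
720,1.55,101.53,0.9173,1.3840
730,1.5101,101.29,0.9185,1.3835
740,1.4797,101.1,0.9197,1.3830
750,1.45,100.95,0.9208,1.3825
760,1.4161,100.84,0.9220,1.3820
770,1.381,100.78,0.9232,1.3815
780,1.3479,100.76,0.9243,1.3810
790,1.3199,100.79,0.9255,1.3805
800,1.3,100.86,0.9267,1.3800
810,1.2852,100.97,0.9278,1.3795
820,1.2716,101.13,0.9290,1.3790
830,1.2604,101.33,0.9302,1.3785
840,1.2528,101.58,0.9313,1.3780
850,1.25,101.88,0.9325,1.3775
860,1.25,102.23,0.9337,1.3770
870,1.25,102.63,0.9348,1.3765
880,1.25,103.07,0.9360,1.3760
890,1.25,103.57,0.9372,1.3755
900,1.25,104.13,0.9383,1.3750
910,1.2591,104.74,0.9395,1.3745
920,1.2834,105.41,0.9407,1.3740
930,1.3182,106.13,0.9418,1.3735
940,1.3589,106.92,0.9430,1.3730
950,1.4,107.78,0.9442,1.3725
960,1.4594,108.71,0.9453,1.3720
970,1.5,109.71,0.9465,1.3715
980,1.4981,110.78,0.9477,1.3710
990,1.485,111.93,0.9488,1.3705
1000,1.45,113.17,0.9500,1.3700
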