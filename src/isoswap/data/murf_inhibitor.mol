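murf_inhibitor_synthetic
     RDKit          3D
  synthetic reconstruction of a sulfonamide MurF inhibitor (3 rings + SO2NH linker)
 27 30  0  0  0  0  0  0  0  0999 V2000
    0.4205   -0.1836    4.1009 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.4329    0.8593    3.0953 S   0  0  0  0  0  0  0  0  0  0  0  0
    0.8657    2.2027    3.4101 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1300    0.8869    2.4347 N   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3401    1.7302    1.2927 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2908    3.1185    1.4083 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4640    3.9094    0.2729 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3895    5.6243    0.4665 Cl  0  0  0  0  0  0  0  0  0  0  0  0
   -1.6945    3.3059   -0.9689 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.9281    4.2260   -2.4142 Cl  0  0  0  0  0  0  0  0  0  0  0  0
   -1.7549    1.9095   -1.0766 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5757    1.0979    0.0487 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.6513   -0.3103    0.0107 N   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0355   -0.8258    0.2140 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.5167   -1.6478   -0.9924 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.6558   -2.7521   -1.3084 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2625   -2.4768   -1.0864 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.9320   -0.9772   -1.1025 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5478    0.2298    1.8550 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0105   -1.0477    1.6136 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.8761   -1.1287    0.4749 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.5344   -2.2395   -0.1041 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.3355   -2.0738   -1.2378 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.4949   -0.8174   -1.8058 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.8598    0.2975   -1.2543 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0527    0.1260   -0.1133 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.1785    1.3448    0.7310 S   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  2  0
  2  4  1  0
  4  5  1  0
  5  6  2  0
  6  7  1  0
  7  8  1  0
  7  9  2  0
  9 10  1  0
  9 11  1  0
 11 12  2  0
 12 13  1  0
 13 14  1  0
 14 15  1  0
 15 16  1  0
 16 17  1  0
 17 18  1  0
  2 19  1  0
 19 20  2  0
 20 21  1  0
 21 22  2  0
 22 23  1  0
 23 24  2  0
 24 25  1  0
 25 26  2  0
 26 27  1  0
 12  5  1  0
 18 13  1  0
 27 19  1  0
 26 21  1  0
M  END
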