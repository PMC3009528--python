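# Synthetic reference frame for complex standardization.
# Generated by pm13.fixtures.reference_frame_text(); regenerate with
#   python -c 'import pm13.fixtures as f; print(f.reference_frame_text())'
# Sections: sequences and CA coordinates (position x y z, Angstrom).
>ALPHA_SEQ
DSCYTRDISTASDQEGICAFPVCNWQFAPIIIDQWKQYRLGTCVEIEYCEEEQCMPPLVK
SHFEIEATTTPYSN
>BETA_SEQ
CVYAVVERLMWRFKAGAAHGRKTKYDMYNNHELTAFLCMVTSVPDCAEHWNQMQIRYIAS
SHWTDERTPVGKHIFIWTLEQFNMMCC
>PEPTIDE_SEQ
CWVIPSNPEDVWH
>ALPHA_CA
5 -47.400000 4.300000 0.000000
6 -43.600000 4.300000 0.626662
7 -39.800000 4.300000 0.779078
8 -36.000000 4.300000 0.341904
9 -32.200000 4.300000 -0.354016
10 -28.400000 4.300000 -0.782024
11 -24.600000 4.300000 -0.618212
12 -20.800000 4.300000 0.013451
13 -17.000000 4.300000 0.634934
14 -13.200000 4.300000 0.775912
15 -9.400000 4.300000 0.329695
16 -5.600000 4.300000 -0.366029
17 -1.800000 4.300000 -0.784749
18 2.000000 4.300000 -0.609587
19 5.800000 4.300000 0.026898
20 9.600000 4.300000 0.643028
21 13.400000 4.300000 0.772526
22 17.200000 4.300000 0.317392
23 21.000000 4.300000 -0.377938
24 24.800000 4.300000 -0.787252
25 28.600000 4.300000 -0.600790
26 32.400000 4.300000 0.040338
27 36.200000 4.300000 0.650939
28 40.000000 4.300000 0.768922
29 43.800000 4.300000 0.305000
30 47.600000 4.300000 -0.389740
31 51.400000 4.300000 -0.789532
32 55.200000 4.300000 -0.591823
33 59.000000 4.300000 0.053766
34 62.800000 4.300000 0.658666
35 66.600000 4.300000 0.765101
36 70.400000 4.300000 0.292522
37 74.200000 4.300000 -0.401431
38 78.000000 4.300000 -0.791590
39 81.800000 4.300000 -0.582689
40 85.600000 4.300000 0.067180
41 89.400000 4.300000 0.666208
42 89.400000 8.100000 0.761063
43 85.600000 8.100000 0.279961
44 81.800000 8.100000 -0.413010
45 78.000000 8.100000 -0.793423
46 74.200000 8.100000 -0.573390
47 70.400000 8.100000 0.080574
48 66.600000 8.100000 0.673560
49 62.800000 8.100000 0.756810
50 59.000000 8.100000 0.267321
51 55.200000 8.100000 -0.424471
52 51.400000 8.100000 -0.795032
53 47.600000 8.100000 -0.563929
54 43.800000 8.100000 0.093945
55 40.000000 8.100000 0.680723
56 36.200000 8.100000 0.752343
57 32.400000 8.100000 0.254605
58 28.600000 8.100000 -0.435813
59 24.800000 8.100000 -0.796416
60 21.000000 8.100000 -0.554308
61 17.200000 8.100000 0.107290
62 13.400000 8.100000 0.687693
63 9.600000 8.100000 0.747664
64 5.800000 8.100000 0.241817
65 2.000000 8.100000 -0.447031
66 -1.800000 8.100000 -0.797576
67 -5.600000 8.100000 -0.544531
68 -9.400000 8.100000 0.120604
69 -13.200000 8.100000 0.694468
70 -17.000000 8.100000 0.742773
71 -20.800000 8.100000 0.228961
72 -24.600000 8.100000 -0.458123
73 -28.400000 8.100000 -0.798509
74 -32.200000 8.100000 -0.534599
75 -36.000000 8.100000 0.133885
76 -39.800000 8.100000 0.701047
77 -43.600000 8.100000 0.737672
78 -47.400000 8.100000 0.216041
>BETA_CA
5 -60.700000 -4.300000 0.770847
6 -56.900000 -4.300000 0.646797
7 -53.100000 -4.300000 0.033265
8 -49.300000 -4.300000 -0.605442
9 -45.500000 -4.300000 -0.785962
10 -41.700000 -4.300000 -0.371682
11 -37.900000 -4.300000 0.323880
12 -34.100000 -4.300000 0.774336
13 -30.300000 -4.300000 0.638790
14 -26.500000 -4.300000 0.019820
15 -22.700000 -4.300000 -0.614149
16 -18.900000 -4.300000 -0.783342
17 -15.100000 -4.300000 -0.359718
18 -11.300000 -4.300000 0.336134
19 -7.500000 -4.300000 0.777606
20 -3.700000 -4.300000 0.630602
21 0.100000 -4.300000 0.006371
22 3.900000 -4.300000 -0.622682
23 7.700000 -4.300000 -0.780501
24 11.500000 -4.300000 -0.347652
25 15.300000 -4.300000 0.348292
26 19.100000 -4.300000 0.780656
27 22.900000 -4.300000 0.622235
28 26.700000 -4.300000 -0.007081
29 30.500000 -4.300000 -0.631039
30 34.300000 -4.300000 -0.777439
31 38.100000 -4.300000 -0.335489
32 41.900000 -4.300000 0.360352
33 45.700000 -4.300000 0.783486
34 49.500000 -4.300000 0.613693
35 53.300000 -4.300000 -0.020531
36 57.100000 -4.300000 -0.639217
37 60.900000 -4.300000 -0.774157
38 64.700000 -4.300000 -0.323230
39 68.500000 -4.300000 0.372311
40 72.300000 -4.300000 0.786094
41 76.100000 -4.300000 0.604977
42 79.900000 -4.300000 -0.033974
43 83.700000 -4.300000 -0.647215
44 87.500000 -4.300000 -0.770656
45 91.300000 -4.300000 -0.310880
46 95.100000 -4.300000 0.384164
47 98.900000 -4.300000 0.788480
48 102.700000 -4.300000 0.596091
49 102.700000 -8.100000 -0.047409
50 98.900000 -8.100000 -0.655030
51 95.100000 -8.100000 -0.766938
52 91.300000 -8.100000 -0.298442
53 87.500000 -8.100000 0.395908
54 83.700000 -8.100000 0.790643
55 79.900000 -8.100000 0.587035
56 76.100000 -8.100000 -0.060829
57 72.300000 -8.100000 -0.662660
58 68.500000 -8.100000 -0.763002
59 64.700000 -8.100000 -0.285920
60 60.900000 -8.100000 0.407541
61 57.100000 -8.100000 0.792583
62 53.300000 -8.100000 0.577814
63 49.500000 -8.100000 -0.074233
64 45.700000 -8.100000 -0.670102
65 41.900000 -8.100000 -0.758851
66 38.100000 -8.100000 -0.273317
67 34.300000 -8.100000 0.419058
68 30.500000 -8.100000 0.794298
69 26.700000 -8.100000 0.568429
70 22.900000 -8.100000 -0.087616
71 19.100000 -8.100000 -0.677355
72 15.300000 -8.100000 -0.754485
73 11.500000 -8.100000 -0.260636
74 7.700000 -8.100000 0.430457
75 3.900000 -8.100000 0.795789
76 0.100000 -8.100000 0.558884
77 -3.700000 -8.100000 -0.100973
78 -7.500000 -8.100000 -0.684416
79 -11.300000 -8.100000 -0.749906
80 -15.100000 -8.100000 -0.247882
81 -18.900000 -8.100000 0.441734
82 -22.700000 -8.100000 0.797055
83 -26.500000 -8.100000 0.549180
84 -30.300000 -8.100000 -0.114303
85 -34.100000 -8.100000 -0.691284
86 -37.900000 -8.100000 -0.745115
87 -41.700000 -8.100000 -0.235058
88 -45.500000 -8.100000 0.452886
89 -49.300000 -8.100000 0.798095
90 -53.100000 -8.100000 0.539322
91 -56.900000 -8.100000 -0.127600
>PEPTIDE_CA
308 0.000000 0.000000 1.600000
309 3.500000 0.000000 1.733681
310 7.000000 0.000000 1.721274
311 10.500000 0.000000 1.576338
312 14.000000 0.000000 1.457260
313 17.500000 0.000000 1.494169
314 21.000000 0.000000 1.646731
315 24.500000 0.000000 1.748225
316 28.000000 0.000000 1.687738
317 31.500000 0.000000 1.531370
318 35.000000 0.000000 1.450001
319 38.500000 0.000000 1.532553
320 42.000000 0.000000 1.688811
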