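index,label,type,Tc,Thr,Ttw,Fmax,Fmftf,meanfr,minfr,maxfr
1,S1,S,28,65.5,160,3.8,32.35,26.9,13,38.2
2,S2,S,24,54,120,5.1,64.96,43.7,17.5,58.9
3,S3,S,22,54,110,5.3,75.03,47.8,18.6,64
4,S4,S,24,53,120,5.5,67.64,39.5,16.4,53.7
5,S5,S,24,55,120,6.5,69.35,35.3,15.3,48.5
6,S6,S,24,61,150,6.5,48.6,31.1,14.1,43.3
7,S7,S,36,82,170,7.8,66.67,22.8,11.9,33
8,S8,S,21.5,46,121,11,38.4,52,19.7,69.2
9,FR1,FR,14,28,69.7,2.1,17.86,58.7,29.7,104
10,FR2,FR,12.3,22.3,50.5,3,26.19,72.2,36.1,129.6
11,FR3,FR,13,24,55.1,7.75,44.05,70.3,35.2,126
12,FR4,FR,15.8,33,85,8.1,45.33,43.4,22.4,74.7
13,FR5,FR,15.3,32.7,86,9,44.26,47.2,24.3,82
14,FR6,FR,16,34,81.8,10.2,50.55,41.5,21.5,71.1
15,FR7,FR,11.8,19.5,60,12.2,76.56,74.1,37,133.3
16,FR8,FR,19.5,41.3,107.8,12.9,50.18,33.8,17.9,56.4
17,FR9,FR,13,22.3,47.5,14.1,73.99,68.3,34.3,122.3
18,FR10,FR,20.8,42.5,99,14.2,46.52,31.9,17,52.7
19,FR11,FR,13.5,25,57.5,14.5,99.76,66.4,33.4,118.6
20,FR12,FR,14.8,26.5,59,14.8,80.4,49.2,25.2,85.7
21,FR13,FR,13.8,22.8,46.5,15.8,70.94,60.7,30.6,107.7
22,FR14,FR,17,36,94,17,105.3,37.7,19.7,63.7
23,FR15,FR,15.4,33.5,82.2,18,75.46,45.3,23.4,78.4
24,FR16,FR,18.5,43,160,21,79.87,35.7,18.8,60.1
25,FR17,FR,14,26.9,80,23,146,56.8,28.8,100.3
26,FR18,FR,13.5,28.4,160,23.7,114.7,64.5,32.5,115
27,FR19,FR,14.3,33,160,26.6,103.6,53,27,93
28,FR20,FR,16.3,36,85,30.67,201.1,39.6,20.6,67.4
29,FR21,FR,14,29.5,67,56,159,54.9,27.9,96.7
30,FR22,FR,13.5,27.5,65,70.5,184.1,62.6,31.6,111.3
31,FR23,FR,14.7,30.6,80,78.3,275,51.1,26.1,89.4
32,FF1,FF,12.5,21,42.5,5.9,43.53,67.4,33.8,120.4
33,FF2,FF,12.9,22,46.5,9.7,34.69,64,32.2,114
34,FF3,FF,12.2,21.8,48.5,11.4,42.31,69,34.6,123.6
35,FF4,FF,13,21.5,44,13.5,92.55,62.3,31.4,110.7
36,FF5,FF,11.8,23.1,56,14.8,81.5,72.4,36.2,130.1
37,FF6,FF,13.5,25.8,61.3,18.4,98.05,53.8,27.4,94.6
38,FF7,FF,12,22.8,54,18.6,63.37,70.7,35.4,126.9
39,FF8,FF,15,30.5,70.8,22.2,75.58,38.6,20.2,65.6
40,FF9,FF,13.4,25.4,60,22.7,86.1,55.5,28.2,97.8
41,FF10,FF,13.3,25.8,62,29,110.6,57.2,29,101.1
42,FF11,FF,11.5,23,57.2,32.2,97.25,74.1,37,133.3
43,FF12,FF,15.7,31.2,71,33.5,112,35.3,18.6,59.2
44,FF13,FF,17.5,36.3,85.5,33.8,89.8,33.6,17.8,56
45,FF14,FF,13,21.5,43.8,38.2,149.6,60.6,30.6,107.5
46,FF15,FF,12.6,21,43.3,41.4,191.1,65.7,33,117.2
47,FF16,FF,13.9,25.2,57,54.1,186.3,48.8,25,85
48,FF17,FF,14,25,55.5,57.7,178.9,47.1,24.2,81.7
49,FF18,FF,15,24.6,60,63.4,155,37,19.4,62.4
50,FF19,FF,18.5,38,80,84.3,322.9,31.9,17,52.7
51,FF20,FF,13.7,29.2,70,97.6,231,52.2,26.6,91.4
52,FF21,FF,14.5,31,70,121.4,295.7,42,21.8,72.1
53,FF22,FF,13.8,26.5,70,129.5,284.7,50.5,25.8,88.2
54,FF23,FF,14.5,29.6,61,130,220,40.3,21,68.8
55,FF24,FF,14.2,28.5,60,141,456.1,43.7,22.6,75.3
56,FF25,FF,14,31,70,170.3,510.9,45.4,23.4,78.5
57,FF26,FF,13,31,69,175,382.4,58.9,29.8,104.3
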