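case,density_pct,volume_pct,size_pct,combined_pct,recist,pfs_months
1,1.68,287.33,43.75,289.01,PD,2.0
2,22.86,229.06,-11.55,251.92,SD,3.4
3,17.05,31.79,22.91,48.84,PD,—
4,14.89,25.28,-6.3,40.17,SD,4.3
5,17.77,-28.74,-39.28,-10.97,PR,6.2
6,-2.95,-88.68,-76.76,-91.63,PR,9.4
7,-31.67,296,193.75,264.33,PD,3.3
8,11,81.25,47.62,92.25,PD,3.0
9,10.99,5,-22.96,15.99,PR,5.7
10,0.97,9.89,-5.22,10.86,SD,4.8
11,-27.84,-74.55,-10.94,-102.39,SD,9.8
12,-4.7,131.25,97.06,126.55,PD,1.9
13,-16.48,57.86,16.9,41.38,SD,—
14,-13.13,43.48,-14.47,30.35,SD,5.7
15,12.87,152.91,17.7,165.78,SD,3.2
16,5.39,-27.53,-58.96,-22.14,PR,—
17,0.65,33.61,-10.68,34.26,SD,—
18,5.79,199.12,-5.73,204.91,SD,5.6
19,-30.16,-1.61,77.1,-31.77,PD,4.4
20,28,18.24,11.28,46.24,SD,2.4
21,1.46,13.73,-2.38,15.19,SD,4.9
22,-24.17,112.5,42.86,88.33,PD,1.8
23,1.69,34.67,2.13,36.36,SD,4.2
24,23.67,5.24,-6.69,28.91,SD,3.5
25,29.23,49.52,-18.43,78.75,SD,3.5
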