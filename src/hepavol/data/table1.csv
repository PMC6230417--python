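case,age,sex,net_type,tumor_grade,ki67_pct,therapy,therapy_courses
1,72,M,g-NET,3,80,etoposide+cisplatin,6
2,71,M,g-NET,3,80,etoposide+cisplatin,2
3,49,F,p-NET,2,20,etoposide+cisplatin,2
4,47,M,SI-NET,3,90,etoposide+cisplatin,4
5,28,F,r-NET,3,80,etoposide+cisplatin,2
6,45,M,SI-NET,3,70,etoposide+cisplatin,3
7,66,M,p-NET,3,80,etoposide+cisplatin,2
8,59,M,r-NET,2,15,everolimus,3
9,49,F,r-NET,1,1,everolimus,2
10,55,F,p-NET,2,10,everolimus,4
11,39,M,SI-NET,1,<1,octreotide,6
12,66,M,p-NET,2,5,octreotide,2
13,59,M,r-NET,2,15,octreotide,3
14,40,M,p-NET,2,8,octreotide,4
15,42,F,SI-NET,2,7,octreotide,6
16,69,M,p-NET,2,1,octreotide,4
17,62,F,SI-NET,1,<1,octreotide,3
18,37,M,SI-NET,2,5,octreotide,3
19,71,M,g-NET,3,80,capecitabine+temozolomide,4
20,42,F,p-NET,3,50,sunitinib,3
21,56,M,r-NET,2,5,sunitinib,2
22,46,F,p-NET,2,10,sunitinib,5
23,29,M,p-NET,2,15,sunitinib,4
24,37,M,SI-NET,2,5,sunitinib,5
25,36,F,p-NET,1,<1,sunitinib,8
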