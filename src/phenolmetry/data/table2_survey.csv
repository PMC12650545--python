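ref_id,year,citations,source,region,age,mg_per_ml,media,units,minutes,temp_c,manufacturer,catalog,ph,lcys,dnase
1,2009,124,Mouse,C,X,x,Custom,100,30,37,S-A,x,yes (7.4),Use,x
2,2019,105,Rat,H,E17–E18,0.1,PBS,x,10,37,S-A,P-4762,x,Use,Use
3,2017,28,Mouse,TG,6–10 weeks,x,HBSS+,40,30,37,W,x,yes,Use,x
4,2009,39,Rat,C,16 weeks,2.0,Hib. A,x,30,30,W,x,x,x,x
5,2014,55,Rat,H,E18,3.5,PBS,x,12,32,Wako,x,x,x,Use
6,2014,33,Rat,H,E18,x,PDS,20,15–20,37,WBC,PDS,x,Use,Use
7,2020,28,Mouse,WB,P0 or P1,N/A,N/A,N/A,10–30,x,BB,N/A,N/A,N/A,N/A
8,2017,37,Mouse & Rat,H,P1-3,1.0,L-15,x,x,x,N/A,N/A,x,Use,x
9,2014,681,Mouse,H,E16–E17,x,HBSS,20,30–60,37,WB,LS 3126,x,Use,Use
10,2017,110,Mouse,C,E14–E15,x,PDS,20,x,x,WBC,x,x,Use,Use
11,2015,656,Mouse,C,E17,x,PDS,20,x,x,WB,LK003150,x,Use,Use
12,2020,126,Mouse,"C, VM, S","E16–E18; P1",x,x,20,20,37,WB,LS003126,x,Use,x
13,2018,233,Mouse,C,E16.5,x,PDS,20,x,x,WBC,PDS,x,Use,Use
14,2013,166,Mouse,SC,E12.5,x,PDS,20,x,x,W,PDS,x,Use,Use
15,2019,101,Mouse,H,P0 or P1,0.5,PGB,x,20,37,x,x,x,x,Use
16,2020,136,Mouse,C,E17,x,PDS,20,x,x,WBC,PDS,x,Use,Use
17,2012,307,Mouse,C,P0,N/A,x,N/A,x,x,W,x,x,x,x
18,2011,117,Mouse,RGC,P7–P8,x,N/A,15,30,37,WB,x,x,Use,Use
19,2020,188,Mouse,H,P1,N/A,x,N/A,20,27,x,x,x,x,x
20,2021,101,Mouse,Ce,N/A,N/A,x,N/A,30,x,x,x,x,x,x
21,2017,180,Mouse,H,E16–17,N/A,HBSS+,N/A,x,x,WB,x,x,x,x
22,2020,121,Mouse,H,E16–E18,N/A,x,N/A,45,37,WBC,LS003126,x,Use,x
23,2016,167,Rat,H,P0,x,x,x,x,x,x,x,x,x,x
24,2014,1275,Mouse,H,P0–1,x,x,50,5,x,WB,x,x,x,x
25,2022,103,Rat,"C, H, VZ",E18,2.0,x,x,30,37,BB,PAP,x,x,x
26,2021,165,Mouse,C and H,E15.5–16.5,N/A,HBSS,N/A,12,37,WBC,LS003127,x,Use,Use
27,2019,102,Mouse,C,E18,1.0,x,x,10,37,S-A,76220,x,x,x
28,2018,102,Rat,C,E18,x,x,N/A,x,x,WB,LS003126,x,Use,Use
29,2016,301,Mouse,H,E18,x,PDS,20,x,x,WB,PDS,x,Use,Use
30,2013,161,Mouse,H,P0–P1,x,EBSS,20,30,37,x,x,x,x,x
31,2018,344,Mouse,H,P0–P1,x,x,50,6–8,x,WB,x,x,x,x
32,2013,485,Mouse,C,E15.5–16.5,x,HBSS,N/A,x,37,W,x,x,x,Use
33,2018,363,Rat,H,P0–1,x,x,x,x,x,x,x,x,x,x
34,2017,370,Mouse,C,E13.5,N/A,x,N/A,10,37,MB,130-092-628,x,x,x
35,2017,212,Mouse,LC,P1,1.0,Custom,x,30,37,S-A,P4762,x,x,Use
36,2012,138,Mouse,H,"2,4,8,11,21 mo.",2.0,Hib. A,x,30,30,W,x,x,x,x
37,2011,109,Mouse,C,1 mo.,x,Custom,x,30,30,x,x,x,x,x
38,2017,103,Mouse,DG/H,3–4 mo.,x,EBSS,20,60,37,x,x,x,x,Use
39,2014,278,Mouse,H,P0,x,x,x,x,x,x,x,x,x,x
40,2016,154,Mouse,C,P0,x,x,100,30,37,x,x,x,x,x
41,2018,130,Mouse,H,P0,x,x,20,x,x,S-A,x,x,x,x
42,2009,137,Mouse,C,E17–E18,x,x,x,45,37,WB,x,x,x,x
43,2010,113,Mouse,C and S,E18,x,PDS,N/A,x,x,W,PDS,x,Use,Use
44,2016,443,Mouse,H and C,E16–18,x,x,x,x,x,WBC,x,x,x,x
45,2020,127,Mouse,WB,N/A,x,x,20,20,37,x,x,yes,x,x
46,2012,129,Mouse,H,P0-P2,N/A,x,N/A,x,x,x,x,x,x,x
47,2010,34,Mouse & Rat,RGC,X,x,DMEM,30-35,10,37,W,x,x,Use,x
48,2012,79,Rat,C,E18,N/A,DMEM,x,30,37,x,x,x,x,Use
49,2017,53,Human,C,N/A,x,x,20,10–15,37,WB,x,x,x,x
50,2021,55,Mouse & Rat,C,E18,x,x,x,x,x,x,x,x,x,x
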