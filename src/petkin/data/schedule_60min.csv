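frame_start_s,frame_end_s
0,10
10,20
20,30
30,40
40,50
50,60
60,70
70,80
80,90
90,100
100,110
110,120
120,150
150,180
180,210
210,240
240,270
270,300
300,420
420,540
540,660
660,780
780,900
900,1200
1200,1500
1500,1800
1800,2100
2100,2400
2400,3000
3000,3600
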