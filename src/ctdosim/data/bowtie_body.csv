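fan_angle_deg,thickness_mm_al
0.0,0.0000
0.5,0.0105
1.0,0.0420
1.5,0.0945
2.0,0.1680
2.5,0.2625
3.0,0.3780
3.5,0.5145
4.0,0.6720
4.5,0.8505
5.0,1.0500
5.5,1.2705
6.0,1.5120
6.5,1.7745
7.0,2.0580
7.5,2.3625
8.0,2.6880
8.5,3.0345
9.0,3.4020
9.5,3.7905
10.0,4.2000
10.5,4.6305
11.0,5.0820
11.5,5.5545
12.0,6.0480
12.5,6.5625
13.0,7.0980
13.5,7.6545
14.0,8.2320
14.5,8.8305
15.0,9.4500
15.5,10.0905
16.0,10.7520
16.5,11.4345
17.0,12.1380
17.5,12.8625
18.0,13.6080
18.5,14.3745
19.0,15.1620
19.5,15.9705
20.0,16.8000
20.5,17.6505
21.0,18.5220
21.5,19.4145
22.0,20.3280
22.5,21.2625
23.0,22.2180
23.5,23.1945
24.0,24.1920
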