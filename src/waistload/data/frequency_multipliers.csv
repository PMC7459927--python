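frequency_per_min,duration_class,v_band,fm
0.2,<=1h,V<75,1.00
0.2,<=1h,V>=75,1.00
0.2,<=2h,V<75,0.95
0.2,<=2h,V>=75,0.95
0.2,<=8h,V<75,0.85
0.2,<=8h,V>=75,0.85
0.5,<=1h,V<75,0.97
0.5,<=1h,V>=75,0.97
0.5,<=2h,V<75,0.92
0.5,<=2h,V>=75,0.92
0.5,<=8h,V<75,0.81
0.5,<=8h,V>=75,0.81
1,<=1h,V<75,0.94
1,<=1h,V>=75,0.94
1,<=2h,V<75,0.88
1,<=2h,V>=75,0.88
1,<=8h,V<75,0.75
1,<=8h,V>=75,0.75
2,<=1h,V<75,0.91
2,<=1h,V>=75,0.91
2,<=2h,V<75,0.84
2,<=2h,V>=75,0.84
2,<=8h,V<75,0.66
2,<=8h,V>=75,0.66
3,<=1h,V<75,0.88
3,<=1h,V>=75,0.88
3,<=2h,V<75,0.79
3,<=2h,V>=75,0.79
3,<=8h,V<75,0.55
3,<=8h,V>=75,0.55
4,<=1h,V<75,0.84
4,<=1h,V>=75,0.84
4,<=2h,V<75,0.72
4,<=2h,V>=75,0.72
4,<=8h,V<75,0.45
4,<=8h,V>=75,0.45
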