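A,coded_A,B,coded_B,release_pct
0,-1,1,-1,14.01
0,-1,1,-1,13.90
0,-1,48,1,18.06
0,-1,48,1,28.02
2.44,-0.4637,8,-0.70213,65.77
2.44,-0.4637,8,-0.70213,63.42
2.44,-0.4637,8,-0.70213,68.69
2.44,-0.4637,8,-0.70213,69.43
2.44,-0.4637,8,-0.70213,62.62
2.44,-0.4637,8,-0.70213,63.33
4.76,0.0462,24.5,0,73.79
4.76,0.0462,24.5,0,75.53
4.76,0.0462,24.5,0,78.42
4.76,0.0462,24.5,0,80.09
4.76,0.0462,24.5,0,75.63
4.76,0.0462,24.5,0,78.20
9.10,1,1,-1,89.27
9.10,1,1,-1,85.60
9.10,1,48,1,98.89
9.10,1,48,1,99.41
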