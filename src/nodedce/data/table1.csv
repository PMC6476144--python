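node,agent,cluster,auc,auc_sd,wash_in,wash_in_sd,wash_out,wash_out_sd,volume_pct
1,Gd-DTPA,inner,217,41,1.3,0.3,-3.8,0.8,25
1,Gd-DTPA,outer,100,25,0.8,0.3,-1.5,0.6,75
2,Gd-DTPA,inner,124,16,1.9,0.3,-3.0,0.5,19
2,Gd-DTPA,outer,71,12,1.2,0.5,-1.6,0.4,81
3,Gd-DTPA,inner,101,14,2.6,0.4,-1.9,0.2,21
3,Gd-DTPA,outer,58,13,1.2,0.3,-1.2,0.3,79
4,Gd-DTPA,inner,143,23,1.6,0.5,-0.6,0.6,26
4,Gd-DTPA,outer,74,17,0.9,0.4,-0.5,0.4,74
5,Gd-DTPA,inner,100,9,1.1,0.7,-0.7,0.3,49
5,Gd-DTPA,outer,69,9,1.1,0.4,-0.4,0.3,51
6,Gd-DTPA,inner,91,9,1.7,0.5,-0.5,0.3,32
6,Gd-DTPA,outer,63,6,1.2,0.5,-0.3,0.2,68
7,Gd-DTPA,inner,98,11,1.4,0.4,-0.7,0.4,33
7,Gd-DTPA,outer,66,9,1.2,0.5,-0.4,0.2,67
8,Gd-DTPA,inner,178,26,1.1,0.3,-1.1,0.6,29
8,Gd-DTPA,outer,99,22,1.0,0.3,-0.5,0.4,71
9,Gd-DTPA,inner,149,27,1.5,0.5,-0.4,0.7,25
9,Gd-DTPA,outer,91,18,1.0,0.5,-0.6,0.3,75
10,Gd-BOPTA,inner,211,33,1.4,0.3,-2.7,0.5,47
10,Gd-BOPTA,outer,109,29,1.2,0.2,-1.2,0.4,53
11,Gd-BOPTA,inner,157,23,2.3,0.4,-2.2,0.6,14
11,Gd-BOPTA,outer,97,14,1.3,0.4,-1.2,0.3,86
12,Gd-BOPTA,inner,88,14,1.3,0.3,-2.3,1.2,40
12,Gd-BOPTA,outer,51,12,1.0,0.3,-1.2,0.7,60
13,Gd-BOPTA,inner,51,9,1.9,0.4,-2.1,0.4,38
13,Gd-BOPTA,outer,29,7,1.3,0.4,-1.3,0.3,62
14,Gd-BOPTA,inner,61,7,1.5,0.5,-1.4,0.2,43
14,Gd-BOPTA,outer,36,8,1.3,0.7,-0.9,0.3,57
15,Gd-BOPTA,inner,109,18,1.7,0.3,-3.5,0.8,29
15,Gd-BOPTA,outer,48,16,1.1,0.4,-1.3,0.5,71
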