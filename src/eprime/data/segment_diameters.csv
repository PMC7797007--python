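sex,segment_id,diameter_mm
M,left-main,4.5
F,left-main,4.0
M,proximal-LAD,3.7
F,proximal-LAD,3.3
M,mid-LAD,2.9
F,mid-LAD,2.6
M,distal-LAD,2.0
F,distal-LAD,1.8
M,first-diagonal,2.2
F,first-diagonal,2.0
M,second-diagonal,1.9
F,second-diagonal,1.7
M,proximal-LCx,3.4
F,proximal-LCx,3.0
M,distal-LCx,2.2
F,distal-LCx,1.9
M,first-marginal,2.4
F,first-marginal,2.1
M,second-marginal,2.0
F,second-marginal,1.8
M,proximal-RCA,3.9
F,proximal-RCA,3.5
M,mid-RCA,3.4
F,mid-RCA,3.0
M,distal-RCA,2.8
F,distal-RCA,2.5
M,PDA,2.2
F,PDA,2.0
M,posterolateral-branch,2.0
F,posterolateral-branch,1.8
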