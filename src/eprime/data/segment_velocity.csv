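sex,segment_id,v_at_60bpm_mm_s,slope_mm_s_per_bpm
M,left-main,17.0,0.10
F,left-main,17.5,0.10
M,proximal-LAD,17.0,0.12
F,proximal-LAD,17.5,0.12
M,mid-LAD,18.0,0.14
F,mid-LAD,18.5,0.14
M,distal-LAD,19.0,0.16
F,distal-LAD,19.5,0.16
M,first-diagonal,18.0,0.14
F,first-diagonal,18.5,0.14
M,second-diagonal,18.0,0.14
F,second-diagonal,18.5,0.14
M,proximal-LCx,20.0,0.18
F,proximal-LCx,20.5,0.18
M,distal-LCx,21.0,0.18
F,distal-LCx,21.5,0.18
M,first-marginal,20.0,0.16
F,first-marginal,20.5,0.16
M,second-marginal,20.0,0.16
F,second-marginal,20.5,0.16
M,proximal-RCA,22.0,0.20
F,proximal-RCA,22.5,0.20
M,mid-RCA,24.0,0.22
F,mid-RCA,24.5,0.22
M,distal-RCA,22.0,0.20
F,distal-RCA,22.5,0.20
M,PDA,20.0,0.18
F,PDA,20.5,0.18
M,posterolateral-branch,20.0,0.18
F,posterolateral-branch,20.5,0.18
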