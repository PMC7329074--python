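x_deg,y_deg,sector
-9,21,IN
-3,21,IT
3,21,IT
9,21,IT
-15,15,IN
-9,15,IN
-3,15,IT
3,15,IT
9,15,IT
15,15,IT
-21,9,IN
-15,9,IN
-9,9,IN
-3,9,IT
3,9,IT
9,9,IT
15,9,IT
21,9,IT
-27,3,N
-21,3,N
-15,3,N
-9,3,N
-3,3,N
3,3,T
9,3,T
15,3,blind_spot
21,3,T
-27,-3,N
-21,-3,N
-15,-3,N
-9,-3,N
-3,-3,N
3,-3,T
9,-3,T
15,-3,blind_spot
21,-3,T
-21,-9,SN
-15,-9,SN
-9,-9,SN
-3,-9,ST
3,-9,ST
9,-9,ST
15,-9,ST
21,-9,ST
-15,-15,SN
-9,-15,SN
-3,-15,ST
3,-15,ST
9,-15,ST
15,-15,ST
-9,-21,SN
-3,-21,ST
3,-21,ST
9,-21,ST
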