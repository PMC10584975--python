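no,location,x,y,z
1,L Superioparietal,-40,-21,51
2,R Postcentral gyrus,40,-21,51
3,L Superioparietal,-38,-26,53
4,R Postcentral gyrus,38,-26,53
5,L Postcentral gyrus,-48,-15,50
6,R Postcentral gyrus,48,-15,50
7,L Cingulate gyrus,-24,-24,32
8,R Cingulate gyrus,24,-24,32
9,L Supramarginal gyrus,-34,-32,38
10,R Superior parietal,34,-32,38
11,L Rostral middle frontal gyrus,-42,40,25
12,R Caudal middle frontal,42,40,25
13,L Paracentral,0,-4,65
14,R Posterior cingulate,8,-12,52
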