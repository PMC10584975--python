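no,location,x,y,z
1,Paracentral lobule,-9.1,-8.5,60.2
2,Paracentral lobule,10.1,-6.9,62.3
3,Paracentral lobule,4.6,-3.4,54.3
4,Paracentral lobule,8.4,-9.9,57.9
5,Posterior cingulate,7.5,-1.6,53.5
6,Precuneus,-2.6,-33.9,54.5
7,Posterior cingulate,-3.5,-30.7,52.1
8,Precuneus,-4.1,-43.2,49.7
9,Isthmus cingulate,-3.6,-39.2,46.1
10,Posterior cingulate,-3.3,-26.0,50.4
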