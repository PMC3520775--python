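species,param,estimate,iiv_sd
rat,vc,38.8,0.162
rat,vp1,141,0.169
rat,vp2,1580,
rat,cl,16.4,0.162
rat,q1,29.1,0.169
rat,q2,22.3,0.162
rat,resid_plasma,0.482,
human,vc,2580,
human,vp1,57900,
human,vp2,41100,
human,cl,538,
human,q1,6550,
human,q2,5880,
human,resid_plasma,0.654,
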