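glomerulus,category
V,aversive
DL4,aversive
DL5,aversive
DA4l,aversive
DP1l,food
VA6,food
DL2d,food
VL2a,food
VM7d,food
DM1,food
DM4,food
VA1d,pheromonal
VA1v,pheromonal
DA1,pheromonal
DL3,pheromonal
VL2p,egg-laying
VC4,egg-laying
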