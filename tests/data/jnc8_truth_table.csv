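race,ckd,class_label,permitted,rule
White,0,ACEi,1,general
White,0,ARB,1,general
White,0,thiazide,1,general
White,0,CCB,1,general
White,0,beta-blocker,0,general
White,0,other,0,general
White,0,ACEi+thiazide,1,general
White,0,ACEi+CCB,1,general
White,0,ARB+thiazide,1,general
White,0,CCB+beta-blocker,0,general
White,0,beta-blocker+thiazide,0,general
White,1,ACEi,1,ckd
White,1,ARB,1,ckd
White,1,thiazide,0,ckd
White,1,CCB,0,ckd
White,1,beta-blocker,0,ckd
White,1,other,0,ckd
White,1,ACEi+thiazide,1,ckd
White,1,ACEi+CCB,1,ckd
White,1,ARB+thiazide,1,ckd
White,1,CCB+beta-blocker,0,ckd
White,1,beta-blocker+thiazide,0,ckd
Black,0,ACEi,0,black
Black,0,ARB,0,black
Black,0,thiazide,1,black
Black,0,CCB,1,black
Black,0,beta-blocker,0,black
Black,0,other,0,black
Black,0,ACEi+thiazide,0,black
Black,0,ACEi+CCB,0,black
Black,0,ARB+thiazide,0,black
Black,0,CCB+beta-blocker,0,black
Black,0,beta-blocker+thiazide,0,black
Black,1,ACEi,1,ckd
Black,1,ARB,1,ckd
Black,1,thiazide,0,ckd
Black,1,CCB,0,ckd
Black,1,beta-blocker,0,ckd
Black,1,other,0,ckd
Black,1,ACEi+thiazide,1,ckd
Black,1,ACEi+CCB,1,ckd
Black,1,ARB+thiazide,1,ckd
Black,1,CCB+beta-blocker,0,ckd
Black,1,beta-blocker+thiazide,0,ckd
Other,0,ACEi,1,general
Other,0,ARB,1,general
Other,0,thiazide,1,general
Other,0,CCB,1,general
Other,0,beta-blocker,0,general
Other,0,other,0,general
Other,0,ACEi+thiazide,1,general
Other,0,ACEi+CCB,1,general
Other,0,ARB+thiazide,1,general
Other,0,CCB+beta-blocker,0,general
Other,0,beta-blocker+thiazide,0,general
Other,1,ACEi,1,ckd
Other,1,ARB,1,ckd
Other,1,thiazide,0,ckd
Other,1,CCB,0,ckd
Other,1,beta-blocker,0,ckd
Other,1,other,0,ckd
Other,1,ACEi+thiazide,1,ckd
Other,1,ACEi+CCB,1,ckd
Other,1,ARB+thiazide,1,ckd
Other,1,CCB+beta-blocker,0,ckd
Other,1,beta-blocker+thiazide,0,ckd
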