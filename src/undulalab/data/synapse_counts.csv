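source,target,count,kind
AS,dorsal_BWM,68,chemical
AS,VD,66,chemical
AS,unassigned,10,chemical
A,ventral_BWM,225,chemical
A,dorsal_BWM,111,chemical
B,ventral_BWM,228,chemical
B,dorsal_BWM,58,chemical
VA,DD,180,chemical
VB,DD,194,chemical
DA,DD,8,chemical
DB,DD,29,chemical
AVA,AS,63,chemical
AVE,AS,7,chemical
AVB,AS,13,chemical
PVC,AS,2,chemical
AVA,AS,37,gap
AVB,AS,5,gap
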