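code,name,group
DLO,dorsolateral orbital cortex,PFC
LO,lateral orbital cortex,PFC
MO,medial orbital cortex,PFC
VO,ventral orbital cortex,PFC
M2,secondary motor cortex,PFC
AC,cingulate cortex,mPFC
PL,prelimbic cortex,mPFC
IL,infralimbic cortex,mPFC
RSDa,retrosplenial dysgranular cortex anterior A30,RSC
RSDp,retrosplenial dysgranular cortex posterior,RSC
RSGab,retrosplenial granular cortex A29ab,RSC
RSGca,retrosplenial granular cortex anterior A29c,RSC
RSGcp,retrosplenial granular cortex posterior A29c,RSC
AD,anterodorsal thalamic nucleus,TAL
AM,anteromedial thalamic nucleus,TAL
AV,anteroventral thalamic nucleus,TAL
MD,mediodorsal thalamic nucleus,TAL
PVT,paraventricular thalamic nucleus,TAL
RE,reuniens thalamic nucleus,TAL
BLAa,basolateral amygdaloid nucleus anterior,AMY
BLAp,basolateral amygdaloid nucleus posterior,AMY
BLAv,basolateral amygdaloid nucleus ventral,AMY
BMEa,basomedial amygdaloid nucleus anterior,AMY
BMEp,basomedial amygdaloid nucleus posterior,AMY
CEA,central amygdaloid nucleus,AMY
ITC,intercalated amygdaloid nucleus,AMY
LAd,lateral amygdaloid nucleus dorsal,AMY
LAv,lateral amygdaloid nucleus ventral,AMY
MEAa,medial amygdaloid nucleus anterior,AMY
MEAp,medial amygdaloid nucleus posterior,AMY
dCA1,dorsal CA1 region of hippocampus,DH
dCA3,dorsal CA3 region of hippocampus,DH
dDG,dorsal dentate gyrus,DH
vCA1,ventral CA1 region of hippocampus,VH
vCA3,ventral CA3 region of hippocampus,VH
vDG,ventral dentate gyrus,VH
dSUB,dorsal subiculum,SUB
vSUB,ventral subiculum,SUB
PAS,parasubiculum,SUB
PRES,presubiculum,SUB
POST,postsubiculum,SUB
PER,perirhinal cortex,PHC
POR,postrhinal cortex,PHC
ECT,ectorhinal cortex,PHC
CENT,caudomedial entorhinal cortex,PHC
DIENT,dorsal intermediate entorhinal cortex,PHC
DLENT,dorsal lateral entorhinal cortex,PHC
MENT,medial entorhinal cortex,PHC
VIENT,ventral intermediate entorhinal cortex,PHC
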