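phoneme,syl,son,cons,cont,delrel,lat,nas,strid,voi,sg,cg,ant,cor,distr,lab,hi,lo,back,rnd,tense,long
b,-,-,+,-,-,-,-,-,+,-,-,+,-,-,+,-,-,-,-,0,-
p,-,-,+,-,-,-,-,-,-,-,-,+,-,-,+,-,-,-,-,0,-
d,-,-,+,-,-,-,-,-,+,-,-,+,+,-,-,-,-,-,-,0,-
t,-,-,+,-,-,-,-,-,-,-,-,+,+,-,-,-,-,-,-,0,-
g,-,-,+,-,-,-,-,-,+,-,-,-,-,-,-,+,-,+,-,0,-
k,-,-,+,-,-,-,-,-,-,-,-,-,-,-,-,+,-,+,-,0,-
m,-,+,+,-,-,-,+,-,+,-,-,+,-,-,+,-,-,-,-,0,-
n,-,+,+,-,-,-,+,-,+,-,-,+,+,-,-,-,-,-,-,0,-
l,-,+,+,+,-,+,-,-,+,-,-,+,+,-,-,-,-,-,-,0,-
r,-,+,+,+,-,-,-,-,+,-,-,-,+,-,-,-,-,-,-,0,-
f,-,-,+,+,-,-,-,+,-,-,-,+,-,-,+,-,-,-,-,0,-
v,-,-,+,+,-,-,-,+,+,-,-,+,-,-,+,-,-,-,-,0,-
s,-,-,+,+,-,-,-,+,-,-,-,+,+,-,-,-,-,-,-,0,-
z,-,-,+,+,-,-,-,+,+,-,-,+,+,-,-,-,-,-,-,0,-
x,-,-,+,+,-,-,-,-,-,-,-,-,-,-,-,+,-,+,-,0,-
h,-,-,-,+,-,-,-,-,-,+,-,-,-,-,-,-,-,-,-,0,-
j,-,+,-,+,-,-,-,-,+,-,-,-,-,-,-,+,-,-,-,0,-
w,-,+,-,+,-,-,-,-,+,-,-,-,-,-,+,+,-,+,+,0,-
ʃ,-,-,+,+,-,-,-,+,-,-,-,-,+,+,-,+,-,-,-,0,-
ʒ,-,-,+,+,-,-,-,+,+,-,-,-,+,+,-,+,-,-,-,0,-
ç,-,-,+,+,-,-,-,-,-,-,-,-,-,-,-,+,-,-,-,0,-
ŋ,-,+,+,-,-,-,+,-,+,-,-,-,-,-,-,+,-,+,-,0,-
a,+,+,-,+,-,-,-,-,+,-,-,-,-,-,-,-,+,+,-,-,-
e,+,+,-,+,-,-,-,-,+,-,-,-,-,-,-,-,-,-,-,-,-
i,+,+,-,+,-,-,-,-,+,-,-,-,-,-,-,+,-,-,-,-,-
o,+,+,-,+,-,-,-,-,+,-,-,-,-,-,+,-,-,+,+,-,-
u,+,+,-,+,-,-,-,-,+,-,-,-,-,-,+,+,-,+,+,-,-
ɛ,+,+,-,+,-,-,-,-,+,-,-,-,-,-,-,-,-,-,-,-,-
ɔ,+,+,-,+,-,-,-,-,+,-,-,-,-,-,+,-,-,+,+,-,-
ʏ,+,+,-,+,-,-,-,-,+,-,-,-,-,-,+,+,-,-,+,-,-
œ,+,+,-,+,-,-,-,-,+,-,-,-,-,-,+,-,-,-,+,-,-
aː,+,+,-,+,-,-,-,-,+,-,-,-,-,-,-,-,+,+,-,+,+
eː,+,+,-,+,-,-,-,-,+,-,-,-,-,-,-,-,-,-,-,+,+
iː,+,+,-,+,-,-,-,-,+,-,-,-,-,-,-,+,-,-,-,+,+
oː,+,+,-,+,-,-,-,-,+,-,-,-,-,-,+,-,-,+,+,+,+
uː,+,+,-,+,-,-,-,-,+,-,-,-,-,-,+,+,-,+,+,+,+
ɛː,+,+,-,+,-,-,-,-,+,-,-,-,-,-,-,-,-,-,-,-,+
øː,+,+,-,+,-,-,-,-,+,-,-,-,-,-,+,-,-,-,+,+,+
yː,+,+,-,+,-,-,-,-,+,-,-,-,-,-,+,+,-,-,+,+,+
ts,-,-,+,-,+,-,-,+,-,-,-,+,+,-,-,-,-,-,-,0,-
pf,-,-,+,-,+,-,-,+,-,-,-,+,-,-,+,-,-,-,-,0,-
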