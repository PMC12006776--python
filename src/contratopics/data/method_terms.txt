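iud
implant
pill
ring
patch
shot
injection
depo
copper
hormonal
hormone
contraceptive
contraception
ocp
cocp
pop
oral
vaginal
intrauterine
spermicide
generic
brand
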