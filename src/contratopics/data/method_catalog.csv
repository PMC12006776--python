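drug_name,method,is_brand
Mirena,hormonal IUD,1
Kyleena,hormonal IUD,1
Liletta,hormonal IUD,1
Skyla,hormonal IUD,1
ParaGard,copper IUD,1
Copper IUD,copper IUD,0
Nexplanon,implant,1
Implanon,implant,1
Etonogestrel,implant,0
NuvaRing,vaginal ring,1
Etonogestrel / ethinyl estradiol,vaginal ring,0
Depo-Provera,shot,1
Depo-SubQ Provera 104,shot,1
Medroxyprogesterone,shot,0
Xulane,patch,1
Ortho Evra,patch,1
Norelgestromin / ethinyl estradiol,patch,0
Sprintec,COCP,1
Tri-Sprintec,COCP,1
Microgynon,COCP,1
Loestrin 24 Fe,COCP,1
Lo Loestrin Fe,COCP,1
Loestrin,COCP,1
Junel Fe 1 / 20,COCP,1
Yaz,COCP,1
Yasmin,COCP,1
Ocella,COCP,1
Alesse,COCP,1
Aviane,COCP,1
Lutera,COCP,1
Levora,COCP,1
Ortho Tri-Cyclen,COCP,1
Ortho Tri-Cyclen Lo,COCP,1
Apri,COCP,1
Estarylla,COCP,1
Gianvi,COCP,1
Ethinyl estradiol / norethindrone,COCP,0
Ethinyl estradiol / norgestimate,COCP,0
Ethinyl estradiol / levonorgestrel,COCP,0
Ethinyl estradiol / drospirenone,COCP,0
Camila,POP,1
Errin,POP,1
Jolivette,POP,1
Micronor,POP,1
Nora-Be,POP,1
Heather,POP,1
Norethindrone,POP,0
Seasonale,OCP-91-day,1
Seasonique,OCP-91-day,1
LoSeasonique,OCP-91-day,1
Jolessa,OCP-91-day,1
Introvale,OCP-91-day,1
Camrese,OCP-91-day,1
Amethia,OCP-91-day,1
Quasense,OCP-91-day,1
Plan B,emergency contraception,1
Plan B One-Step,emergency contraception,1
Next Choice,emergency contraception,1
Ella,emergency contraception,1
Ulipristal,emergency contraception,0
VCF,spermicide,1
Encare,spermicide,1
Nonoxynol-9,spermicide,0
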