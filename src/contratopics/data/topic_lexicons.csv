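topic,word
weight_gain,weight
weight_gain,gain
weight_gain,gained
weight_gain,pound
weight_gain,appetite
weight_gain,hungry
weight_gain,eating
weight_gain,fat
weight_gain,belly
weight_gain,scale
weight_gain,craving
weight_gain,metabolism
weight_gain,waist
weight_gain,heavier
weight_gain,snacking
weight_gain,overweight
weight_gain,gaining
weight_gain,slim
skin_problems,skin
skin_problems,acne
skin_problems,pimple
skin_problems,breakout
skin_problems,cystic
skin_problems,face
skin_problems,chin
skin_problems,oily
skin_problems,complexion
skin_problems,rash
skin_problems,blemish
skin_problems,forehead
skin_problems,jawline
skin_problems,cyst
skin_problems,zit
skin_problems,greasy
skin_problems,bump
skin_problems,scarring
loss_of_libido,libido
loss_of_libido,sex
loss_of_libido,drive
loss_of_libido,intimacy
loss_of_libido,desire
loss_of_libido,dryness
loss_of_libido,intercourse
loss_of_libido,arousal
loss_of_libido,attraction
loss_of_libido,passion
loss_of_libido,romance
loss_of_libido,sexual
loss_of_libido,partner
loss_of_libido,interest
loss_of_libido,dry
loss_of_libido,lubrication
loss_of_libido,sexually
loss_of_libido,uninterested
mental_health,mood
mental_health,depression
mental_health,anxiety
mental_health,depressed
mental_health,anxious
mental_health,crying
mental_health,irritable
mental_health,swing
mental_health,angry
mental_health,emotional
mental_health,panic
mental_health,sad
mental_health,temper
mental_health,rage
mental_health,mental
mental_health,stress
mental_health,nervous
mental_health,moody
menstrual_irregularities,period
menstrual_irregularities,spotting
menstrual_irregularities,irregular
menstrual_irregularities,late
menstrual_irregularities,early
menstrual_irregularities,missed
menstrual_irregularities,light
menstrual_irregularities,unpredictable
menstrual_irregularities,cycle
menstrual_irregularities,skipped
menstrual_irregularities,random
menstrual_irregularities,twice
menstrual_irregularities,lighter
menstrual_irregularities,shorter
menstrual_irregularities,longer
menstrual_irregularities,schedule
menstrual_irregularities,surprise
menstrual_irregularities,timing
cramps_pain,cramp
cramps_pain,pain
cramps_pain,cramping
cramps_pain,insertion
cramps_pain,severe
cramps_pain,ache
cramps_pain,sharp
cramps_pain,agony
cramps_pain,excruciating
cramps_pain,stabbing
cramps_pain,sore
cramps_pain,hurt
cramps_pain,unbearable
cramps_pain,pelvic
cramps_pain,intense
cramps_pain,painful
cramps_pain,hurting
cramps_pain,throbbing
continuous_bleeding,bleeding
continuous_bleeding,bleed
continuous_bleeding,blood
continuous_bleeding,nonstop
continuous_bleeding,constant
continuous_bleeding,heavy
continuous_bleeding,flow
continuous_bleeding,clot
continuous_bleeding,hemorrhage
continuous_bleeding,soaked
continuous_bleeding,tampon
continuous_bleeding,pad
continuous_bleeding,continuous
continuous_bleeding,constantly
continuous_bleeding,gushing
continuous_bleeding,endless
continuous_bleeding,straight
continuous_bleeding,stop
multiple_cause,headache
multiple_cause,tired
multiple_cause,nausea
multiple_cause,dizzy
multiple_cause,fatigue
multiple_cause,migraine
multiple_cause,terrible
multiple_cause,awful
multiple_cause,horrible
multiple_cause,worst
multiple_cause,sick
multiple_cause,annoyed
multiple_cause,frustrated
multiple_cause,regret
multiple_cause,disappointed
multiple_cause,unhappy
multiple_cause,miserable
multiple_cause,complaint
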