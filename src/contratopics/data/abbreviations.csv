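short_form,long_form
can't,cannot
won't,will not
ain't,am not
don't,do not
doesn't,does not
didn't,did not
isn't,is not
aren't,are not
wasn't,was not
weren't,were not
hasn't,has not
haven't,have not
hadn't,had not
couldn't,could not
wouldn't,would not
shouldn't,should not
mustn't,must not
mightn't,might not
needn't,need not
shan't,shall not
i'm,i am
i've,i have
i'll,i will
i'd,i would
you're,you are
you've,you have
you'll,you will
you'd,you would
he's,he is
he'll,he will
he'd,he would
she's,she is
she'll,she will
she'd,she would
it's,it is
it'll,it will
it'd,it would
we're,we are
we've,we have
we'll,we will
we'd,we would
they're,they are
they've,they have
they'll,they will
they'd,they would
that's,that is
that'll,that will
that'd,that would
there's,there is
there'll,there will
here's,here is
what's,what is
what're,what are
who's,who is
who'll,who will
where's,where is
when's,when is
why's,why is
how's,how is
let's,let us
y'all,you all
gonna,going to
wanna,want to
gotta,got to
kinda,kind of
sorta,sort of
dunno,do not know
gimme,give me
lemme,let me
outta,out of
could've,could have
would've,would have
should've,should have
must've,must have
might've,might have
pms,premenstrual syndrome
pmdd,premenstrual dysphoric disorder
yr,year
yrs,years
hr,hour
hrs,hours
min,minute
mins,minutes
wk,week
wks,weeks
mo,month
mos,months
appt,appointment
dr,doctor
drs,doctors
ob,obstetrician
obgyn,obstetrician gynecologist
gyno,gynecologist
gyn,gynecologist
med,medication
meds,medications
rx,prescription
otc,over the counter
bp,blood pressure
uti,urinary tract infection
sti,sexually transmitted infection
std,sexually transmitted disease
hbc,hormonal birth control
bf,boyfriend
hubby,husband
lb,pound
lbs,pounds
kg,kilogram
oz,ounce
approx,approximately
asap,as soon as possible
btw,by the way
fyi,for your information
idk,i do not know
imo,in my opinion
omg,oh my goodness
tmi,too much information
af,period
cuz,because
bc,birth control
b4,before
thru,through
tho,though
w/o,without
msg,message
pls,please
plz,please
thx,thanks
u,you
ur,your
abt,about
avg,average
fx,effects
temp,temperature
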