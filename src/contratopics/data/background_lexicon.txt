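time
first
get
got
would
like
side
effect
since
never
really
also
still
one
two
three
take
taking
started
start
use
using
doctor
experience
feel
felt
know
thing
going
went
even
much
well
bit
little
far
switch
switched
try
tried
read
review
body
woman
change
noticed
say
told
thought
week
month
day
year
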