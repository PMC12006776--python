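love
great
perfect
happy
recommend
amazing
easy
wonderful
best
pleased
satisfied
fantastic
convenient
reliable
effective
smooth
excellent
awesome
helpful
worry
free
glad
comfortable
regular
normal
fine
good
work
working
worked
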