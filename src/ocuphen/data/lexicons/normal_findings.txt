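# Markers of normal (non-pathological) findings, one per line, matched
# case-insensitively on word boundaries. Extend with local dialect as needed.
clear
klar
unremarkable
unauffällig
regelrecht
reizfrei
within normal limits
normal
quiet
intact
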