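# Negation triggers, one per line, matched case-insensitively on word
# boundaries within a segment. Extend with local dialect as needed.
no
not
without
ruled out
not present
absence of
no evidence of
kein
keine
ohne
nicht
ausgeschlossen
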