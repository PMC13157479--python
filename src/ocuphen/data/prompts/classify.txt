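Classify the following ophthalmic finding. Answer with exactly one word:
"pathological" if an abnormality is described as present, "normal" if the
finding is explicitly normal or unremarkable, "negated" if a pathology is
explicitly ruled out or absent.

Finding: {input}

Label:
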