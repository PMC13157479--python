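Split the following ophthalmology note into discrete findings, one finding
per line, preserving the original order. Do not paraphrase, merge, or drop
findings. Return only the list.

Note:
{input}

Findings:
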