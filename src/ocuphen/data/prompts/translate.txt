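You are a clinical translator for an eye clinic. Translate the following
German ophthalmology note into English. Preserve the clinical meaning and
keep any text that is already English unchanged. Return only the
translation.

Note:
{input}

English translation:
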