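# German → English ophthalmic phrase lexicon for the fallback translator.
# Longest phrase wins; tokens absent from this table pass through verbatim.
Amotio retinae	retinal detachment
Netzhautablösung	retinal detachment
Wimpernverlust	Eyelash loss
Roth-Fleck	Roth spot
Rote Katarakt	Red cataract
Schießscheibenmakulopathie	Target maculopathy
Doppelte Wimpernreihe	Double eyelashes
Frische Laserherde	Fresh laser burns
Anliegende Lamelle	Adhering flap
Hornhaut klar	Cornea clear
Linse unauffällig	Lens unremarkable
Fundus regelrecht	Fundus normal
Vorderkammer reizfrei	Anterior chamber quiet
keine Hinweise auf	no evidence of
ausgeschlossen	ruled out
keine	no
kein	no
ohne	without
nicht	not
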