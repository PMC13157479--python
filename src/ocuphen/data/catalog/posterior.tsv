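11504	Target maculopathy
31151	Tractional intraretinal cysts on macular OCT
11530	Adhering flap
25314	Choroidal nevus at the inferior vascular arcade
11530	Bridge vessel with elevated margins
200071	Areas of degeneration at 7 o’clock
7777	Double row laser burns
30499	Drusen within atrophic areas
40049	Fluid at the temporal edge of the atrophic zone
7777	Inferior temporal laser grid from 6:30 to 9 o’clock
8028	Macular cystic lesions
1177	Peripheral retinal resection
31805	Roth spot
500061	Multiple avascular areas in zone III
1777	Fresh laser burns
11530	Floating retinal flap
31805	Streak-like bleeding at the inferior margin
0	Visualisation improved
0	Visualisation significantly reduced
30609	Fibrosis in the outer neurosensory retina
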