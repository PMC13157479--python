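1128	Hair on the graft
45025	Lid fissure width: 10 mm, 11 mm
11457	Eyelash loss
6000709	Absent Bell phenomenon
500081	Central capsulorhexis
525	Temporal punctate iris defect
200020	Three linear scratches from 6 o’clock to 9 o’clock, mid-peripheral and peripheral
0	Sclera is compressible
9743	Double eyelashes
100019	Inferior cataract with spicule
100018	Red cataract
12905	Wide-set eyes
500074	Elevation deficit
31705	Forced head position
7648	Lens with diffuse, snow-like opacities
0	Motility
11488	Pigment on endothelium (left > right)
40004	Substance defect with pooling
2664	Tumor with increased vascularity
7734	Suspected dacryoadenitis
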