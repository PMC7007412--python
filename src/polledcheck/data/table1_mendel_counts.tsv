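group	family	sire	dam	offspring	n_errors
GH.H	1	RCI002	RC.dam1	RC.calf1	169672
GH.H	1	RCI002	RC.dam2	RC.calf2	158736
GH.H	1	RCI002	RC.dam3	RC.calf3	126192
GH.H	1	RCI002	RC.dam4	RC.calf4	143283
GH.H	1	RCI002	RC.dam5	RC.calf5	174909
GH.H	1	RCI002	RC.dam6	RC.calf6	137177
H.H	2	HH.sire1	HH.dam1	HH.calf1	125899
H.H	3	HH.sire23	HH.dam2	HH.calf2	120690
H.H	3	HH.sire23	HH.dam3	HH.calf3	117590
Ho.H	4	HO1	Ho1.dam1	Ho1.calf1	141404
Ho.H	4	HO1	Ho1.dam2	Ho1.calf2	143436
Ho.H	4	HO1	Ho1.dam3	Ho1.calf3	184300
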