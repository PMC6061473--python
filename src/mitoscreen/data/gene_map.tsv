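name	start	end	strand	incomplete_terminal
ND1	3307	4262	heavy	True
ND2	4470	5511	heavy	True
ND3	10059	10404	heavy	True
ND4L	10470	10766	heavy	False
ND4	10760	12137	heavy	True
ND5	12337	14148	heavy	False
ND6	14149	14673	light	False
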