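name	count
Prozac	998
Fluoxetina	756
Sertralina	542
Escitalopram	248
Citta	210
Citalo	109
Paroxetina	69
Pram	49
Fluvoxamina	40
Citalopram	33
Seroxat	22
Eleval	21
Lexapro	20
Opra	18
Casbol	14
Ariale	11
Zoloft	9
Altruline	9
Paxil	7
Akarin	7
Heipram	4
Aremis	4
Cimal	3
Tiarix	2
Seretran	2
Dominium	2
Citox	2
Atenix	2
Aserin	2
Talam	1
Dalsan	1
Celexa	1
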