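generic_name	name	is_generic
Fluvoxamina	Fluvoxamina	1
Fluvoxamina	Dumirox	0
Fluvoxamina	Faverin	0
Fluvoxamina	Floxyfral	0
Fluvoxamina	Fluvoxin	0
Fluvoxamina	Luvox	0
Fluvoxamina	Uvox	0
Fluoxetina	Fluoxetina	1
Fluoxetina	Prozac	0
Fluoxetina	Reneuron	0
Fluoxetina	Adofen	0
Fluoxetina	Luramon	0
Fluoxetina	Sarafem	0
Paroxetina	Paroxetina	1
Paroxetina	Seroxat	0
Paroxetina	Motivan	0
Paroxetina	Frosinor	0
Paroxetina	Praxil	0
Paroxetina	Daparox	0
Paroxetina	Xetin	0
Paroxetina	Apo-oxpar	0
Paroxetina	Appoxar	0
Paroxetina	Aropax	0
Paroxetina	Aroxat	0
Paroxetina	Aroxat CR	0
Paroxetina	Bectam	0
Paroxetina	Benepax	0
Paroxetina	Casbol	0
Paroxetina	Cebrilin	0
Paroxetina	Deroxat	0
Paroxetina	Hemtrixil	0
Paroxetina	Ixicrol	0
Paroxetina	Loxamine	0
Paroxetina	Meplar	0
Paroxetina	Olane	0
Paroxetina	Optipar	0
Paroxetina	Oxetine	0
Paroxetina	Pamax	0
Paroxetina	ParadiseCR	0
Paroxetina	Paradox	0
Paroxetina	Paraxyle	0
Paroxetina	Parexis	0
Paroxetina	Paroxat	0
Paroxetina	Paroxet	0
Paroxetina	Paxan	0
Paroxetina	Paxera	0
Paroxetina	Paxil	0
Paroxetina	Paxil CR	0
Paroxetina	Pexot	0
Paroxetina	Plasare	0
Paroxetina	Pondera	0
Paroxetina	Posivyl	0
Paroxetina	Psicoasten	0
Paroxetina	Rexetin	0
Paroxetina	Seretran	0
Paroxetina	Sereupin	0
Paroxetina	Tiarix	0
Paroxetina	Tamcere	0
Paroxetina	Traviata	0
Paroxetina	Xerenex	0
Paroxetina	Xetroran	0
Sertralina	Sertralina	1
Sertralina	Aremis	0
Sertralina	Besitran	0
Sertralina	Zoloft	0
Sertralina	Altisben	0
Sertralina	Aserin	0
Sertralina	Altruline	0
Sertralina	Ariale	0
Sertralina	Asertral	0
Sertralina	Atenix	0
Sertralina	Eleval	0
Sertralina	Emergen	0
Sertralina	Dominium	0
Sertralina	Inosert	0
Sertralina	Irradial	0
Sertralina	Sedora	0
Sertralina	Serolux	0
Sertralina	Sertex	0
Citalopram	Citalopram	1
Citalopram	Seropram	0
Citalopram	Celexa	0
Citalopram	Akarin	0
Citalopram	C Pram S	0
Citalopram	Celapram	0
Citalopram	Celica	0
Citalopram	Ciazil	0
Citalopram	Cilate	0
Citalopram	Cilift	0
Citalopram	Cimal	0
Citalopram	Cipralex	0
Citalopram	Cipram	0
Citalopram	Cipramil	0
Citalopram	Cipraned	0
Citalopram	Cinapen	0
Citalopram	Ciprapine	0
Citalopram	Ciprotan	0
Citalopram	Citabax	0
Citalopram	Citaxin	0
Citalopram	Citalec	0
Citalopram	Citalex	0
Citalopram	Citalo	0
Citalopram	Citalopram	0
Citalopram	Citol	0
Citalopram	Citox	0
Citalopram	Citrol	0
Citalopram	Citta	0
Citalopram	Dalsan	0
Citalopram	Denyl	0
Citalopram	Elopram	0
Citalopram	Estar	0
Citalopram	Humorup	0
Citalopram	Humorap	0
Citalopram	Oropram	0
Citalopram	Opra	0
Citalopram	Pram	0
Citalopram	Pramcit	0
Citalopram	Procimax	0
Citalopram	Recital	0
Citalopram	Sepram	0
Citalopram	Szetalo	0
Citalopram	Talam	0
Citalopram	Temperax	0
Citalopram	Vodelax	0
Citalopram	Zentius	0
Citalopram	Zetalo	0
Citalopram	Cipratal	0
Citalopram	Zylotex	0
Escitalopram	Escitalopram	1
Escitalopram	Cipralex	0
Escitalopram	Diprex	0
Escitalopram	Esertia	0
Escitalopram	Essential	0
Escitalopram	Heipram	0
Escitalopram	Lexapro	0
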