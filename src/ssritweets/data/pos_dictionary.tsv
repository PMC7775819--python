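word	pos	person	number
yo	pronoun	1	singular
me	pronoun	1	singular
mí	pronoun	1	singular
conmigo	pronoun	1	singular
tú	pronoun	2	singular
te	pronoun	2	singular
ti	pronoun	2	singular
contigo	pronoun	2	singular
usted	pronoun	2	singular
él	pronoun	3	singular
ella	pronoun	3	singular
ello	pronoun	3	singular
le	pronoun	3	singular
nosotros	pronoun	1	plural
nosotras	pronoun	1	plural
nos	pronoun	1	plural
vosotros	pronoun	2	plural
vosotras	pronoun	2	plural
os	pronoun	2	plural
ustedes	pronoun	2	plural
ellos	pronoun	3	plural
ellas	pronoun	3	plural
les	pronoun	3	plural
tengo	verb		
tiene	verb		
tomo	verb		
toma	verb		
quiero	verb		
quiere	verb		
hacer	verb		
hace	verb		
puedo	verb		
puede	verb		
vamos	verb		
voy	verb		
dice	verb		
digo	verb		
creo	verb		
pienso	verb		
siento	verb		
veo	verb		
mira	verb		
dormir	verb		
comer	verb		
vivir	verb		
jugar	verb		
trabajar	verb		
escribir	verb		
leer	verb		
salir	verb		
llegar	verb		
casa	noun		
perro	noun		
gato	noun		
libro	noun		
mesa	noun		
tiempo	noun		
gente	noun		
mundo	noun		
vida	noun		
cosa	noun		
noche	noun		
día	noun		
agua	noun		
café	noun		
ciudad	noun		
trabajo	noun		
música	noun		
foto	noun		
amigo	noun		
amiga	noun		
madre	noun		
padre	noun		
semana	noun		
calle	noun		
cielo	noun		
mar	noun		
sol	noun		
luna	noun		
sueño	noun		
doctor	noun		
sertralina	noun		
fluoxetina	noun		
paroxetina	noun		
citalopram	noun		
escitalopram	noun		
fluvoxamina	noun		
muy	adverb		
siempre	adverb		
ahora	adverb		
luego	adverb		
aquí	adverb		
así	adverb		
hoy	adverb		
ayer	adverb		
ya	adverb		
casi	adverb		
pronto	adverb		
tarde	adverb		
cerca	adverb		
lejos	adverb		
grande	adjective		
pequeño	adjective		
nuevo	adjective		
viejo	adjective		
bonito	adjective		
raro	adjective		
largo	adjective		
corto	adjective		
rojo	adjective		
azul	adjective		
rápido	adjective		
lento	adjective		
fuerte	adjective		
claro	adjective		
oscuro	adjective		
tranquilo	adjective		
el	determiner		
la	determiner		
los	determiner		
las	determiner		
un	determiner		
una	determiner		
unos	determiner		
unas	determiner		
mi	determiner		
tu	determiner		
su	determiner		
de	adposition		
en	adposition		
a	adposition		
por	adposition		
para	adposition		
con	adposition		
desde	adposition		
hasta	adposition		
entre	adposition		
sobre	adposition		
y	conjunction		
o	conjunction		
pero	conjunction		
porque	conjunction		
aunque	conjunction		
cuando	conjunction		
ay	interjection		
uf	interjection		
eh	interjection		
oh	interjection		
enero	date		
febrero	date		
marzo	date		
lunes	date		
martes	date		
domingo	date		
que	other		
se	other		
es	other		
hay	other		
más	other		
como	other		
si	other		
también	other		
todo	other		
esto	other		
eso	other		
algo	other		
alguien	other		
mucho	other		
poco	other		
tanto	other		
otro	other		
otra	other		
igual	other		
vez	other		
parte	other		
forma	other		
caso	other		
cada	other		
donde	other		
mientras	other		
entonces	other		
pues	other		
además	other		
tal	other		
menos	other		
aún	other		
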