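word	emotion
feliz	happiness
felicidad	happiness
alegría	happiness
alegre	happiness
contento	happiness
contenta	happiness
sonrisa	happiness
genial	happiness
triste	sadness
tristeza	sadness
llorar	sadness
lloro	sadness
pena	sadness
melancolía	sadness
luto	sadness
desánimo	sadness
miedo	fear
terror	fear
susto	fear
pánico	fear
temor	fear
asustado	fear
asustada	fear
nervios	fear
rabia	anger
ira	anger
enfado	anger
enojo	anger
furia	anger
bronca	anger
coraje	anger
indignación	anger
asco	disgust
repugnancia	disgust
náusea	disgust
repulsión	disgust
grima	disgust
aversión	disgust
sorpresa	surprise
sorprendido	surprise
sorprendida	surprise
asombro	surprise
increíble	surprise
inesperado	surprise
impresionante	surprise
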