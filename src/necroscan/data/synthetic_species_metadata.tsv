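seq_id	species	lineage	subtype	n_taar_genes
mdTAAR6	Monodelphis domestica	Marsupialia	TAAR6	21
mdTAAR8	Monodelphis domestica	Marsupialia	TAAR8	21
tmTAAR6	Trichechus manatus	Afrotheria	TAAR6	3
tmTAAR8	Trichechus manatus	Afrotheria	TAAR8	3
laTAAR6	Loxodonta africana	Afrotheria	TAAR6	9
laTAAR8	Loxodonta africana	Afrotheria	TAAR8	9
btTAAR6	Bos taurus	Artiodactyla	TAAR6	21
cdTAAR6	Camelus dromedarius	Artiodactyla	TAAR6	8
cdTAAR8	Camelus dromedarius	Artiodactyla	TAAR8	8
ssTAAR6	Sus scrofa	Artiodactyla	TAAR6	9
ssTAAR8	Sus scrofa	Artiodactyla	TAAR8	9
ecTAAR6	Equus caballus	Perissodactyla	TAAR6	10
ecTAAR8	Equus caballus	Perissodactyla	TAAR8	10
umTAAR6	Ursus maritimus	Carnivora	TAAR6	8
umTAAR8	Ursus maritimus	Carnivora	TAAR8	8
fcTAAR6	Felis catus	Carnivora	TAAR6	2
rnTAAR6	Rattus norvegicus	Rodentia	TAAR6	17
rnTAAR8	Rattus norvegicus	Rodentia	TAAR8	17
mmTAAR6	Mus musculus	Rodentia	TAAR6	15
mmTAAR8	Mus musculus	Rodentia	TAAR8	15
paTAAR6	Pongo abelii	Primates	TAAR6	6
paTAAR8	Pongo abelii	Primates	TAAR8	6
ggTAAR6	Gorilla gorilla	Primates	TAAR6	6
ggTAAR8	Gorilla gorilla	Primates	TAAR8	6
hsTAAR6	Homo sapiens	Primates	TAAR6	6
hsTAAR8	Homo sapiens	Primates	TAAR8	6
	Canis lupus familiaris	Carnivora		2
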