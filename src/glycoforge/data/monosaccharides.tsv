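# name	superclass	carbons	stem	shape	color	default_config	anomeric	mods	amines	fischer
Glc	HEX	6	dglc	circle	blue	D	1	-	-	2:R,3:L,4:R,5:R
Man	HEX	6	dman	circle	green	D	1	-	-	2:L,3:L,4:R,5:R
Gal	HEX	6	dgal	circle	yellow	D	1	-	-	2:R,3:L,4:L,5:R
Gul	HEX	6	dgul	circle	orange	D	1	-	-	2:R,3:R,4:L,5:R
Alt	HEX	6	dalt	circle	pink	D	1	-	-	2:L,3:R,4:R,5:R
All	HEX	6	dall	circle	purple	D	1	-	-	2:R,3:R,4:R,5:R
Tal	HEX	6	dtal	circle	lightblue	D	1	-	-	2:L,3:L,4:L,5:R
Ido	HEX	6	dido	circle	brown	D	1	-	-	2:L,3:R,4:L,5:R
GlcN	HEX	6	dglc	crossed-square	blue	D	1	-	2	2:R,3:L,4:R,5:R
ManN	HEX	6	dman	crossed-square	green	D	1	-	2	2:L,3:L,4:R,5:R
GalN	HEX	6	dgal	crossed-square	yellow	D	1	-	2	2:R,3:L,4:L,5:R
GlcA	HEX	6	dglc	divided-diamond	blue	D	1	6:a	-	2:R,3:L,4:R,5:R
ManA	HEX	6	dman	divided-diamond	green	D	1	6:a	-	2:L,3:L,4:R,5:R
GalA	HEX	6	dgal	divided-diamond	yellow	D	1	6:a	-	2:R,3:L,4:L,5:R
IdoA	HEX	6	lido	divided-diamond	brown	L	1	6:a	-	2:L,3:R,4:L,5:R
Qui	HEX	6	dglc	triangle	blue	D	1	6:d	-	2:R,3:L,4:R,5:R
Rha	HEX	6	lman	triangle	green	L	1	6:d	-	2:L,3:L,4:R,5:R
Fuc	HEX	6	lgal	triangle	red	L	1	6:d	-	2:R,3:L,4:L,5:R
Ara	PEN	5	lara	star	green	L	1	-	-	2:L,3:R,4:R
Lyx	PEN	5	dlyx	star	yellow	D	1	-	-	2:L,3:L,4:R
Xyl	PEN	5	dxyl	star	orange	D	1	-	-	2:R,3:L,4:R
Rib	PEN	5	drib	star	pink	D	1	-	-	2:R,3:R,4:R
Kdn	NON	9	dgro-dgal	diamond	green	D	2	1:a|2:keto|3:d	-	4:R,5:L,6:L,7:R,8:R
Neu	NON	9	dgro-dgal	diamond	brown	D	2	1:a|2:keto|3:d	5	4:R,5:L,6:L,7:R,8:R
Kdo	OCT	8	dman	hexagon	yellow	D	2	1:a|2:keto|3:d	-	4:L,5:L,6:R,7:R
LDmanHep	HEP	7	lgro-dman	hexagon	green	D	1	-	-	2:L,3:L,4:R,5:R,6:L
DDmanHep	HEP	7	dgro-dman	hexagon	pink	D	1	-	-	2:L,3:L,4:R,5:R,6:R
Fru	HEX	6	dara	pentagon	green	D	2	2:keto	-	3:L,4:R,5:R
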