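rank	drug	verb1	protein1	verb2	protein2	verb3	protein3	verb4	side_effect
1	anastrozole	observe	ar	decrease	muc5ac	use	polymerase	suggest	acute hepatitis
2	anastrozole	differ	age	associate	muc5ac	use	polymerase	suggest	acute hepatitis
3	irinotecan	inhibit	p38	inhibit	g17	inhibit, neutralize	gastrin	associate	dyspepsia
4	tamoxifen	abolish, delete	p38	inhibit	g17	inhibit, neutralize	gastrin	associate	dyspepsia
5	doxorubicin	induce, activate	p38	inhibit	g17	inhibit, neutralize	gastrin	associate	dyspepsia
6	nilotinib	reduce, increase	p38	inhibit	g17	inhibit, neutralize	gastrin	associate	dyspepsia
7	sorafenib	inhibit, block	p38	inhibit	g17	inhibit, neutralize	gastrin	associate	dyspepsia
8	bortezomib	inhibit, decrease	p38	inhibit	g17	inhibit, neutralize	gastrin	associate	dyspepsia
9	bortezomib	induce	protein kinase	phosphorylate	p150	occur	cd5	present	glomerulonephropathy
10	cetrorelix	reduce, decrease	egf	decrease	p15	increase	smad4	interact	septal defect
11	cetrorelix	inhibit	pcna	conserve	p15	increase	smad4	interact	septal defect
12	bortezomib	induce, stimulate	p53	inactivate	p150	occur	cd5	present	glomerulonephropathy
13	gemcitabine	increase	il-2	stimulate	gls	identify, serve	glutaminase	catalyze	nervous system disorders
14	doxorubicin	decrease, enhance	il-6	interact	clec-2	serve	podoplanin	accelerate	leukoplakia
15	nilotinib	reduce, increase	p38	enhance, inhibit	mao-a	increase	ssao	predict	intracranial hemorrhage
16	cisplatin	induce, increase	tnf-α	increase, decrease	spo	use	lipase	occur	hypophosphatemia
17	methotrexate	inhibit	lp	result	nrl	result, become	rod	lead	nocardiosis
18	chlorambucil	induce, up-regulate	p53	promote	l3mbtl1	enhance, decrease	erythropoietin	exert	ureteral obstruction
19	methotrexate	up-regulate, inhibit	ts	encode	kinesin-2	reduce	rod	lead	nocardiosis
20	methotrexate	separate, observe	cr	increase	cofilin-1	correlate	rod	lead	nocardiosis
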