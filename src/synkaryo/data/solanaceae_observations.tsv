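# Multi-species Solanaceae rearrangement observations, expressed against the
# tomato reference scaffold (20 markers per chromosome, ranks 1-20, centromere
# between ranks 10 and 11).  States per species: R = shares the reference
# order in the region, E = carries the event, U = uninformative (region
# reshuffled by translocations or too few shared markers).  Nicotiana is
# uninformative for inversion timing except where noted; it is used for
# translocations.  For inversions span_lo/span_hi is the inverted block's
# rank span; for translocations it is the breakpoint rank interval.
event_id	kind	ref_chromosome	span_lo	span_hi	min_count	tomato	potato	eggplant	pepper	nicotiana	note
inv_T2_t1	inversion	T2	3	7	1	R	E	E	E	U	shared by potato/eggplant/pepper; derived on the tomato branch
inv_T5_t1	inversion	T5	12	16	1	R	E	E	E	U	shared by potato, eggplant (E3b) and pepper (P11a); derived in tomato
inv_T9_t1	inversion	T9	4	8	1	R	E	E	E	U	separates T9 from Pt9/E9/P9a; derived in tomato
inv_T10_t1	inversion	T10	6	9	1	R	E	U	E	U	potato and pepper agree against tomato; eggplant region reshuffled
inv_T11_pt1	inversion	T11	5	8	1	R	E	R	R	U	seen in potato only
inv_T12_pt1	inversion	T12	13	17	1	R	E	U	R	U	potato differs; tomato agrees with pepper counterparts
inv_T6_a1	inversion	T6	2	6	1	R	R	E	E	U	top-of-chromosome inversion shared by eggplant and pepper
inv_T6_a2	inversion	T6	14	18	1	R	R	E	U	E	bottom inversion shared by eggplant and Nicotiana (N6b); pepper carries its own local event
inv_T11_a1	inversion	T11	12	15	1	R	R	E	E	U	shared by eggplant (E11a/E12b) and pepper (P12a/P11b)
inv_T11_a2	inversion	T11	16	19	1	R	R	E	E	U	second inversion shared by eggplant and pepper
inv_T1_e1	inversion	T1	3	7	1	R	R	E	R	U	eggplant-only inversion on E1
inv_T2_e1	inversion	T2	9	13	1	R	R	E	R	U	eggplant inversion not seen in pepper
inv_T2_e2	inversion	T2	15	18	1	R	R	E	R	U	second eggplant inversion on chromosome 2
inv_T3_e1	inversion	T3	2	5	1	R	R	E	R	R	eggplant inversion; not seen in pepper or Nicotiana
inv_T3_e2	inversion	T3	7	10	1	R	R	E	R	R	second eggplant inversion on chromosome 3
inv_T4_e1	inversion	T4	3	6	1	R	R	E	R	U	derived inversion on E11b
inv_T4_e2	inversion	T4	8	12	1	R	R	E	R	U	derived inversion on E11b
inv_T4_e3	inversion	T4	14	17	1	R	R	E	R	U	derived inversion on E11b
inv_T5_e1	inversion	T5	2	6	1	R	R	E	R	U	eggplant inversions accompanying the E3b/E10a reshuffle; exact number unresolved, counted once
inv_T7_e1	inversion	T7	5	9	1	R	R	E	R	U	single derived inversion on E7
inv_T10_e1	inversion	T10	2	4	1	R	R	E	R	U	eggplant multi-inversion series on chromosome 10
inv_T10_e2	inversion	T10	5	8	1	R	R	E	R	U	eggplant multi-inversion series on chromosome 10
inv_T10_e3	inversion	T10	10	13	1	R	R	E	R	U	eggplant multi-inversion series on chromosome 10
inv_T10_e4	inversion	T10	14	16	1	R	R	E	R	U	eggplant multi-inversion series on chromosome 10
inv_T10_e5	inversion	T10	17	19	1	R	R	E	R	U	eggplant multi-inversion series on chromosome 10
inv_T12_e1	inversion	T12	2	5	1	R	U	E	R	U	inversion on E10b; derived in eggplant
inv_T5_ate1	inversion	T5	7	10	1	R	R	R	E	E	pepper and Nicotiana share the inversion; derived on the branch to the tomato/potato/eggplant ancestor
inv_T6_p1	inversion	T6	8	11	1	R	R	R	E	R	pepper-only inversion (Nicotiana informative here by exception)
inv_T1_u1	inversion	T1	8	13	1	R	R	R	E	U	P1b pericentric inversion; timing between pepper and its ancestor branch unresolved
inv_T1_u2	inversion	T1	9	14	1	R	R	R	E	U	P1b pericentric inversion; timing unresolved
inv_T1_u3	inversion	T1	2	6	1	R	R	R	E	U	P1b paracentric inversion; timing unresolved
inv_T1_u4	inversion	T1	14	18	1	R	R	R	E	U	P1b paracentric inversion; timing unresolved
inv_T2_u1	inversion	T2	4	7	1	R	R	R	E	U	pepper inversion; Nicotiana order too reshuffled to time it
inv_T2_u2	inversion	T2	12	16	1	R	R	R	E	U	pepper inversion; timing unresolved
inv_T3_u1	inversion	T3	12	15	1	R	R	R	E	U	pepper inversion (P4a/P3c); timing unresolved
inv_T3_u2	inversion	T3	16	19	1	R	R	R	E	U	pepper inversion (P4a/P3c); timing unresolved
inv_T4_u1	inversion	T4	2	5	1	R	R	R	E	U	inversion on P5a; timing unknown
inv_T11_u1	inversion	T11	7	10	1	R	R	R	E	U	additional pepper inversion; timing unknown
inv_T12_u1	inversion	T12	7	10	1	R	R	R	E	U	inversion between P12c and T12; timing unknown
tr_T10_e1	translocation	T10	4	5	1	R	R	E	R	R	chromosome-10 markers moved to E4 (junction flanked by TG386/T677 on the eggplant map); derived in eggplant
tr_T10_e2	translocation	T10	14	15	1	R	R	E	R	R	chromosome-10 markers moved to E10; derived in eggplant; possibly the same event as tr_T10_e1 (count ambiguity)
tr_T5_e_ins	translocation	T5	2	3	1	R	R	E	R	R	chromosome-5 segment inserted into E3 (E3b embedded); derived in eggplant
tr_T12_e_ins	translocation	T12	4	5	1	R	R	E	R	R	chromosome-12 segment inserted into E10 (E12a); derived in eggplant
tr_T8_p1	translocation	T8	6	7	1	R	R	R	E	R	non-reciprocal translocation producing P1/P8; absent in Nicotiana; derived in pepper
tr_T4_p_ins	translocation	T4	10	12	1	R	R	U	E	R	small chromosome-4 segment inserted into P12; derived in pepper
tr_T12_p1	translocation	T12	7	8	1	R	R	U	E	R	junction separating P9b and P3b; derived in pepper
tr_T4_e1	translocation	T4	9	11	1	R	R	E	U	U	junction between E11b and E4b; timing between eggplant and its ancestor branch unresolved
tr_T5_e1	translocation	T5	9	11	1	R	R	E	U	U	junction between E3b and E5a material; timing unresolved
tr_T5_p1	translocation	T5	10	11	1	R	R	U	E	U	junction between P11a and P5b; timing unresolved
tr_T5_n1	translocation	T5	9	12	1	R	R	U	U	E	junction between N10b and N5a; timing unresolved
tr_T9_p1	translocation	T9	10	12	1	R	R	R	E	U	junction between P9a and P3a; timing unresolved
tr_T9_n1	translocation	T9	9	11	1	R	R	R	U	E	junction between N7b and N1b; timing unresolved
tr_T3_p1	translocation	T3	16	17	1	R	R	R	E	U	junction producing P4a and P3c; timing unresolved
tr_T3_n1	translocation	T3	15	17	1	R	R	R	U	E	junction producing N9c and N3b; timing unresolved
tr_T11_e1	translocation	T11	9	11	1	R	R	E	U	U	eggplant junction (E11a/E12b); timing unresolved
tr_T11_p1	translocation	T11	9	11	1	R	R	U	E	U	pepper junction (P12a/P11b); timing unresolved
tr_T11_n1	translocation	T11	10	12	1	R	R	U	U	E	Nicotiana junction sharing the chromosome-11 breakpoint; timing unresolved
tr_T12_e1	translocation	T12	10	12	1	R	R	E	U	U	junction separating E10b and E5b; timing unresolved
tr_T12_p2	translocation	T12	10	11	1	R	R	U	E	U	junction separating P3b and P12c; timing unresolved
tr_T12_n1	translocation	T12	9	11	1	R	R	U	U	E	Nicotiana junction between N6b and N12b; timing unresolved
tr_T1_n1	translocation	T1	3	4	1	R	R	R	R	E	Nicotiana junction (N11c/N9b/N1a series); timing between the Nicotiana branch and the basal branch unresolved
tr_T1_n2	translocation	T1	13	14	1	R	R	R	R	E	second Nicotiana junction on chromosome 1; timing unresolved
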