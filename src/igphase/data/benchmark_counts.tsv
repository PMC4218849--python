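# Published benchmark run: one healthy-donor IgG repertoire amplified as
# four independent library preparations (preps 1-3 IgG only, prep 4 also
# light chains / other isotypes) plus one HIV-1 patient time point.
# "nd" = category not sequenced, "na" = not applicable.
#total_reads	10249237
#sample_undetermined	1981155
#contaminant	1381101
sample	category	assigned_pairs	merged	rearranged
donor_prep1	IgG1	529390	515758	505942
donor_prep1	IgG2	369741	360472	354751
donor_prep1	IgG3	36604	35620	34920
donor_prep1	IgG4	3785	3645	3572
donor_prep1	klMA	nd	nd	nd
donor_prep1	undetermined	11577	na	na
donor_prep2	IgG1	692673	674590	660899
donor_prep2	IgG2	488483	475851	467958
donor_prep2	IgG3	50454	48880	47773
donor_prep2	IgG4	6191	5968	5859
donor_prep2	klMA	nd	nd	nd
donor_prep2	undetermined	18326	na	na
donor_prep3	IgG1	641364	623522	611013
donor_prep3	IgG2	453471	441108	433565
donor_prep3	IgG3	46361	44911	43848
donor_prep3	IgG4	5386	5155	5030
donor_prep3	klMA	nd	nd	nd
donor_prep3	undetermined	18149	na	na
donor_prep4	IgG1	699378	679819	665267
donor_prep4	IgG2	481592	468433	460214
donor_prep4	IgG3	52028	50328	49024
donor_prep4	IgG4	7199	6900	6695
donor_prep4	klMA	1317918	1257301	1210698
donor_prep4	undetermined	84941	na	na
patient_wk213	IgG1	677787	659884	646977
patient_wk213	IgG2	183718	178800	175718
patient_wk213	IgG3	163839	158878	155704
patient_wk213	IgG4	4487	4366	4211
patient_wk213	klMA	1151587	1097762	1053604
patient_wk213	undetermined	71653	na	na
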